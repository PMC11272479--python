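"""Cohort container and descriptive / rank statistics for socket designs.

A cohort is a per-socket table: the eight design variables plus recipient
demographics (sex, age, reason for amputation, time since amputation,
design label PTB / TSB / PTB-SC, K-level, socket comfort score).  One
individual may contribute several sockets; all statistics here are per
socket.

Rank-based methods are used throughout because rectification size
distributions are not normally distributed: Mann-Whitney U for PTB vs TSB
group differences (with Bonferroni correction over the eight variables) and
Spearman rank correlation for pairwise association between rectification
sizes.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CohortError
from .rectification import PROFILE_COLUMNS, PROFILE_VARIABLES

__all__ = [
    "DesignCohort",
    "cohort_summary",
    "mann_whitney_u",
    "bonferroni_adjust",
    "spearman_matrix",
    "compare_designs",
    "reference_demographics_cohort",
    "load_rectification_table",
]

# column-name aliases accepted when importing externally published
# rectification tables (deposited processed data uses long region names)
_COLUMN_ALIASES = {
    "PT_mm": ("pt", "pt_mm", "patellar tendon", "patellar_tendon"),
    "FH_mm": ("fh", "fh_mm", "fibular head", "fibula head", "fibular_head"),
    "MP_mm": ("mp", "mp_mm", "medial paratibial", "medial_paratibial"),
    "LP_mm": ("lp", "lp_mm", "lateral paratibial", "lateral_paratibial"),
    "TC_mm": ("tc", "tc_mm", "tibial crest", "tibial_crest"),
    "DE_mm": ("de", "de_mm", "distal end", "distal_end"),
    "LMC_mm": ("lmc", "lmc_mm", "sc", "lateral-medial condyles",
               "supracondylar"),
    "VR_pct": ("vr", "vr_pct", "volume reduction", "volume_reduction"),
}


def load_rectification_table(path) -> pd.DataFrame:
    """Read an externally published rectification table into canonical form.

    Accepts CSV (or Excel) files whose columns name the eight design
    variables by abbreviation or by full region name, case-insensitively,
    and returns a DataFrame with the canonical columns ``PT_mm`` ...
    ``VR_pct`` (plus ``design`` when a design-label column is present).
    Intended for deposited processed datasets accompanying published
    cohorts, which are downloaded separately by the user.
    """
    from pathlib import Path as _P

    path = _P(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path, comment="#")
    lookup = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        keys = set(aliases) | {canon.lower()}
        for col in raw.columns:
            if str(col).strip().lower() in keys:
                lookup[col] = canon
                break
    out = raw.rename(columns=lookup)
    missing = [c for c in PROFILE_COLUMNS if c not in out.columns]
    if missing:
        raise CohortError(
            f"could not identify columns {missing} in {path.name}; "
            f"found {list(raw.columns)}"
        )
    for col in raw.columns:
        if str(col).strip().lower() in ("design", "design_label", "socket type",
                                        "socket_type"):
            out = out.rename(columns={col: "design"})
    return out[[c for c in out.columns
                if c in PROFILE_COLUMNS or c == "design"]]

DESIGN_LABELS = ("PTB", "TSB", "PTB-SC")
REASONS = ("dysvascularity", "trauma", "infection", "neuro", "neoplasia",
           "congenital")

_VAR2COL = dict(zip(PROFILE_VARIABLES, PROFILE_COLUMNS))


class DesignCohort:
    """Validated per-socket table of design variables and demographics.

    Expected columns: the eight design variables (``PT_mm`` ... ``VR_pct``)
    plus ``sex`` (F|M), ``age`` (years), ``reason``, ``time_since_amputation``
    (years), ``design`` (PTB|TSB|PTB-SC), ``k_level`` (1-4) and optional
    ``scs`` (1-10).  ``reason`` may be missing for individual sockets (not
    every clinical record carries one).
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy().reset_index(drop=True)
        if len(df) == 0:
            raise CohortError("cohort table is empty")
        for col in PROFILE_COLUMNS:
            if col not in df.columns:
                raise CohortError(f"missing design-variable column {col!r}")
        if "design" in df.columns:
            bad = set(df["design"].dropna()) - set(DESIGN_LABELS)
            if bad:
                raise CohortError(f"unknown design labels: {sorted(bad)}")
        if "reason" in df.columns:
            bad = set(df["reason"].dropna()) - set(REASONS)
            if bad:
                raise CohortError(f"unknown amputation reasons: {sorted(bad)}")
        if "k_level" in df.columns:
            k = df["k_level"].dropna()
            if len(k) and not k.isin([1, 2, 3, 4]).all():
                raise CohortError("k_level must be in 1..4")
        if "scs" in df.columns:
            s = df["scs"].dropna()
            if len(s) and ((s < 1) | (s > 10)).any():
                raise CohortError("scs must lie in [1, 10]")
        self.table = df

    def __len__(self):
        return len(self.table)

    def variables(self) -> pd.DataFrame:
        """The eight design-variable columns, in canonical order."""
        return self.table[list(PROFILE_COLUMNS)]

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DesignCohort":
        return cls(pd.read_csv(path, comment="#"))


def _counts(series: pd.Series, values) -> dict:
    vc = series.value_counts()
    return {v: int(vc.get(v, 0)) for v in values}


def _stratum_row(df: pd.DataFrame, total_n: int) -> dict:
    row: dict = {"n": len(df)}
    row["pct_of_total"] = int(round(100.0 * len(df) / total_n))
    if "sex" in df.columns:
        for k, v in _counts(df["sex"], ("F", "M")).items():
            row[f"n_{k}"] = v
    if "design" in df.columns:
        dcounts = _counts(df["design"], DESIGN_LABELS)
        for k, v in dcounts.items():
            row[f"n_{k}"] = v
        for k, v in dcounts.items():
            row[f"pct_{k}"] = int(round(100.0 * v / len(df)))
    if "age" in df.columns:
        age = df["age"].dropna()
        row["age_mean"] = round(float(age.mean()), 1) if len(age) else np.nan
        row["age_sd"] = round(float(age.std(ddof=1)), 1) if len(age) > 1 else np.nan
    if "time_since_amputation" in df.columns:
        t = df["time_since_amputation"].dropna()
        if len(t):
            row["time_median"] = round(float(t.median()), 1)
            row["time_min"] = round(float(t.min()), 1)
            row["time_max"] = round(float(t.max()), 1)
    if "k_level" in df.columns:
        k = df["k_level"].dropna().astype(int)
        kc = _counts(k, (1, 2, 3, 4))
        for lev, v in kc.items():
            row[f"n_k{lev}"] = v
        if len(k):
            row["k_mean"] = round(
                sum(lev * v for lev, v in kc.items()) / sum(kc.values()), 1
            )
    if "scs" in df.columns:
        s = df["scs"].dropna().astype(int)
        for lev in range(5, 11):
            row[f"n_scs{lev}"] = int((s == lev).sum())
        if len(s):
            row["scs_mean"] = round(float(s.mean()), 1)
    return row


def cohort_summary(cohort: DesignCohort, strata: str = "overall") -> pd.DataFrame:
    """Demographic summary per stratum (means to 1 d.p., shares to nearest %).

    ``strata`` is one of ``overall``, ``sex``, ``design``, ``reason`` or any
    categorical column of the cohort table.  Per stratum the table reports
    n, sex and design counts, design shares within the stratum, mean (s.d.)
    age, median (range) time since amputation, K-level counts with the
    count-weighted mean, SCS counts and mean, and the stratum's share of the
    whole cohort.  Single-member strata report s.d. as missing and a
    collapsed range.
    """
    df = cohort.table
    if strata == "overall":
        return pd.DataFrame({"overall": _stratum_row(df, len(df))}).T
    if strata not in df.columns:
        raise CohortError(f"unknown stratum key {strata!r}")
    rows = {}
    for key, grp in df.groupby(strata, dropna=True, observed=True):
        rows[key] = _stratum_row(grp, len(df))
    if not rows:
        raise CohortError(f"stratum column {strata!r} has no non-missing values")
    return pd.DataFrame(rows).T


# reason -> (PTB, TSB, PTB-SC) socket counts in the reference UK service
# evaluation population of 163 CAD/CAM sockets; 8 further sockets carry no
# recorded reason (designs 5/1/2), bringing the design totals to 135/21/7.
_REFERENCE_REASON_DESIGN = {
    "dysvascularity": (59, 3, 1),
    "trauma": (32, 14, 1),
    "infection": (22, 2, 2),
    "neuro": (10, 0, 0),
    "neoplasia": (5, 1, 0),
    "congenital": (2, 0, 1),
    None: (5, 1, 2),
}
_REFERENCE_KLEVEL = (22, 61, 74, 6)


def reference_demographics_cohort() -> DesignCohort:
    """Fixed 163-socket cohort reproducing the reference demographic counts.

    The joint reason-by-design counts, the K-level distribution and the
    design totals (135 PTB / 21 TSB / 7 PTB-SC) match the published UK
    service-evaluation population this package's defaults emulate.  Design
    variables are filled with nominal placeholder sizes: the table exists
    for demographic arithmetic (shares, count-weighted K-level means), not
    geometry.
    """
    rows = []
    for reason, counts in _REFERENCE_REASON_DESIGN.items():
        for design, cnt in zip(DESIGN_LABELS, counts):
            rows.extend({"reason": reason, "design": design} for _ in range(cnt))
    df = pd.DataFrame(rows)
    assert len(df) == 163
    k = np.concatenate([np.full(c, lev) for lev, c in
                        enumerate(_REFERENCE_KLEVEL, start=1)])
    df["k_level"] = k
    df["sex"] = ["F"] * 51 + ["M"] * 111 + [None]
    df["age"] = 57.7
    df["time_since_amputation"] = 1.2
    df["scs"] = 8
    df["socket_id"] = [f"REF-{i:03d}" for i in range(len(df))]
    for col in PROFILE_COLUMNS:
        df[col] = 3.0
    return DesignCohort(df)


def _exact_mwu_p(x: np.ndarray, y: np.ndarray, u_x: float) -> float:
    """Two-sided exact p by enumeration of all rank assignments (no ties)."""
    n, m = len(x), len(y)
    ranks = np.argsort(np.argsort(np.concatenate([x, y]))) + 1.0
    pooled = list(range(n + m))
    rank_arr = ranks
    target = u_x
    count_le = 0
    count_ge = 0
    total = comb(n + m, n)
    for subset in combinations(pooled, n):
        r = rank_arr[list(subset)].sum()
        u = r - n * (n + 1) / 2
        if u <= target + 1e-12:
            count_le += 1
        if u >= target - 1e-12:
            count_ge += 1
    p = 2.0 * min(count_le, count_ge) / total
    return min(p, 1.0)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U statistic (for group A) and a two-sided p-value.

    Small untied samples (n_A + n_B <= 16, no tied values) use exact
    enumeration over rank assignments; otherwise the normal approximation
    with tie-corrected variance and continuity correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise CohortError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2)
    if (len(a) + len(b)) <= 16 and not has_ties:
        p = _exact_mwu_p(a, b, u_a)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
    return u_a, float(p)


def bonferroni_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p).

    ``m`` defaults to the number of p-values and must be at least that.
    """
    p = np.atleast_1d(np.asarray(pvalues, dtype=float))
    if m is None:
        m = p.size
    if m < p.size:
        raise CohortError(f"m={m} smaller than number of p-values ({p.size})")
    return np.minimum(1.0, m * p)


def spearman_matrix(
    cohort: DesignCohort | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank-correlation matrix over the eight design variables.

    rho is the Pearson correlation of midranks per variable pair; two-sided
    p-values use the t approximation with n-2 degrees of freedom.  The
    matrix is symmetric with unit diagonal.  A constant variable yields
    missing (NaN) correlations for its pairs, not zero.

    Sign convention: a positive correlation means both rectifications grow
    together on their own carve/build scales (both builds or both carves
    vary together); a negative one pairs a build with a carve.
    """
    df = cohort.variables() if isinstance(cohort, DesignCohort) else cohort
    df = df[list(df.columns)]
    n = len(df)
    if n < 4:
        raise CohortError("need at least 4 profiles for a correlation matrix")
    cols = list(df.columns)
    ranks = {c: sps.rankdata(df[c].to_numpy(dtype=float)) for c in cols}
    const = {c: np.ptp(df[c].to_numpy(dtype=float)) == 0 for c in cols}
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            if j <= i:
                continue
            if const[ci] or const[cj]:
                r, p = np.nan, np.nan
            else:
                r = float(np.corrcoef(ranks[ci], ranks[cj])[0, 1])
                if abs(r) >= 1.0:
                    p = 0.0
                else:
                    t = r * np.sqrt((n - 2) / (1.0 - r * r))
                    p = float(2.0 * sps.t.sf(abs(t), n - 2))
            rho.loc[ci, cj] = rho.loc[cj, ci] = r
            pmat.loc[ci, cj] = pmat.loc[cj, ci] = p
    for c in cols:
        if const[c]:
            rho.loc[c, c] = np.nan
    return rho, pmat


def compare_designs(
    cohort: DesignCohort,
    m: int = 8,
    merge_ptbsc: bool = True,
) -> pd.DataFrame:
    """PTB vs TSB Mann-Whitney comparison per design variable.

    Supracondylar PTB sockets (PTB-SC) are pooled with PTB by default, so
    the comparison is two-group.  Bonferroni correction uses ``m`` tests
    (default 8, one per design variable).
    """
    df = cohort.table
    design = df["design"].copy()
    if merge_ptbsc:
        design = design.replace({"PTB-SC": "PTB"})
    rows = []
    pvals = []
    for var in PROFILE_VARIABLES:
        col = _VAR2COL[var]
        ga = df.loc[design == "PTB", col].dropna().to_numpy()
        gb = df.loc[design == "TSB", col].dropna().to_numpy()
        u, p = mann_whitney_u(ga, gb)
        rows.append({"variable": var, "U": u, "p": p,
                     "median_PTB": float(np.median(ga)),
                     "median_TSB": float(np.median(gb))})
        pvals.append(p)
    out = pd.DataFrame(rows).set_index("variable")
    out["p_adj"] = bonferroni_adjust(pvals, m=m)
    return out
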