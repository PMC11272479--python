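"""Batch extraction and cohort analysis with reproducible file outputs.

Two entry points tie the stages together:

* :func:`run_extract` — walk a manifest of limb/socket/landmark/mask files,
  align each pair and extract its rectification profile into a cohort CSV.
  Rows fail independently; a failure is recorded and the run continues.
* :func:`run_analysis` — take a cohort CSV and emit the full report bundle:
  demographic summaries, per-design rectification distributions, the
  Mann-Whitney PTB/TSB comparison, the Spearman correlation matrix, KDE
  size categories, pairwise NB probability panels and most-probable
  templates for a chosen volume-reduction category.

Every output CSV starts with a ``#`` header line carrying the tool version,
a hash of the effective configuration and the seed, so identical inputs
reproduce byte-identical outputs (no timestamps are written).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import align_pair
from .cohort import (
    DesignCohort,
    cohort_summary,
    compare_designs,
    spearman_matrix,
)
from .design_model import (
    CATEGORIES,
    conditional_probabilities,
    fit_all_categories,
    fit_conditional_nb,
    generate_template,
    render_template_map,
)
from .errors import RectimapError
from .mesh import (
    LandmarkSet,
    RegionMaskSet,
    RigidTransform,
    read_mesh,
    write_deviation_ply,
)
from .rectification import PROFILE_VARIABLES, extract_profile

__all__ = ["run_extract", "run_analysis"]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _header(config: dict, seed) -> str:
    return (f"# rectimap version={__version__} "
            f"config_hash={_config_hash(config)} seed={seed}")


def _write_csv(df: pd.DataFrame, path: Path, header: str, index=True):
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=index)


def run_extract(
    manifest: str | Path | pd.DataFrame,
    out_csv: str | Path,
    seed: int = 0,
) -> pd.DataFrame:
    """Align and extract every limb/socket pair listed in a manifest.

    The manifest (CSV or DataFrame) needs columns ``socket_id``, ``limb``,
    ``socket``, ``landmarks_limb``, ``landmarks_socket``, ``masks`` and
    optionally ``design_label`` and ``transform_override`` (a JSON file
    with a rigid transform applied after ICP).  Failed rows get
    ``status != ok`` and NaN variables; the run continues.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, comment="#")
    required = {"socket_id", "limb", "socket", "landmarks_limb",
                "landmarks_socket", "masks"}
    missing = required - set(manifest.columns)
    if missing:
        raise RectimapError(f"manifest missing columns: {sorted(missing)}")
    rows = []
    for _, rec in manifest.iterrows():
        row = {"socket_id": rec["socket_id"],
               "design_label": rec.get("design_label")}
        try:
            limb = read_mesh(rec["limb"])
            socket = read_mesh(rec["socket"])
            lm_l = LandmarkSet.from_json(rec["landmarks_limb"])
            lm_s = LandmarkSet.from_json(rec["landmarks_socket"])
            masks = RegionMaskSet.from_json(rec["masks"])
            override = None
            ov = rec.get("transform_override")
            if isinstance(ov, str) and ov:
                override = RigidTransform.from_dict(
                    json.loads(Path(ov).read_text())
                )
            from .synthetic import anterior_subpatellar_mask

            amask = anterior_subpatellar_mask(limb, lm_l)
            ares = align_pair(limb, socket, lm_l, lm_s, amask,
                              override=override)
            from .mesh import apply_transform

            aligned = apply_transform(socket, ares.transform)
            profile, _ = extract_profile(
                limb, aligned, lm_l, masks,
                socket_id=str(rec["socket_id"]),
                design_label=row["design_label"],
            )
            row.update(profile.as_dict())
            row["status"] = "ok"
            row["coarse_rms_mm"] = ares.coarse_rms
            row["icp_rms_mm"] = ares.icp.rms
            row["icp_converged"] = ares.icp.converged
        except (RectimapError, OSError, ValueError, KeyError) as exc:
            row["status"] = f"failed: {exc}"
            warnings.warn(f"socket {rec['socket_id']}: {exc}", stacklevel=2)
        rows.append(row)
    out = pd.DataFrame(rows)
    header = _header({"manifest_columns": sorted(manifest.columns)}, seed)
    _write_csv(out, Path(out_csv), header, index=False)
    return out


def run_analysis(
    cohort_csv: str | Path,
    out_dir: str | Path,
    config: dict | None = None,
) -> dict:
    """Produce the full report bundle for a cohort CSV.

    ``config`` keys (all optional): ``seed`` (recorded in outputs),
    ``bonferroni_m`` (default 8), ``merge_ptbsc`` (default True),
    ``template_choices`` (default ``[("VR", "low"), ("VR", "high")]``),
    ``pairwise`` (list of [target, conditioning] pairs for probability
    panels; default a small canonical set), ``limb``/``masks``/``landmarks``
    (paths; when given, templates are also rendered as deviation-map PLYs).

    Statistics that need more sockets than the cohort provides are reported
    as missing entries in the returned summary, not raised.
    """
    config = dict(config or {})
    seed = config.get("seed", 0)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header(config, seed)
    cohort = DesignCohort.from_csv(cohort_csv)
    results: dict = {"n": len(cohort), "outputs": [], "skipped": []}

    def emit(df, name, index=True):
        _write_csv(df, out / name, header, index=index)
        results["outputs"].append(name)

    emit(cohort_summary(cohort, "overall"), "summary_overall.csv")
    for strata in ("design", "sex", "reason"):
        if strata in cohort.table.columns:
            emit(cohort_summary(cohort, strata), f"summary_by_{strata}.csv")

    # per-design rectification size distributions (quartiles per variable)
    if "design" in cohort.table.columns:
        recs = []
        for (label, var), grp in (
            cohort.table.melt(id_vars="design",
                              value_vars=list(cohort.variables().columns))
            .groupby(["design", "variable"], observed=True)
        ):
            q = grp["value"].quantile([0.25, 0.5, 0.75])
            recs.append({"design": label, "variable": var,
                         "q25": q[0.25], "median": q[0.5], "q75": q[0.75],
                         "n": len(grp)})
        emit(pd.DataFrame(recs), "design_distributions.csv", index=False)

    try:
        emit(compare_designs(cohort, m=config.get("bonferroni_m", 8),
                             merge_ptbsc=config.get("merge_ptbsc", True)),
             "design_comparison.csv")
    except RectimapError as exc:
        results["skipped"].append(f"design_comparison: {exc}")

    if len(cohort) >= 4:
        rho, p = spearman_matrix(cohort)
        emit(rho, "spearman_rho.csv")
        emit(p, "spearman_p.csv")
    else:
        results["skipped"].append("spearman_matrix: fewer than 4 profiles")

    if len(cohort) >= 5:
        cuts = fit_all_categories(cohort)
        emit(pd.DataFrame([
            {"variable": v, "cut_low_33": c.cut_low, "cut_high_67": c.cut_high,
             "exemplar_low_10": c.exemplar_low, "exemplar_mid_50": c.exemplar_mid,
             "exemplar_high_90": c.exemplar_high}
            for v, c in cuts.items()
        ]), "categories.csv", index=False)

        pairs = config.get(
            "pairwise",
            [["MP", "LP"], ["PT", "TC"], ["DE", "VR"]],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for target, conditioning in pairs:
                model = fit_conditional_nb(cohort, target, conditioning, cuts)
                mat = pd.DataFrame(
                    [conditional_probabilities(
                        model, cuts[conditioning].exemplar(cat))
                     for cat in CATEGORIES],
                    index=[f"{conditioning}_{c}" for c in CATEGORIES],
                    columns=[f"P_{target}_{c}" for c in CATEGORIES],
                )
                emit(mat, f"probabilities_{target}_given_{conditioning}.csv")

            for var, cat in config.get("template_choices",
                                       [("VR", "low"), ("VR", "high")]):
                template = generate_template(cohort, cuts, var, cat)
                tpath = out / f"template_{var}_{cat}.json"
                tpath.write_text(json.dumps(
                    {"_meta": header.lstrip("# ")} |
                    {k: {"category": c, "exemplar": s}
                     for k, (c, s) in template.items()},
                    indent=2,
                ))
                results["outputs"].append(tpath.name)
                if all(k in config for k in ("limb", "masks", "landmarks")):
                    limb = read_mesh(config["limb"])
                    masks = RegionMaskSet.from_json(config["masks"])
                    landmarks = LandmarkSet.from_json(config["landmarks"])
                    dmap = render_template_map(template, limb, masks, landmarks)
                    write_deviation_ply(limb, dmap.values,
                                        out / f"template_{var}_{cat}.ply")
                    results["outputs"].append(f"template_{var}_{cat}.ply")
    else:
        results["skipped"].append("categories/templates: fewer than 5 profiles")

    (out / "run_meta.json").write_text(json.dumps({
        "version": __version__, "config_hash": _config_hash(config),
        "seed": seed, "n": len(cohort),
        "outputs": results["outputs"], "skipped": results["skipped"],
    }, indent=2))
    return results
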