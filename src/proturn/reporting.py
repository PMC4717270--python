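"""Compartment annotation, summary surfaces, enrichment, and the pipeline.

This module assembles the analysis outputs a labeling study reports:
half-life summaries stratified by subcellular compartment and group,
counts of proteins whose half-life lengthened/shortened between groups
(with Venn overlaps across muscles), the abundance-vs-turnover correlation,
Fisher's-exact gene-set enrichment, and the end-to-end driver that runs
simulate -> deconvolve -> fit -> compare -> abundance -> summaries and
writes every table plus a machine-readable manifest.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__, abundance, io, isotopologue, kinetics, simulate

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""


# ---------------------------------------------------------------------------
# annotation


def annotate_compartments(
    protein_ids: Iterable[str],
    mito_list: Iterable[str],
    cyto_list: Iterable[str],
) -> pd.DataFrame:
    """Assign each protein to mito/cyto/other from reference identifier lists.

    Mito takes precedence on conflict (logged); unlisted proteins are
    'other'.
    """
    mito = set(mito_list)
    cyto = set(cyto_list)
    for pid in sorted(mito & cyto):
        logger.warning(
            "protein %s listed as both mito and cyto; using mito", pid
        )
    rows = []
    for pid in protein_ids:
        if pid in mito:
            comp = "mito"
        elif pid in cyto:
            comp = "cyto"
        else:
            comp = "other"
        rows.append({"protein_id": pid, "compartment": comp})
    return pd.DataFrame(rows, columns=["protein_id", "compartment"])


# ---------------------------------------------------------------------------
# summaries


def summarize_half_lives(
    kept_fits: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Median/mean half-life per stratum (total/mito/cyto x group).

    Expects fits already filtered by the long-half-life exclusion. Empty
    strata get n = 0 and undefined (NaN) medians.
    """
    df = kept_fits.merge(annotations, on="protein_id", how="left")
    df["compartment"] = df["compartment"].fillna("other")
    rows = []
    groups = sorted(df["group"].unique()) if not df.empty else []
    for stratum in ("total", "mito", "cyto"):
        sub = df if stratum == "total" else df[df["compartment"] == stratum]
        for grp in groups:
            vals = sub.loc[sub["group"] == grp, "half_life_days"]
            rows.append(
                {
                    "stratum": stratum,
                    "group": grp,
                    "median_t_half": float(vals.median()) if len(vals) else float("nan"),
                    "mean_t_half": float(vals.mean()) if len(vals) else float("nan"),
                    "n_proteins": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def classify_changes(
    comparisons: pd.DataFrame, q_threshold: float = 0.05
) -> dict:
    """Per-contrast change counts plus Venn overlaps across contrasts.

    Direction comes from the sign of the half-life change at q below the
    threshold (longer_lived / shorter_lived / unchanged; the three counts
    partition the tested set). For each pair of contrasts and direction, the
    Venn triple (only_a, both, only_b) is reported twice: restricted to
    proteins tested in both contrasts, and unrestricted.
    """
    if "q_value" not in comparisons or comparisons["q_value"].isna().all():
        comparisons = kinetics.attach_qvalues(comparisons, q_threshold=q_threshold)
    else:
        comparisons = comparisons.copy()
        significant = comparisons["q_value"] < q_threshold
        comparisons["direction"] = "unchanged"
        comparisons.loc[
            significant & (comparisons["delta_alpha"] > 0), "direction"
        ] = "longer_lived"
        comparisons.loc[
            significant & (comparisons["delta_alpha"] < 0), "direction"
        ] = "shorter_lived"
    contrasts = (
        sorted(comparisons["contrast"].unique())
        if "contrast" in comparisons
        else ["all"]
    )
    if "contrast" not in comparisons:
        comparisons = comparisons.assign(contrast="all")
    result: dict = {"per_contrast": {}, "venn": {}}
    sets: dict[tuple[str, str], set] = {}
    tested: dict[str, set] = {}
    for c in contrasts:
        sub = comparisons[comparisons["contrast"] == c]
        counts = sub["direction"].value_counts()
        result["per_contrast"][c] = {
            "longer_lived": int(counts.get("longer_lived", 0)),
            "shorter_lived": int(counts.get("shorter_lived", 0)),
            "unchanged": int(counts.get("unchanged", 0)),
            "tested": int(len(sub)),
        }
        tested[c] = set(sub["protein_id"])
        for direction in ("longer_lived", "shorter_lived"):
            sets[(c, direction)] = set(
                sub.loc[sub["direction"] == direction, "protein_id"]
            )
    for i, c1 in enumerate(contrasts):
        for c2 in contrasts[i + 1:]:
            common = tested[c1] & tested[c2]
            pair: dict = {"tested_in_both": len(common)}
            for direction in ("longer_lived", "shorter_lived"):
                s1, s2 = sets[(c1, direction)], sets[(c2, direction)]
                r1, r2 = s1 & common, s2 & common
                pair[direction] = {
                    "tested_in_both": [
                        len(r1 - r2), len(r1 & r2), len(r2 - r1)
                    ],
                    "all_tested": [len(s1 - s2), len(s1 & s2), len(s2 - s1)],
                }
            result["venn"][f"{c1}|{c2}"] = pair
    return result


def correlate_changes(
    delta_abundance: Sequence[float] | pd.Series,
    delta_half_life: Sequence[float] | pd.Series,
) -> dict:
    """OLS regression of half-life change on abundance change (log ratios)."""
    x = np.asarray(delta_abundance, dtype=float)
    y = np.asarray(delta_half_life, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("insufficient pairs: need >= 3 paired proteins")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: abundance changes are constant")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n": int(x.size),
    }


def enrich_gene_sets(
    hit_set: Iterable[str],
    universe: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    *,
    min_hits: int = 4,
    fdr_method: str = "BH",
) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment of hits within each gene set.

    Sets are intersected with the universe first; the overlap ratio is
    (hits in set) / (set size within universe); sets with fewer than
    ``min_hits`` hits are excluded from the output (and from the q-value
    family).
    """
    universe = set(universe)
    hits = set(hit_set)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not hits <= universe:
        raise ValueError("hit_set must be a subset of the universe")
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        if not members:
            continue
        a = len(hits & members)
        if a < min_hits:
            continue
        b = len(hits) - a  # hits outside the set
        c = len(members) - a  # non-hits inside the set
        d = len(universe) - len(hits) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "set_name": name,
                "n_set": len(members),
                "n_hits": a,
                "overlap_ratio": a / len(members),
                "fisher_p": float(p),
            }
        )
    out = pd.DataFrame(
        rows, columns=["set_name", "n_set", "n_hits", "overlap_ratio", "fisher_p"]
    )
    if not out.empty:
        out["q_value"] = abundance.adjust_multiplicity(
            out["fisher_p"].to_numpy(), method=fdr_method
        )
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _infer_comparisons(groups: Sequence[str]) -> list[dict]:
    """Pair young_X with old_X for every shared suffix X."""
    pairs = []
    suffixes = {
        g.split("_", 1)[1] for g in groups if g.startswith(("young_", "old_"))
    }
    for sfx in sorted(suffixes):
        a, b = f"young_{sfx}", f"old_{sfx}"
        if a in groups and b in groups:
            pairs.append({"contrast": sfx, "group_a": a, "group_b": b})
    return pairs


def run_pipeline(config: Mapping, out_dir: str | Path) -> dict:
    """Execute the full analysis and write all outputs under ``out_dir``.

    ``config`` either requests simulation (key ``simulate``) or points to
    existing input files (key ``inputs`` with envelope/abundance paths and
    optional mito_list/cyto_list/gene_sets). Returns a dict of in-memory
    results; every table is also written as TSV, with a JSON manifest and a
    run log recording seed and versions. A stage failure raises
    :class:`PipelineStageError` naming the stage; outputs written before the
    failure are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    q_threshold = float(cfg.get("q_threshold", 0.05))
    max_hl = float(cfg.get("max_half_life_days", kinetics.DEFAULT_MAX_HALF_LIFE_DAYS))
    fdr_method = str(cfg.get("fdr_method", "BH"))
    results: dict = {}
    written: dict[str, str] = {}
    log_lines = [
        f"proturn {__version__} on python {platform.python_version()}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed={seed} q_threshold={q_threshold} "
        f"max_half_life_days={max_hl} fdr_method={fdr_method}",
    ]

    def _write(name: str, df: pd.DataFrame) -> None:
        path = io.write_tsv(df, out / f"{name}.tsv")
        written[name] = path.name
        log_lines.append(f"wrote {path.name} ({len(df)} rows)")

    def _run(stage: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            log_lines.append(f"stage {stage} FAILED: {exc}")
            (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
            raise PipelineStageError(f"stage {stage!r} failed: {exc}") from exc

    # --- inputs: simulate or load -----------------------------------------
    annotations = None
    gene_sets = None
    true_p = None
    if "simulate" in cfg:
        sim_cfg = dict(cfg["simulate"])
        design_kwargs = dict(sim_cfg.pop("design", {}))
        design_kwargs.setdefault("seed", seed)
        design = simulate.StudyDesign(**design_kwargs)
        n_proteins = int(sim_cfg.pop("n_proteins", 60))
        study = _run(
            "simulate", simulate.simulate_study, n_proteins, design, **sim_cfg
        )
        envelope_df = study["envelope"]
        auc_df = study["abundance"]
        gt = study["ground_truth"]
        _write("envelope", envelope_df)
        _write("abundance", auc_df)
        _write("ground_truth", gt)
        mito = set(gt.loc[gt["compartment"] == "mito", "protein_id"])
        cyto = set(gt.loc[gt["compartment"] == "cyto", "protein_id"])
        io.write_id_list(mito, out / "mito_reference.txt")
        io.write_id_list(cyto, out / "cyto_reference.txt")
        annotations = annotate_compartments(gt["protein_id"], mito, cyto)
        if design.enrichment_rate is None and not design.enrichment_max_by_group:
            true_p = design.enrichment_max
        groups = list(design.groups)
    else:
        inputs = cfg.get("inputs") or {}
        if "envelope" not in inputs:
            raise PipelineStageError(
                "stage 'inputs' failed: config needs 'simulate' or inputs.envelope"
            )
        envelope_df = _run("inputs", io.read_envelope_tsv, inputs["envelope"])
        auc_df = (
            _run("inputs", io.read_abundance_tsv, inputs["abundance"])
            if "abundance" in inputs
            else pd.DataFrame(columns=io.ABUNDANCE_COLUMNS)
        )
        mito = io.read_id_list(inputs["mito_list"]) if "mito_list" in inputs else set()
        cyto = io.read_id_list(inputs["cyto_list"]) if "cyto_list" in inputs else set()
        annotations = annotate_compartments(
            sorted(envelope_df["protein_id"].unique()), mito, cyto
        )
        if "gene_sets" in inputs:
            gene_sets = io.read_gmt(inputs["gene_sets"])
        groups = sorted(envelope_df["group"].unique())
    results["annotations"] = annotations
    _write("compartments", annotations)

    # --- deconvolve --------------------------------------------------------
    p_cfg = cfg.get("enrichment_p", "estimate")
    if p_cfg == "true" and true_p is not None:
        p_arg: float | None = true_p
    elif isinstance(p_cfg, (int, float)):
        p_arg = float(p_cfg)
    else:
        p_arg = None  # estimate per sample
    fractions, enrichment = _run(
        "deconvolve", isotopologue.deconvolve_table, envelope_df, p_arg
    )
    results["fractions"], results["enrichment"] = fractions, enrichment
    _write("fraction_new", fractions)
    _write("enrichment", enrichment)

    # --- fit + compare ------------------------------------------------------
    fits = _run("fit", kinetics.fit_turnover_table, fractions)
    kept, excluded = kinetics.filter_fits(fits, max_hl)
    results["fits"], results["fits_excluded"] = kept, excluded
    _write("fits", fits)
    _write("fits_excluded", excluded)

    comparisons_cfg = cfg.get("comparisons") or _infer_comparisons(groups)
    comp_frames = []
    for spec_ in comparisons_cfg:
        comp_frames.append(
            _run(
                "compare",
                kinetics.compare_groups_table,
                fractions,
                spec_["group_a"],
                spec_["group_b"],
                contrast=spec_.get("contrast"),
            )
        )
    comparisons = (
        pd.concat(comp_frames, ignore_index=True) if comp_frames else pd.DataFrame()
    )
    if not comparisons.empty:
        tested_ok = set(kept["protein_id"])
        comparisons = comparisons[comparisons["protein_id"].isin(tested_ok)]
        comparisons = kinetics.attach_qvalues(
            comparisons, method=fdr_method, q_threshold=q_threshold
        )
    results["comparisons"] = comparisons
    _write("comparisons", comparisons)

    # --- abundance ----------------------------------------------------------
    abundance_frames = []
    for spec_ in comparisons_cfg:
        if auc_df.empty:
            break
        ab = _run(
            "abundance",
            abundance.abundance_table,
            auc_df[auc_df["group"].isin([spec_["group_a"], spec_["group_b"]])],
            spec_["group_a"],
            spec_["group_b"],
            fdr_method=fdr_method,
        )
        ab["contrast"] = spec_.get("contrast")
        abundance_frames.append(ab)
    abundance_results = (
        pd.concat(abundance_frames, ignore_index=True)
        if abundance_frames
        else pd.DataFrame()
    )
    results["abundance"] = abundance_results
    _write("abundance_results", abundance_results)

    if not auc_df.empty:
        auc_fracs = _run("abundance", abundance.mito_auc_fraction, auc_df, annotations)
        results["auc_fractions"] = auc_fracs
        _write("auc_fractions", auc_fracs)

    # --- summaries ----------------------------------------------------------
    summary = _run("report", summarize_half_lives, kept, annotations)
    results["half_life_summary"] = summary
    _write("half_life_summary", summary)

    if not comparisons.empty:
        changes = _run("report", classify_changes, comparisons, q_threshold)
        results["change_counts"] = changes
        (out / "change_counts.json").write_text(json.dumps(changes, indent=2))
        written["change_counts"] = "change_counts.json"

    correlations = {}
    for spec_ in comparisons_cfg:
        contrast = spec_.get("contrast")
        if abundance_results.empty or kept.empty:
            continue
        hl = kept.pivot_table(
            index="protein_id", columns="group", values="half_life_days"
        )
        ga, gb = spec_["group_a"], spec_["group_b"]
        if ga not in hl.columns or gb not in hl.columns:
            continue
        dhl = np.log2(hl[gb] / hl[ga]).rename("delta_half_life")
        ab = abundance_results[abundance_results["contrast"] == contrast]
        merged = ab.set_index("protein_id").join(dhl, how="inner")
        try:
            correlations[contrast] = correlate_changes(
                merged["log2_fc_old_over_young"], merged["delta_half_life"]
            )
        except ValueError as exc:
            correlations[contrast] = {"error": str(exc)}
    if correlations:
        results["correlations"] = correlations
        (out / "correlations.json").write_text(json.dumps(correlations, indent=2))
        written["correlations"] = "correlations.json"

    if gene_sets and not comparisons.empty:
        universe = set(comparisons["protein_id"])
        hit = set(
            comparisons.loc[comparisons["direction"] != "unchanged", "protein_id"]
        )
        enr_sets = _run(
            "report", enrich_gene_sets, hit & universe, universe, gene_sets,
            fdr_method=fdr_method,
        )
        results["gene_set_enrichment"] = enr_sets
        _write("gene_set_enrichment", enr_sets)

    manifest = {
        "package": "proturn",
        "version": __version__,
        "seed": seed,
        "parameters": {
            "q_threshold": q_threshold,
            "max_half_life_days": max_hl,
            "fdr_method": fdr_method,
        },
        "outputs": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    results["manifest"] = manifest
    return results
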