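"""First-order protein turnover kinetics and between-group rate comparison.

The percent newly synthesized of a protein pool follows
``y(t) = 100 + beta1 * exp(alpha * t)`` under first-order kinetics (for a
pool fully present at t = 0, beta1 = -100 and alpha = -k). Taking
``ln(100 - y) = ln(-beta1) + alpha * t`` linearizes the model, and the
turnover rate is the common slope of a log-linear regression across a
protein's peptides, each peptide receiving its own intercept (the blocking
factor absorbing peptide-specific offsets such as pool-enrichment or
ionization differences). The half-life is t_half = ln(2) / |alpha|.

Group comparisons (ANCOVA) fit both groups jointly with per-peptide-per-group
intercepts, a common slope, and a group x time interaction; the interaction
t-test is the reported p-value. Proteins whose half-life exceeds a threshold
(default one year) in any group are excluded from summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .abundance import adjust_multiplicity

#: observations at or above 100% newly synthesized are clipped to 100 - EPS
#: before the log transform (ln(100 - y) is undefined at y = 100)
CLIP_EPS = 0.01

DEFAULT_MAX_HALF_LIFE_DAYS = 365.0


@dataclass(frozen=True)
class TurnoverFit:
    protein_id: str | None
    group: str | None
    alpha: float
    beta1: float
    half_life_days: float
    se_alpha: float
    n_peptides: int
    n_observations: int
    r_squared: float
    excluded_flag: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class GroupComparison:
    protein_id: str | None
    group_a: str
    group_b: str
    delta_alpha: float
    p_value: float
    q_value: float = float("nan")
    direction: str = "unchanged"


def half_life_from_slope(alpha: float) -> float:
    """t_half = ln(2)/|slope|; infinite (flagged, not thrown) at slope 0."""
    if alpha == 0.0 or not math.isfinite(alpha):
        return math.inf
    return math.log(2.0) / abs(alpha)


def _log_unsynthesized(percent_new: np.ndarray) -> np.ndarray:
    y = np.asarray(percent_new, dtype=float)
    y = np.minimum(y, 100.0 - CLIP_EPS)
    return np.log(100.0 - y)


def _block_design(blocks: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Indicator matrix with one column per block, no global intercept."""
    cats = pd.Categorical(blocks)
    mat = np.zeros((len(blocks), len(cats.categories)))
    mat[np.arange(len(blocks)), cats.codes] = 1.0
    return mat, [str(c) for c in cats.categories]


def fit_turnover(
    measurements: pd.DataFrame,
    *,
    protein_id: str | None = None,
    group: str | None = None,
) -> TurnoverFit:
    """Fit one protein x group: common slope, one intercept per peptide.

    ``measurements`` needs columns peptide_id, time_days, percent_new.
    Requires at least two distinct time points; all-zero percent_new yields
    a zero slope and an infinite half-life (flagged for exclusion).
    """
    df = measurements.dropna(subset=["time_days", "percent_new"])
    times = df["time_days"].to_numpy(dtype=float)
    if df.empty or np.unique(times).size < 2:
        raise ValueError("rate not identifiable: need >= 2 distinct time points")
    z = _log_unsynthesized(df["percent_new"].to_numpy())
    blocks, _ = _block_design(df["peptide_id"])
    X = np.column_stack([blocks, times])
    res = sm.OLS(z, X).fit()
    alpha = float(res.params[-1])
    if abs(alpha) < 1e-12:  # machine-noise slope: no detectable turnover
        alpha = 0.0
    se_alpha = float(res.bse[-1])
    intercepts = res.params[:-1]
    half_life = half_life_from_slope(alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_squared = float(res.rsquared)
    fit = TurnoverFit(
        protein_id=protein_id,
        group=group,
        alpha=alpha,
        beta1=-float(np.exp(np.mean(intercepts))),
        half_life_days=half_life,
        se_alpha=se_alpha,
        n_peptides=int(df["peptide_id"].nunique()),
        n_observations=int(len(df)),
        r_squared=r_squared if np.isfinite(r_squared) else 1.0,
    )
    if not math.isfinite(half_life):
        fit = replace(
            fit, excluded_flag=True, exclusion_reason="no detectable turnover"
        )
    return fit


def fit_turnover_table(fractions: pd.DataFrame, min_timepoints: int = 2) -> pd.DataFrame:
    """One TurnoverFit row per protein x group from a fraction-new table."""
    rows = []
    for (prot, grp), df in fractions.groupby(["protein_id", "group"], sort=True):
        if df["time_days"].nunique() < min_timepoints:
            continue
        fit = fit_turnover(df, protein_id=str(prot), group=str(grp))
        rows.append(fit.__dict__)
    return pd.DataFrame(rows)


def compare_groups_ancova(
    measurements_a: pd.DataFrame,
    measurements_b: pd.DataFrame,
    *,
    group_a: str = "A",
    group_b: str = "B",
    protein_id: str | None = None,
) -> GroupComparison:
    """ANCOVA on the log-linear model: is the turnover slope group-dependent?

    Joint fit of ln(100 - y) with an intercept per peptide-within-group
    (blocking), a common time slope, and a time x group interaction whose
    coefficient is alpha_B - alpha_A. The interaction t-test p-value is
    reported; q-values are attached later over the whole protein family.
    """
    for df in (measurements_a, measurements_b):
        if df.empty or df["time_days"].nunique() < 2:
            raise ValueError("not testable: each group needs >= 2 distinct time points")
    a = measurements_a.assign(_grp=group_a)
    b = measurements_b.assign(_grp=group_b)
    df = pd.concat([a, b], ignore_index=True)
    z = _log_unsynthesized(df["percent_new"].to_numpy())
    times = df["time_days"].to_numpy(dtype=float)
    is_b = (df["_grp"] == group_b).to_numpy(dtype=float)
    blocks, _ = _block_design(df["peptide_id"].astype(str) + "|" + df["_grp"])
    X = np.column_stack([blocks, times, times * is_b])
    res = sm.OLS(z, X).fit()
    delta = float(res.params[-1])
    se = float(res.bse[-1])
    noiseless = res.ssr <= 1e-16 * max(float(z @ z), 1.0)
    if se == 0.0 or not np.isfinite(se) or noiseless:
        # noiseless limit: residuals at machine precision make the t-test
        # meaningless; report the exact answer instead
        p = 1.0 if abs(delta) < 1e-10 else 0.0
    else:
        p = float(res.pvalues[-1])
    return GroupComparison(
        protein_id=protein_id, group_a=group_a, group_b=group_b,
        delta_alpha=delta, p_value=p,
    )


def compare_groups_table(
    fractions: pd.DataFrame,
    group_a: str,
    group_b: str,
    *,
    contrast: str | None = None,
) -> pd.DataFrame:
    """Per-protein ANCOVA for every protein testable in both groups."""
    rows = []
    for prot, df in fractions.groupby("protein_id", sort=True):
        da = df[df["group"] == group_a]
        db = df[df["group"] == group_b]
        if da["time_days"].nunique() < 2 or db["time_days"].nunique() < 2:
            continue
        cmp_ = compare_groups_ancova(
            da, db, group_a=group_a, group_b=group_b, protein_id=str(prot)
        )
        row = cmp_.__dict__.copy()
        row["contrast"] = contrast or f"{group_a}_vs_{group_b}"
        rows.append(row)
    return pd.DataFrame(rows)


def attach_qvalues(
    comparisons: pd.DataFrame,
    method: str = "BH",
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Add q_value and half-life-change direction labels to a comparison table.

    Multiplicity is adjusted within each contrast (the per-muscle protein
    family). A positive delta_alpha (slope less negative in group B) means a
    longer half-life in group B.
    """
    out = comparisons.copy()
    if out.empty:
        return out
    groups = out.groupby("contrast")["p_value"] if "contrast" in out else [(None, out["p_value"])]
    q = pd.Series(np.nan, index=out.index)
    for _, pvals in groups:
        q.loc[pvals.index] = adjust_multiplicity(pvals.to_numpy(), method=method)
    out["q_value"] = q
    significant = out["q_value"] < q_threshold
    out["direction"] = "unchanged"
    out.loc[significant & (out["delta_alpha"] > 0), "direction"] = "longer_lived"
    out.loc[significant & (out["delta_alpha"] < 0), "direction"] = "shorter_lived"
    return out


def filter_fits(
    fits: pd.DataFrame,
    max_half_life_days: float = DEFAULT_MAX_HALF_LIFE_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split fits into (kept, excluded) by the long-half-life rule.

    A protein whose half-life exceeds the threshold in ANY group is excluded
    wholesale (all of its rows). Idempotent and order-independent.
    """
    if fits.empty:
        return fits.copy(), fits.copy()
    over = fits["half_life_days"] > max_half_life_days
    bad_proteins = set(fits.loc[over | fits["excluded_flag"], "protein_id"])
    is_bad = fits["protein_id"].isin(bad_proteins)
    kept = fits[~is_bad].copy()
    excluded = fits[is_bad].copy()
    excluded["excluded_flag"] = True
    reason = f"half-life > {max_half_life_days:g} d in at least one group"
    excluded.loc[excluded["exclusion_reason"] == "", "exclusion_reason"] = reason
    return kept, excluded
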