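"""Differential protein abundance from peptide areas.

Per protein, peptide AUCs are modeled on the log2 scale with one intercept
per peptide (blocking) and a group effect — the moderated-free analogue of a
two-sample t-test that shares the group contrast across peptides while
absorbing peptide-specific ionization efficiency. P-values across the
protein family are adjusted for multiplicity with Benjamini-Hochberg
q-values by default (Storey's pi0-estimated q-values optionally).

Also provides the mitochondrial AUC-fraction content estimate: the summed
area of annotated mitochondrial proteins relative to the total area per
sample, compared between ages with a two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class AbundanceResult:
    protein_id: str | None
    log2_fc_old_over_young: float
    t_statistic: float
    p_value: float
    q_value: float = float("nan")
    n_peptides: int = 0


def protein_fold_change(
    auc_rows: pd.DataFrame,
    group_a: str,
    group_b: str,
    *,
    protein_id: str | None = None,
) -> AbundanceResult:
    """Group-b-over-group-a log2 fold change for one protein.

    ``auc_rows`` needs columns peptide_id, group, auc (> 0). Missing peptide
    observations are dropped per-observation. The reported fold change is
    the group coefficient of log2(AUC) ~ peptide + group; scaling any single
    peptide's AUCs by a constant is absorbed by its block intercept.
    """
    df = auc_rows[auc_rows["group"].isin([group_a, group_b])].copy()
    df = df[np.isfinite(df["auc"]) & (df["auc"] > 0)]
    if df.empty or df["group"].nunique() < 2:
        raise ValueError(
            f"contrast not estimable: need observations in both "
            f"{group_a!r} and {group_b!r}"
        )
    y = np.log2(df["auc"].to_numpy(dtype=float))
    cats = pd.Categorical(df["peptide_id"])
    blocks = np.zeros((len(df), len(cats.categories)))
    blocks[np.arange(len(df)), cats.codes] = 1.0
    is_b = (df["group"] == group_b).to_numpy(dtype=float)
    X = np.column_stack([blocks, is_b])
    res = sm.OLS(y, X).fit()
    coef = float(res.params[-1])
    se = float(res.bse[-1])
    if abs(coef) < 1e-12:
        coef = 0.0
    # residuals at machine precision: t-test is meaningless, report exactly
    if se == 0.0 or not np.isfinite(se) or res.ssr <= 1e-16 * max(float(y @ y), 1.0):
        tstat = 0.0 if abs(coef) < 1e-12 else math.copysign(math.inf, coef)
        p = 1.0 if abs(coef) < 1e-12 else 0.0
    else:
        tstat = float(res.tvalues[-1])
        p = float(res.pvalues[-1])
    return AbundanceResult(
        protein_id=protein_id,
        log2_fc_old_over_young=coef,
        t_statistic=tstat,
        p_value=p,
        n_peptides=int(df["peptide_id"].nunique()),
    )


def abundance_table(
    auc_df: pd.DataFrame,
    group_a: str,
    group_b: str,
    *,
    fdr_method: str = "BH",
) -> pd.DataFrame:
    """Per-protein differential abundance with q-values over the family."""
    rows = []
    for prot, df in auc_df.groupby("protein_id", sort=True):
        sub = df[df["group"].isin([group_a, group_b]) & (df["auc"] > 0)]
        if sub.empty or sub["group"].nunique() < 2:
            continue
        res = protein_fold_change(sub, group_a, group_b, protein_id=str(prot))
        rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    if not out.empty:
        ok = np.isfinite(out["p_value"])
        q = np.full(len(out), np.nan)
        q[ok.to_numpy()] = adjust_multiplicity(
            out.loc[ok, "p_value"].to_numpy(), method=fdr_method
        )
        out["q_value"] = q
    return out


def _storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    """Storey's null-proportion estimate at a single lambda."""
    pi0 = np.mean(p > lam) / (1.0 - lam)
    return float(min(1.0, max(pi0, 0.0)))


def adjust_multiplicity(
    p_values: Sequence[float] | np.ndarray, method: str = "BH"
) -> np.ndarray:
    """q-values for a family of p-values, order-preserving.

    ``"BH"`` is the Benjamini-Hochberg step-up adjustment; ``"storey"``
    multiplies BH by Storey's estimated null proportion pi0 (lambda = 0.5),
    a closer analogue of the Bioconductor q-value package.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    if method.upper() == "BH":
        return bh
    if method.lower() == "storey":
        return np.minimum(_storey_pi0(p) * bh, 1.0)
    raise ValueError(f"unknown multiplicity method {method!r}")


def mito_auc_fraction(
    auc_df: pd.DataFrame, compartments: Mapping[str, str] | pd.DataFrame
) -> pd.DataFrame:
    """Mitochondrial share of total peptide area, per sample.

    Proteins absent from the annotation count toward the total only. Raises
    on a sample whose total area is zero.
    """
    if isinstance(compartments, pd.DataFrame):
        compartments = dict(
            zip(compartments["protein_id"], compartments["compartment"])
        )
    df = auc_df.copy()
    df["_is_mito"] = df["protein_id"].map(compartments).eq("mito")
    rows = []
    for sample_id, sdf in df.groupby("sample_id", sort=True):
        total = float(sdf["auc"].sum())
        if total <= 0:
            raise ValueError(f"empty sample: {sample_id} has zero total AUC")
        mito = float(sdf.loc[sdf["_is_mito"], "auc"].sum())
        rows.append(
            {
                "sample_id": sample_id,
                "group": sdf["group"].iloc[0],
                "mito_auc": mito,
                "total_auc": total,
                "fraction": mito / total,
            }
        )
    return pd.DataFrame(rows)


def compare_auc_fractions(
    fractions: pd.DataFrame, group_a: str, group_b: str
) -> dict:
    """Two-sided two-sample t-test of mito AUC fraction between groups."""
    a = fractions.loc[fractions["group"] == group_a, "fraction"].to_numpy()
    b = fractions.loc[fractions["group"] == group_b, "fraction"].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 samples per group for the t-test")
    t, p = stats.ttest_ind(b, a)
    return {
        "group_a": group_a,
        "group_b": group_b,
        "mean_fraction_a": float(a.mean()),
        "mean_fraction_b": float(b.mean()),
        "t_statistic": float(t),
        "p_value": float(p),
    }
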