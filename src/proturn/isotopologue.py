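"""Peptide isotopologue envelope model and its inversion.

A peptide with ``n_leu`` leucines measured after a diet switch to heavy
leucine occupies label-count channels 0..n_leu. Pre-existing molecules sit
entirely in channel 0; molecules synthesized after the switch draw each
leucine independently from the precursor pool, which is heavy with
probability ``p`` (the pool enrichment), so their channel distribution is
Binomial(n_leu, p). The observed envelope is the two-component mixture

    m(f, p) = (1 - f) * e0 + f * Binomial(n_leu, p),

where ``f`` is the fraction of the peptide pool that is newly synthesized
(x100 = percent newly synthesized). This module fits ``f`` per envelope by
constrained least squares on the normalized envelope, estimates ``p`` per
sample by profiling ``f`` out of a pooled objective over multi-leucine
peptides (peptides with a single leucine confound f and p: only their
product is identified), and provides the 1-D retention-coordinate regression
used to transfer peptides quantified in one run into a matched window of
another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


@dataclass(frozen=True)
class LabelEnvelope:
    """Per-peptide, per-sample intensity vector over label-count channels."""

    peptide_id: str
    sample_id: str
    n_leu: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if self.n_leu < 0:
            raise ValueError("n_leu must be >= 0")
        if arr.shape != (self.n_leu + 1,):
            raise ValueError("intensities must have length n_leu + 1")
        if (arr < 0).any():
            raise ValueError("intensities must be nonnegative")

    def normalized(self) -> np.ndarray:
        total = self.intensities.sum()
        if total <= 0:
            raise ValueError("empty envelope: zero total intensity")
        return self.intensities / total


@dataclass(frozen=True)
class EnrichmentEstimate:
    sample_id: str | None
    p_hat: float
    n_peptides_used: int
    objective_value: float


@dataclass(frozen=True)
class FractionNew:
    peptide_id: str | None
    sample_id: str | None
    f_hat: float
    residual_norm: float


@dataclass(frozen=True)
class RunAlignment:
    """OLS line mapping one run's retention coordinate onto another's."""

    slope: float
    intercept: float
    residual_sd: float
    window_halfwidth: float

    def transfer(self, coord: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(coord) + self.intercept


# ---------------------------------------------------------------------------
# forward model


def channel_distribution(n_leu: int, p: float) -> np.ndarray:
    """Binomial label-count distribution of a newly synthesized peptide."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if n_leu < 0:
        raise ValueError("n_leu must be >= 0")
    k = np.arange(n_leu + 1)
    # binomial pmf via log-gamma; exact at the p=0/1 boundaries
    if p == 0.0:
        out = np.zeros(n_leu + 1)
        out[0] = 1.0
        return out
    if p == 1.0:
        out = np.zeros(n_leu + 1)
        out[-1] = 1.0
        return out
    logpmf = (
        special.gammaln(n_leu + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n_leu - k + 1)
        + k * math.log(p)
        + (n_leu - k) * math.log1p(-p)
    )
    return np.exp(logpmf)


def mixture_envelope(f: float, n_leu: int, p: float) -> np.ndarray:
    """(1-f) point mass on channel 0 plus f x Binomial(n_leu, p)."""
    if not (0.0 <= f <= 1.0):
        raise ValueError("f must be in [0, 1]")
    mix = f * channel_distribution(n_leu, p)
    mix[0] += 1.0 - f
    return mix


# ---------------------------------------------------------------------------
# inversion


def _profile_fraction(x: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Least-squares f in [0,1] for normalized envelope x and new-channel dist b.

    The model is linear in f: m(f) = e0 + f (b - e0), so the constrained
    optimum is the projection coefficient clipped to [0, 1].
    """
    d = b.copy()
    d[0] -= 1.0
    denom = float(d @ d)
    if denom == 0.0:
        f = 0.0
    else:
        r = x.copy()
        r[0] -= 1.0
        f = min(1.0, max(0.0, float(r @ d) / denom))
    resid = x - f * b
    resid[0] -= 1.0 - f
    return f, float(np.linalg.norm(resid))


def deconvolve_fraction_new(
    envelope: LabelEnvelope | np.ndarray | Sequence[float],
    p: float,
    *,
    peptide_id: str | None = None,
    sample_id: str | None = None,
) -> FractionNew:
    """Fraction newly synthesized from one envelope at known pool enrichment p.

    Constrained least squares on the normalized envelope; exact (zero
    residual) whenever the envelope lies on the mixture manifold. Raises for
    uninformative peptides (n_leu = 0, no label channels) and empty
    envelopes.
    """
    if not isinstance(envelope, LabelEnvelope):
        arr = np.asarray(envelope, dtype=float)
        envelope = LabelEnvelope(
            peptide_id=peptide_id or "", sample_id=sample_id or "",
            n_leu=arr.size - 1, intensities=arr,
        )
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    if envelope.n_leu == 0:
        raise ValueError("uninformative peptide: n_leu = 0 carries no label signal")
    x = envelope.normalized()  # raises "empty envelope" on zero total
    b = channel_distribution(envelope.n_leu, p)
    f, resid = _profile_fraction(x, b)
    return FractionNew(
        peptide_id=peptide_id or envelope.peptide_id or None,
        sample_id=sample_id or envelope.sample_id or None,
        f_hat=f,
        residual_norm=resid,
    )


def _profile_fraction_rows(X: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`_profile_fraction` over rows of normalized envelopes."""
    d = b.copy()
    d[0] -= 1.0
    denom = float(d @ d)
    R = X.copy()
    R[:, 0] -= 1.0
    if denom == 0.0:
        f = np.zeros(X.shape[0])
    else:
        f = np.clip(R @ d / denom, 0.0, 1.0)
    resid = R - f[:, None] * d
    return f, np.sqrt((resid * resid).sum(axis=1))


def _enrichment_objective(p: float, grouped: Mapping[int, np.ndarray]) -> float:
    total = 0.0
    for n, X in grouped.items():
        b = channel_distribution(int(n), p)
        _, rn = _profile_fraction_rows(X, b)
        total += float(rn @ rn)
    return total


def estimate_enrichment(
    envelopes: Iterable[LabelEnvelope | tuple[int, Sequence[float]]],
    min_leu: int = 2,
    *,
    sample_id: str | None = None,
    grid_size: int = 101,
) -> EnrichmentEstimate:
    """Precursor-pool enrichment p for one sample.

    Minimizes the pooled least-squares objective over p in [0, 1], profiling
    each peptide's fraction-new out at fixed p. Only peptides with at least
    ``min_leu`` leucines contribute (envelope shape beyond the all-or-none
    channels is what identifies p). Deterministic: coarse grid scan followed
    by bounded Brent refinement around the best grid point.
    """
    by_n: dict[int, list[np.ndarray]] = {}
    count = 0
    for env in envelopes:
        if isinstance(env, LabelEnvelope):
            n, inten = env.n_leu, env.intensities
        else:
            n, inten = int(env[0]), np.asarray(env[1], dtype=float)
        if n < min_leu:
            continue
        total = inten.sum()
        if total <= 0:
            continue
        by_n.setdefault(int(n), []).append(inten / total)
        count += 1
    if not by_n:
        raise ValueError(
            "enrichment not identifiable: no peptides with n_leu >= "
            f"{min_leu} and positive intensity"
        )
    grouped = {n: np.vstack(rows) for n, rows in by_n.items()}
    grid = np.linspace(0.0, 1.0, grid_size)
    vals = [_enrichment_objective(p, grouped) for p in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            _enrichment_objective,
            bounds=(lo, hi),
            args=(grouped,),
            method="bounded",
            options={"xatol": 1e-10},
        )
        p_hat, obj = float(res.x), float(res.fun)
        if vals[i] < obj:  # keep the grid point if refinement didn't help
            p_hat, obj = float(grid[i]), float(vals[i])
    else:  # pragma: no cover - degenerate single-point grid
        p_hat, obj = float(grid[i]), float(vals[i])
    return EnrichmentEstimate(
        sample_id=sample_id, p_hat=p_hat, n_peptides_used=count,
        objective_value=obj,
    )


# ---------------------------------------------------------------------------
# table-level drivers


def _sample_matrices(sample_df: pd.DataFrame):
    """Wide envelopes for one sample, grouped by leucine count.

    Yields (n_leu, peptide_ids, meta frame, intensity matrix) with one row
    per peptide and columns 0..n_leu; missing channels are zero.
    """
    wide = sample_df.pivot_table(
        index="peptide_id", columns="channel", values="intensity", aggfunc="first"
    ).fillna(0.0)
    meta = sample_df.drop_duplicates("peptide_id").set_index("peptide_id")
    for n, ids in meta.groupby("n_leu").groups.items():
        n = int(n)
        cols = [c for c in range(n + 1) if c in wide.columns]
        X = np.zeros((len(ids), n + 1))
        X[:, cols] = wide.loc[ids, cols].to_numpy(dtype=float)
        yield n, np.asarray(ids), meta.loc[ids], X


def estimate_enrichment_table(
    envelope_df: pd.DataFrame, min_leu: int = 2
) -> pd.DataFrame:
    """Per-sample enrichment estimates from a long-format envelope table."""
    rows = []
    for sample_id, sdf in envelope_df.groupby("sample_id", sort=True):
        envs: list[tuple[int, np.ndarray]] = []
        for n, _ids, _meta, X in _sample_matrices(sdf):
            envs.extend((n, x) for x in X)
        est = estimate_enrichment(envs, min_leu=min_leu, sample_id=str(sample_id))
        rows.append(
            {
                "sample_id": sample_id,
                "group": sdf["group"].iloc[0],
                "p_hat": est.p_hat,
                "n_peptides_used": est.n_peptides_used,
                "objective_value": est.objective_value,
            }
        )
    return pd.DataFrame(rows)


def deconvolve_table(
    envelope_df: pd.DataFrame,
    p: float | Mapping[str, float] | None = None,
    *,
    min_leu_for_enrichment: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction-new table from a long-format envelope table.

    ``p`` may be a single known enrichment, a per-sample mapping, or ``None``
    to estimate it per sample from multi-leucine peptides. Peptides without
    leucines are uninformative and silently excluded. Returns
    (fraction-new table with ``percent_new`` in 0-100, enrichment table).
    """
    if p is None:
        enr = estimate_enrichment_table(envelope_df, min_leu=min_leu_for_enrichment)
        p_by_sample = dict(zip(enr["sample_id"], enr["p_hat"]))
    elif isinstance(p, Mapping):
        p_by_sample = dict(p)
        enr = pd.DataFrame(
            {"sample_id": list(p_by_sample), "p_hat": list(p_by_sample.values())}
        )
    else:
        p_by_sample = None
        enr = pd.DataFrame(
            {"sample_id": sorted(envelope_df["sample_id"].unique()), "p_hat": float(p)}
        )
    frames = []
    for sample_id, sdf in envelope_df.groupby("sample_id", sort=True):
        p_use = p_by_sample[sample_id] if p_by_sample is not None else float(p)
        for n_leu, ids, meta, X in _sample_matrices(sdf):
            if n_leu == 0:
                continue  # uninformative peptides carry no label signal
            totals = X.sum(axis=1)
            ok = totals > 0
            if not ok.any():
                continue
            Xn = X[ok] / totals[ok, None]
            b = channel_distribution(n_leu, p_use)
            f, rn = _profile_fraction_rows(Xn, b)
            frames.append(
                pd.DataFrame(
                    {
                        "peptide_id": ids[ok],
                        "protein_id": meta.loc[ok, "protein_id"].to_numpy(),
                        "sample_id": sample_id,
                        "group": meta.loc[ok, "group"].to_numpy(),
                        "time_days": meta.loc[ok, "time_days"].to_numpy(dtype=float),
                        "percent_new": 100.0 * f,
                        "residual_norm": rn,
                        "p_hat_used": p_use,
                    }
                )
            )
    cols = [
        "peptide_id", "protein_id", "sample_id", "group", "time_days",
        "percent_new", "residual_norm", "p_hat_used",
    ]
    if not frames:
        return pd.DataFrame(columns=cols), enr
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["sample_id", "peptide_id"], kind="stable", ignore_index=True
    )[cols], enr


# ---------------------------------------------------------------------------
# cross-run alignment


def align_runs(
    shared_rt_pairs: Sequence[tuple[float, float]] | np.ndarray,
    window_k: float = 3.0,
) -> RunAlignment:
    """OLS retention-coordinate map between two runs from shared peptides.

    The fitted line transfers a peptide quantified in run A to its expected
    coordinate in run B; ``window_halfwidth`` (window_k x residual SD) bounds
    the search window for the matched chromatographic peak.
    """
    arr = np.asarray(shared_rt_pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("insufficient anchors: need >= 3 shared (rt_a, rt_b) pairs")
    res = stats.linregress(arr[:, 0], arr[:, 1])
    pred = res.slope * arr[:, 0] + res.intercept
    resid = arr[:, 1] - pred
    dof = max(arr.shape[0] - 2, 1)
    residual_sd = float(np.sqrt((resid @ resid) / dof))
    return RunAlignment(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=residual_sd,
        window_halfwidth=window_k * residual_sd,
    )
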