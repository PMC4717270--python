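"""Synthetic heavy-label (2H3-leucine) proteomics study generator.

Emulates a diet-switch metabolic labeling experiment: animals are moved to a
fully deuterated-leucine diet, and cohorts are sacrificed at fixed labeling
times. For every protein with first-order turnover rate k = ln(2)/t_half, the
fraction of molecules synthesized after the switch is

    f(t) = 1 - exp(-k * t),

and newly synthesized peptide molecules draw each of their leucines from a
precursor pool that is heavy with probability p(t) (the pool enrichment).
Measured peptide isotopologue envelopes are therefore mixtures of a fully
unlabeled component (pre-existing molecules) and a binomially labeled one
(new molecules); see :mod:`proturn.isotopologue` for the forward model.

Everything downstream of the simulator is validated against the ground truth
this module records: true half-lives, compartments, and abundance effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .isotopologue import channel_distribution

COMPARTMENTS = ("mito", "cyto", "other")

#: Compartment mix loosely matching a mitochondria-enriched muscle fraction
#: (~1/3 mitochondrial, ~1/5 cytosolic, remainder other/membrane).
DEFAULT_COMPARTMENT_PROPS = {"mito": 0.35, "cyto": 0.21, "other": 0.44}

#: Default half-life law: log-normal with median 22 days and log-sd 1.0,
#: spanning a few days to beyond a year (long-tail proteins exist and are
#: subject to the >1-year exclusion downstream).
DEFAULT_HALF_LIFE_LAW = {"dist": "lognormal", "median": 22.0, "sigma": 1.0}

DEFAULT_ABUNDANCE_LAW = {"dist": "lognormal", "median": 1e6, "sigma": 1.0}
DEFAULT_PEPTIDES_LAW = {"dist": "poisson", "mean": 4.0, "min": 1}
#: Leucine is a common residue (~10% of positions); a tryptic peptide of
#: typical length carries 0-4 leucines.
DEFAULT_LEU_LAW = {"dist": "poisson", "mean": 1.5, "min": 0}


# ---------------------------------------------------------------------------
# ground-truth containers


@dataclass(frozen=True)
class GroundTruthProtein:
    """True (simulated) state of one protein.

    ``old_half_life_multiplier`` scales the half-life in aged-group samples
    (values > 1 mean the protein becomes longer lived with age);
    ``group_log2_effect`` is the old/young log2 abundance fold change.
    """

    protein_id: str
    compartment: str
    true_half_life: float
    base_abundance: float
    group_log2_effect: float = 0.0
    old_half_life_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.true_half_life <= 0:
            raise ValueError("true_half_life must be > 0")
        if self.base_abundance <= 0:
            raise ValueError("base_abundance must be > 0")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")

    def half_life_in(self, aged: bool) -> float:
        return self.true_half_life * (self.old_half_life_multiplier if aged else 1.0)


@dataclass(frozen=True)
class GroundTruthPeptide:
    """One simulated peptide; maps to exactly one parent protein."""

    peptide_id: str
    protein_id: str
    n_leu: int
    rt_true: float
    ionization_factor: float

    def __post_init__(self) -> None:
        if self.n_leu < 0:
            raise ValueError("n_leu must be >= 0")
        if self.ionization_factor <= 0:
            raise ValueError("ionization_factor must be > 0")


@dataclass(frozen=True)
class StudyDesign:
    """Labeling-study layout and noise model.

    Defaults mirror a four-time-point diet-switch design: sacrifice at
    3, 7, 12 and 17 days, four animals per group, and young/old cohorts for
    each of two muscles. ``enrichment_rate`` of ``None`` means the precursor
    pool reaches ``enrichment_max`` immediately (constant p); otherwise
    p(t) = enrichment_max * (1 - exp(-enrichment_rate * t)).
    """

    time_points: tuple = (3.0, 7.0, 12.0, 17.0)
    n_animals_per_group: int = 4
    groups: tuple = ("young_EDL", "old_EDL", "young_SOL", "old_SOL")
    enrichment_max: float = 0.5
    enrichment_rate: float | None = None
    noise_cv: float = 0.15
    missing_rate: float = 0.1
    seed: int = 0
    #: optional per-group override of enrichment_max, e.g. to give aged
    #: animals a different achieved pool enrichment
    enrichment_max_by_group: Mapping[str, float] | None = None
    #: group labels treated as "aged"; by default any label whose first
    #: underscore-separated token is "old"
    aged_groups: tuple | None = None

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points)
        if not tp or any(t <= 0 for t in tp) or any(
            b <= a for a, b in zip(tp, tp[1:])
        ):
            raise ValueError("time_points must be strictly increasing and positive")
        if not (0.0 < self.enrichment_max <= 1.0):
            raise ValueError("enrichment_max must be in (0, 1]")
        if self.enrichment_rate is not None and self.enrichment_rate < 0:
            raise ValueError("enrichment_rate must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_animals_per_group < 1:
            raise ValueError("n_animals_per_group must be >= 1")

    def is_aged(self, group: str) -> bool:
        if self.aged_groups is not None:
            return group in self.aged_groups
        return group.split("_")[0] == "old"

    def enrichment_at(self, group: str, t: float) -> float:
        pmax = self.enrichment_max
        if self.enrichment_max_by_group and group in self.enrichment_max_by_group:
            pmax = self.enrichment_max_by_group[group]
        if self.enrichment_rate is None:
            return pmax
        return pmax * (1.0 - math.exp(-self.enrichment_rate * t))

    def samples(self) -> list[tuple[str, str, float, int]]:
        """(sample_id, group, time_days, animal) for every sample."""
        out = []
        for g in self.groups:
            for t in self.time_points:
                for a in range(1, self.n_animals_per_group + 1):
                    out.append((f"{g}_d{t:g}_a{a}", g, float(t), a))
        return out


# ---------------------------------------------------------------------------
# distribution laws


def _draw(law: Mapping, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample from a small declarative distribution spec.

    Supported: ``{"dist": "point", "value": v}``,
    ``{"dist": "lognormal", "median": m, "sigma": s}``,
    ``{"dist": "poisson", "mean": m, "min": k}`` (truncated from below),
    ``{"dist": "uniform", "low": a, "high": b}``.
    """
    kind = law.get("dist")
    if kind == "point":
        return np.full(size, float(law["value"]))
    if kind == "lognormal":
        return law["median"] * np.exp(law["sigma"] * rng.standard_normal(size))
    if kind == "uniform":
        return rng.uniform(law["low"], law["high"], size)
    if kind == "poisson":
        lo = int(law.get("min", 0))
        draws = rng.poisson(law["mean"], size)
        bad = draws < lo
        while bad.any():  # rejection sampling for the truncation
            draws[bad] = rng.poisson(law["mean"], int(bad.sum()))
            bad = draws < lo
        return draws
    raise ValueError(f"unknown distribution law {law!r}")


# ---------------------------------------------------------------------------
# generators


def simulate_ground_truth(
    n_proteins: int,
    half_life_law: Mapping | None = None,
    compartment_props: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    abundance_law: Mapping | None = None,
    effect_law_by_compartment: Mapping[str, Mapping] | None = None,
    old_multiplier_law: Mapping | None = None,
    half_life_law_by_compartment: Mapping[str, Mapping] | None = None,
) -> list[GroundTruthProtein]:
    """Draw the ground-truth protein population.

    ``effect_law_by_compartment`` assigns old/young log2 abundance effects per
    compartment (default: no effect); ``old_multiplier_law`` draws per-protein
    aged-group half-life multipliers (default: point mass at 1, i.e. no change
    with age); ``half_life_law_by_compartment`` overrides the half-life law
    for specific compartments (e.g. longer-lived mitochondrial proteins).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1 (empty study requested)")
    half_life_law = half_life_law or DEFAULT_HALF_LIFE_LAW
    abundance_law = abundance_law or DEFAULT_ABUNDANCE_LAW
    props = dict(compartment_props or DEFAULT_COMPARTMENT_PROPS)
    if set(props) - set(COMPARTMENTS):
        raise ValueError(f"unknown compartments {set(props) - set(COMPARTMENTS)}")
    vals = np.array([props.get(c, 0.0) for c in COMPARTMENTS], dtype=float)
    if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-8:
        raise ValueError("compartment proportions must be nonnegative and sum to 1")

    rng = np.random.default_rng(seed)
    comps = rng.choice(COMPARTMENTS, size=n_proteins, p=vals / vals.sum())
    t_half = _draw(half_life_law, n_proteins, rng)
    if half_life_law_by_compartment:
        for comp, law in half_life_law_by_compartment.items():
            mask = comps == comp
            t_half[mask] = _draw(law, int(mask.sum()), rng)
    abund = _draw(abundance_law, n_proteins, rng)
    mult = (
        _draw(old_multiplier_law, n_proteins, rng)
        if old_multiplier_law
        else np.ones(n_proteins)
    )
    effects = np.zeros(n_proteins)
    if effect_law_by_compartment:
        for comp, law in effect_law_by_compartment.items():
            mask = comps == comp
            effects[mask] = _draw(law, int(mask.sum()), rng)

    width = len(str(n_proteins))
    return [
        GroundTruthProtein(
            protein_id=f"P{i + 1:0{width}d}",
            compartment=str(comps[i]),
            true_half_life=float(t_half[i]),
            base_abundance=float(abund[i]),
            group_log2_effect=float(effects[i]),
            old_half_life_multiplier=float(mult[i]),
        )
        for i in range(n_proteins)
    ]


def generate_peptides(
    proteins: Sequence[GroundTruthProtein],
    peptides_per_protein_law: Mapping | None = None,
    leu_count_law: Mapping | None = None,
    seed: int = 0,
) -> list[GroundTruthPeptide]:
    """Draw peptides; each maps to exactly one protein (unique-mapping rule)."""
    if not proteins:
        raise ValueError("proteins must be non-empty")
    pep_law = peptides_per_protein_law or DEFAULT_PEPTIDES_LAW
    leu_law = leu_count_law or DEFAULT_LEU_LAW
    rng = np.random.default_rng(seed)

    n_pep = _draw(pep_law, len(proteins), rng).astype(int)
    peptides: list[GroundTruthPeptide] = []
    for prot, k in zip(proteins, n_pep):
        n_leu = _draw(leu_law, int(k), rng).astype(int)
        rts = rng.uniform(10.0, 110.0, int(k))
        ion = np.exp(rng.standard_normal(int(k)))
        for j in range(int(k)):
            peptides.append(
                GroundTruthPeptide(
                    peptide_id=f"{prot.protein_id}_pep{j + 1}",
                    protein_id=prot.protein_id,
                    n_leu=int(n_leu[j]),
                    rt_true=float(rts[j]),
                    ionization_factor=float(ion[j]),
                )
            )
    return peptides


def _lognormal_noise(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(size) - 0.5 * sigma * sigma)


def simulate_timecourse(
    proteins: Sequence[GroundTruthProtein],
    peptides: Sequence[GroundTruthPeptide],
    design: StudyDesign,
) -> pd.DataFrame:
    """Forward-simulate long-format label envelopes for every peptide/sample.

    Each peptide's envelope over 0..n_leu heavy-leucine channels is
    ``total * [(1-f) e0 + f Binomial(n_leu, p)]`` with multiplicative
    log-normal channel noise (design.noise_cv) and whole-envelope
    missingness completely at random (design.missing_rate).
    """
    by_protein = {p.protein_id: p for p in proteins}
    for pep in peptides:
        if pep.protein_id not in by_protein:
            raise ValueError(f"peptide {pep.peptide_id} maps to unknown protein")

    rng = np.random.default_rng(design.seed)
    pep_nleu = np.array([p.n_leu for p in peptides])
    pep_total = np.array(
        [by_protein[p.protein_id].base_abundance * p.ionization_factor for p in peptides]
    )
    pep_rt = np.array([p.rt_true for p in peptides])

    pep_ids = np.array([p.peptide_id for p in peptides])
    pep_prot = np.array([p.protein_id for p in peptides])
    frames = []
    for sample_id, group, t, _animal in design.samples():
        aged = design.is_aged(group)
        p_enr = design.enrichment_at(group, t)
        f_by_protein = {
            pid: 1.0 - math.exp(-math.log(2.0) / prot.half_life_in(aged) * t)
            for pid, prot in by_protein.items()
        }
        f_pep = np.array([f_by_protein[pid] for pid in pep_prot])
        present = rng.random(len(peptides)) >= design.missing_rate
        # small per-sample RT drift so cross-run alignment has work to do
        rt_obs = pep_rt * (1.0 + rng.normal(0, 0.002)) + rng.normal(0, 0.5)
        for n in np.unique(pep_nleu):
            n = int(n)
            sel = np.flatnonzero((pep_nleu == n) & present)
            if sel.size == 0:
                continue
            dist = channel_distribution(n, p_enr)
            mix = np.outer(f_pep[sel], dist)
            mix[:, 0] += 1.0 - f_pep[sel]
            noise = _lognormal_noise(design.noise_cv, (sel.size, n + 1), rng)
            inten = pep_total[sel, None] * mix * noise
            frames.append(
                pd.DataFrame(
                    {
                        "peptide_id": np.repeat(pep_ids[sel], n + 1),
                        "protein_id": np.repeat(pep_prot[sel], n + 1),
                        "sample_id": sample_id,
                        "group": group,
                        "time_days": t,
                        "rt_minutes": np.repeat(rt_obs[sel], n + 1),
                        "n_leu": n,
                        "channel": np.tile(np.arange(n + 1), sel.size),
                        "intensity": inten.ravel(),
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["sample_id", "peptide_id", "channel"], kind="stable", ignore_index=True
    )


def simulate_abundances(
    proteins: Sequence[GroundTruthProtein],
    peptides: Sequence[GroundTruthPeptide],
    design: StudyDesign,
) -> pd.DataFrame:
    """Per-peptide AUC table: base x ionization x 2^(effect * aged) x noise."""
    by_protein = {p.protein_id: p for p in proteins}
    rng = np.random.default_rng(design.seed + 1)  # decoupled from envelope noise
    rows: dict[str, list] = {c: [] for c in (
        "peptide_id", "protein_id", "sample_id", "group", "auc",
    )}
    for sample_id, group, _t, _animal in design.samples():
        aged = design.is_aged(group)
        present = rng.random(len(peptides)) >= design.missing_rate
        noise = _lognormal_noise(design.noise_cv, len(peptides), rng)
        for i, pep in enumerate(peptides):
            if not present[i]:
                continue
            prot = by_protein[pep.protein_id]
            auc = (
                prot.base_abundance
                * pep.ionization_factor
                * 2.0 ** (prot.group_log2_effect * aged)
                * noise[i]
            )
            rows["peptide_id"].append(pep.peptide_id)
            rows["protein_id"].append(pep.protein_id)
            rows["sample_id"].append(sample_id)
            rows["group"].append(group)
            rows["auc"].append(float(auc))
    return pd.DataFrame(rows)


def simulate_percent_new_measurements(
    true_half_life: float,
    *,
    times: Iterable[float],
    n_peptides: int,
    n_replicates: int,
    noise_sd: float,
    rng: np.random.Generator,
    peptide_prefix: str = "pep",
) -> pd.DataFrame:
    """Measurement-level shortcut: percent-new observations for one protein.

    Noise is multiplicative log-normal on the surviving (unlabeled) fraction,
    i.e. iid Gaussian with sd ``noise_sd`` on ln(100 - y) — exactly the error
    structure the log-linear turnover fit assumes, which makes this the
    reference generator for ANCOVA calibration studies. Noise can push an
    apparent percent-new slightly below zero at early times; values are left
    unclipped so the log-space errors stay homoscedastic.
    """
    k = math.log(2.0) / true_half_life
    rows = {"peptide_id": [], "time_days": [], "percent_new": []}
    for j in range(n_peptides):
        for t in times:
            surv = math.exp(-k * t)
            eps = rng.normal(0.0, noise_sd, n_replicates) if noise_sd > 0 else np.zeros(n_replicates)
            y = 100.0 * (1.0 - surv * np.exp(eps))
            rows["peptide_id"].extend([f"{peptide_prefix}{j + 1}"] * n_replicates)
            rows["time_days"].extend([float(t)] * n_replicates)
            rows["percent_new"].extend(y.tolist())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence


def ground_truth_frame(proteins: Sequence[GroundTruthProtein]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in proteins],
            "compartment": [p.compartment for p in proteins],
            "true_half_life_days": [p.true_half_life for p in proteins],
            "group_log2_effect": [p.group_log2_effect for p in proteins],
            "old_half_life_multiplier": [p.old_half_life_multiplier for p in proteins],
        }
    )


def write_dataset(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write each table as ``<name>.tsv`` under out_dir; returns the paths."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    paths = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


def simulate_study(
    n_proteins: int,
    design: StudyDesign,
    *,
    half_life_law: Mapping | None = None,
    compartment_props: Mapping[str, float] | None = None,
    effect_law_by_compartment: Mapping[str, Mapping] | None = None,
    old_multiplier_law: Mapping | None = None,
    half_life_law_by_compartment: Mapping[str, Mapping] | None = None,
    peptides_per_protein_law: Mapping | None = None,
    leu_count_law: Mapping | None = None,
) -> dict:
    """Convenience: one call producing the full set of study tables."""
    proteins = simulate_ground_truth(
        n_proteins,
        half_life_law,
        compartment_props,
        design.seed,
        effect_law_by_compartment=effect_law_by_compartment,
        old_multiplier_law=old_multiplier_law,
        half_life_law_by_compartment=half_life_law_by_compartment,
    )
    peptides = generate_peptides(
        proteins, peptides_per_protein_law, leu_count_law, design.seed + 7
    )
    return {
        "proteins": proteins,
        "peptides": peptides,
        "envelope": simulate_timecourse(proteins, peptides, design),
        "abundance": simulate_abundances(proteins, peptides, design),
        "ground_truth": ground_truth_frame(proteins),
    }
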