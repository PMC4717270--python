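"""Readers and writers for the pipeline's plain-text table formats.

All tables are tab-separated with a header row. Compartment reference lists
(one protein identifier per line) and GMT gene-set files (set name,
description, then member identifiers, tab-separated) round out the inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

ENVELOPE_COLUMNS = [
    "peptide_id", "protein_id", "sample_id", "group", "time_days",
    "rt_minutes", "n_leu", "channel", "intensity",
]
ABUNDANCE_COLUMNS = ["peptide_id", "protein_id", "sample_id", "group", "auc"]
GROUND_TRUTH_COLUMNS = [
    "protein_id", "compartment", "true_half_life_days", "group_log2_effect",
]
FRACTION_NEW_COLUMNS = [
    "peptide_id", "protein_id", "sample_id", "group", "time_days",
    "percent_new", "residual_norm", "p_hat_used",
]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_envelope_tsv(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ENVELOPE_COLUMNS)


def read_abundance_tsv(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ABUNDANCE_COLUMNS)


def read_ground_truth_tsv(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, GROUND_TRUTH_COLUMNS)


def read_fraction_new_tsv(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, FRACTION_NEW_COLUMNS)


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_id_list(path: str | Path) -> set[str]:
    """Protein identifier list, one per line; blank lines and # comments skipped."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_id_list(ids: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(sorted(ids)) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name -> member identifiers (descriptions discarded)."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT lines need name, description, members")
        sets[parts[0]] = {m for m in parts[2:] if m}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "\t".join([name, description, *sorted(members)])
        for name, members in sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
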