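"""Tabular I/O and run configuration.

Readers accept TSV or CSV with a header; writers always emit headered,
tab-delimited UTF-8.  Configuration files are flat key=value text; unknown
keys are rejected and every resolved configuration is echoed to the log.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class AbundanceTable:
    """Rows of (species_id, count) with unique ids and counts >= 1."""

    species_id: list[str]
    count: np.ndarray

    def __post_init__(self):
        if len(set(self.species_id)) != len(self.species_id):
            dupes = sorted({s for s in self.species_id
                            if self.species_id.count(s) > 1})
            raise ValidationError(f"duplicate species ids: {dupes}")
        self.count = np.asarray(self.count, dtype=int)

    @property
    def abundances(self) -> np.ndarray:
        return self.count


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text(encoding="utf-8")[:4096]
    if "\t" in sample.splitlines()[0]:
        return "\t"
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_abundance_table(path) -> AbundanceTable:
    """Parse a TSV/CSV abundance table (species_id, count).

    Malformed or non-positive counts are reported with their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    delim = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delim, dtype={0: str})
    except Exception as exc:
        raise ValidationError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValidationError(
            f"{path}: expected columns (species_id, count), got {list(df.columns)}")
    ids = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1]
    counts = pd.to_numeric(raw, errors="coerce")
    bad = [i + 2 for i, v in enumerate(counts)  # +2: header + 1-based
           if not np.isfinite(v) or v < 1 or v != int(v)]
    if bad:
        raise ValidationError(
            f"{path}: invalid counts (must be integers >= 1) on lines {bad}")
    return AbundanceTable(species_id=ids, count=counts.astype(int).to_numpy())


def write_table(path, columns: dict) -> None:
    """Write named columns as headered, tab-delimited UTF-8."""
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_config(path, allowed_keys: set[str]) -> dict[str, str]:
    """Flat key=value configuration file; unknown keys are rejected."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected key=value")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in allowed_keys:
            raise ValidationError(
                f"{path}:{lineno}: unknown key {key!r}; allowed: "
                f"{sorted(allowed_keys)}")
        out[key] = val
    return out
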