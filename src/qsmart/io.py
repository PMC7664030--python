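"""Tabular I/O: schema-validated table reading and the FeatureMatrix container.

All tables are UTF-8 CSV/TSV with a header row ("." decimal); the delimiter
is inferred from the file extension. The FeatureMatrix holds the assembled
design matrix together with per-column metadata (feature level, and the two
component features for interaction columns) and round-trips losslessly
through a values file plus a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("qsmart")

#: Feature levels a column may be tagged with.
LEVELS = ("drug", "residue", "motif", "domain", "gene", "family",
          "pathway", "sample", "interaction")


class SchemaError(ValueError):
    """A required column is missing or the file cannot satisfy the schema."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_table(path: str | Path, schema: dict[str, str]) -> pd.DataFrame:
    """Read a CSV/TSV and coerce columns to declared semantic types.

    ``schema`` maps required column names to one of ``str``, ``float``,
    ``int``, ``binary``.  Rows failing numeric coercion are dropped and
    reported with their line numbers; missing columns raise
    :class:`SchemaError`; an empty file raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty input file: {path}") from None
    if raw.empty and raw.columns.empty:
        raise ValueError(f"empty input file: {path}")
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    out = raw.copy()
    bad_rows: set[int] = set()
    for col, kind in schema.items():
        if kind == "str":
            continue
        coerced = pd.to_numeric(out[col], errors="coerce")
        failed = coerced.isna() & out[col].notna()
        if kind == "binary":
            failed |= ~coerced.isin([0, 1]) & out[col].notna()
        bad_rows.update(out.index[failed])
        out[col] = coerced
    if bad_rows:
        # +2: header line plus 1-based numbering
        lines = sorted(i + 2 for i in bad_rows)
        log.warning("%s: rejected %d row(s) failing coercion at line(s) %s",
                    path.name, len(bad_rows), lines)
        out = out.drop(index=sorted(bad_rows)).reset_index(drop=True)
    for col, kind in schema.items():
        if kind == "int":
            out[col] = out[col].astype(np.int64)
        elif kind == "binary":
            out[col] = out[col].astype(np.int64)
        elif kind == "float":
            out[col] = out[col].astype(float)
    return out


@dataclass
class FeatureMatrix:
    """Named design matrix aligned to responses, with column metadata.

    ``values`` is a responses x features DataFrame; ``levels`` tags every
    column with its feature level; ``components`` records, for interaction
    columns only, the two feature names whose elementwise product the
    column is. ``levels`` may carry entries for referenced component
    features that are not value columns themselves (e.g. after a
    sub-selection), so interaction provenance is never lost.
    """

    values: pd.DataFrame
    levels: dict[str, str] = field(default_factory=dict)
    components: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate feature names")
        unknown = [c for c in cols if c not in self.levels]
        if unknown:
            raise ValueError(f"columns without a level tag: {unknown[:5]}")
        bad = {c: lv for c, lv in self.levels.items() if lv not in LEVELS}
        if bad:
            raise ValueError(f"unknown levels: {bad}")
        for col, (a, b) in self.components.items():
            for comp in (a, b):
                if comp not in self.levels:
                    raise ValueError(
                        f"interaction {col}: unknown component {comp}")
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def residue_columns(self) -> list[str]:
        """The M_k subset: residue-level mutation features."""
        return [c for c, lv in self.levels.items() if lv == "residue"]

    def select(self, names: list[str]) -> "FeatureMatrix":
        levels = {c: self.levels[c] for c in names}
        components = {c: self.components[c] for c in names
                      if c in self.components}
        for a, b in components.values():  # keep component metadata
            levels.setdefault(a, self.levels[a])
            levels.setdefault(b, self.levels[b])
        return FeatureMatrix(self.values[names].copy(), levels, components)

    def concat(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if not self.values.index.equals(other.values.index):
            raise ValueError("row indices differ")
        overlap = set(self.values.columns) & set(other.values.columns)
        if overlap:
            raise ValueError(f"overlapping feature names: {sorted(overlap)[:5]}")
        return FeatureMatrix(
            pd.concat([self.values, other.values], axis=1),
            {**self.levels, **other.levels},
            {**self.components, **other.components},
        )

    def equals(self, other: "FeatureMatrix") -> bool:
        return (self.values.equals(other.values)
                and self.levels == other.levels
                and self.components == other.components)


def write_feature_matrix(m: FeatureMatrix, path: str | Path) -> None:
    """Write values to ``path`` and metadata to ``<path>.meta.json``.

    The round trip ``read_feature_matrix(write(...))`` reproduces the
    matrix bit-for-bit (Python float repr is shortest-round-trip).
    """
    path = Path(path)
    m.values.to_csv(path, sep=_sep_for(path), index_label="response_id")
    meta = {
        "levels": m.levels,
        "components": {k: list(v) for k, v in m.components.items()},
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep=_sep_for(path), index_col="response_id")
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    components = {k: (v[0], v[1]) for k, v in meta["components"].items()}
    return FeatureMatrix(values, meta["levels"], components)
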