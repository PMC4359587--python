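"""Reading and writing feature tables, labels and result tables.

Feature tables are CSV/TSV with features as rows: the first column is the
feature identifier, optional ``mz`` / ``rt`` columns carry the m/z and
retention time, and the remaining columns are samples.  Empty cells and
explicit zeros both mean "not detected" and are stored as 0.  All output
tables begin with ``#``-prefixed metadata lines recording the parameters
and seed of the run, so every result can be regenerated from its own
header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "read_feature_table",
    "write_feature_table",
    "read_labels",
    "read_sets",
    "read_pvalues",
    "write_table",
]

_ANNOTATION_COLUMNS = {"mz", "m/z", "rt", "retention_time"}


@dataclass
class AbundanceMatrix:
    """Features-by-samples table of nonnegative abundances; 0 = absent."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    annotations: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a features x samples matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape disagrees with the id lists")
        if np.any(self.values < 0):
            raise ValueError("negative abundance values are not allowed")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _separator(path: str | Path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    return "," if str(path).endswith(".csv") else "\t"


def read_feature_table(
    path: str | Path,
    dialect: str | None = None,
    transpose: bool = False,
) -> AbundanceMatrix:
    """Load a feature abundance table from CSV/TSV.

    Empty cells map to 0 (absent).  Negative values, duplicate feature
    ids and non-numeric cells are rejected.  ``transpose=True`` accepts
    samples-as-rows files.
    """
    df = pd.read_csv(path, sep=_separator(path, dialect), comment="#",
                     index_col=0, dtype=str)
    if transpose:
        df = df.T
    annotation_cols = [c for c in df.columns if c.lower() in _ANNOTATION_COLUMNS]
    annotations = None
    if annotation_cols:
        annotations = df[annotation_cols].apply(pd.to_numeric, errors="coerce")
        df = df.drop(columns=annotation_cols)
    feature_ids = [str(i) for i in df.index]
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError(f"duplicate feature ids in {path}")
    values = df.apply(pd.to_numeric, errors="raise").fillna(0.0).to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"negative abundance values in {path}")
    return AbundanceMatrix(values=values, feature_ids=feature_ids,
                           sample_ids=[str(c) for c in df.columns],
                           annotations=annotations)


def write_feature_table(
    matrix: AbundanceMatrix,
    path: str | Path,
    dialect: str | None = None,
    metadata: dict | None = None,
) -> None:
    """Write an abundance table, optionally with a ``#`` metadata header."""
    df = pd.DataFrame(matrix.values, index=pd.Index(matrix.feature_ids, name="feature_id"),
                      columns=matrix.sample_ids)
    write_table(df.reset_index(), path, dialect=dialect, metadata=metadata)


def read_labels(path: str | Path, sample_ids: list[str] | None = None) -> np.ndarray:
    """Load binary group labels (sample_id, 0/1), aligned to ``sample_ids``.

    A leading column-header row is tolerated.  Every sample of the
    feature table must have a label; unknown sample ids and non-binary
    labels are rejected.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [t for t in line.replace(",", "\t").split("\t") if t.strip()]
            if len(parts) < 2:
                raise ValueError(f"malformed label row in {path}: {line!r}")
            rows.append((parts[0].strip(), parts[1].strip()))
    if rows and rows[0][1] not in ("0", "1"):  # header row
        rows = rows[1:]
    mapping: dict[str, int] = {}
    for sample, label in rows:
        if label not in ("0", "1"):
            raise ValueError(f"labels in {path} must be 0/1, got {label!r}")
        if sample in mapping:
            raise ValueError(f"duplicate sample id {sample!r} in {path}")
        mapping[sample] = int(label)
    if sample_ids is None:
        return np.array(list(mapping.values()))
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    return np.array([mapping[s] for s in sample_ids])


def read_sets(path: str | Path, feature_ids: list[str]) -> list[list[int]]:
    """Load a (feature_id, set_id) table into index groups over ``feature_ids``."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    df.columns = ["feature_id", "set_id"] + list(df.columns[2:])
    pos = {f: i for i, f in enumerate(feature_ids)}
    unknown = [f for f in df["feature_id"] if f not in pos]
    if unknown:
        raise ValueError(f"set assignments for unknown features: {unknown[:5]}")
    groups: dict[str, list[int]] = {}
    for f, s in zip(df["feature_id"], df["set_id"]):
        groups.setdefault(s, []).append(pos[f])
    sets = sorted((sorted(v) for v in groups.values()), key=lambda s: s[0])
    return sets


def read_pvalues(path: str | Path) -> pd.DataFrame:
    """Load a (set_id, p_value) table."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = ["set_id", "p_value"] + list(df.columns[2:])
    df["p_value"] = pd.to_numeric(df["p_value"], errors="raise")
    return df


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    dialect: str | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a DataFrame as CSV/TSV behind a ``#`` metadata header."""
    sep = _separator(path, dialect)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep=sep, index=False, float_format="%.6g")
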