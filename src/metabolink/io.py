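"""Data model and table I/O.

The pipeline's sole primary input is a samples x metabolites concentration
table (one row per sample, one numeric column per metabolite) plus a stage
label and replicate id per sample, as produced by NMR quantification software.
An optional two-column annotation table maps metabolites to compound classes.
"""
from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StageSequence",
    "ConcentrationMatrix",
    "AnnotationTable",
    "read_concentration_table",
    "read_annotation_table",
    "class_composition",
]


@dataclass(frozen=True)
class StageSequence:
    """Ordered biological progression of cell stages.

    ``transitions`` is the derived list of consecutive stage pairs: a
    k-stage sequence has k - 1 transitions.
    """

    stages: tuple[str, ...]

    def __init__(self, stages: Iterable[str]):
        object.__setattr__(self, "stages", tuple(str(s) for s in stages))
        if len(self.stages) < 2:
            raise ValueError("a stage sequence needs at least 2 stages")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage names must be unique")

    @property
    def transitions(self) -> list[tuple[str, str]]:
        return list(zip(self.stages[:-1], self.stages[1:]))

    def __contains__(self, stage: str) -> bool:
        return stage in self.stages

    def __len__(self) -> int:
        return len(self.stages)

    def index(self, stage: str) -> int:
        return self.stages.index(stage)


@dataclass
class ConcentrationMatrix:
    """Validated samples x metabolites concentration table.

    values
        float array of shape (n_samples, n_metabolites); no NaN allowed.
    sample_ids, stage_labels, replicate_ids
        per-sample metadata; sample ids unique.
    metabolite_names
        unique column labels, length n_metabolites.
    """

    values: np.ndarray
    sample_ids: list[str]
    stage_labels: list[str]
    replicate_ids: list[str]
    metabolite_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        for name, seq, expect in (
            ("sample_ids", self.sample_ids, n),
            ("stage_labels", self.stage_labels, n),
            ("replicate_ids", self.replicate_ids, n),
            ("metabolite_names", self.metabolite_names, p),
        ):
            if len(seq) != expect:
                raise ValueError(f"{name} has length {len(seq)}, expected {expect}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        dupes = [m for m, c in Counter(self.metabolite_names).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate metabolite names: {sorted(dupes)}")
        if np.isnan(self.values).any():
            raise ValueError("values contain NaN after loading")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def stages_present(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.stage_labels:
            seen.setdefault(s, None)
        return list(seen)

    def stage_mask(self, stage: str) -> np.ndarray:
        return np.array([s == stage for s in self.stage_labels], dtype=bool)

    def validate_against(self, stages: StageSequence) -> None:
        unknown = sorted(set(self.stage_labels) - set(stages.stages))
        if unknown:
            raise ValueError(f"unknown stage labels {unknown}; expected subset of {list(stages.stages)}")

    def require_replicated_stages(self, min_per_stage: int = 2) -> None:
        """Variance-based operations need >= 2 samples in every present stage."""
        counts = Counter(self.stage_labels)
        bad = sorted(s for s, c in counts.items() if c < min_per_stage)
        if bad:
            raise ValueError(f"stages with fewer than {min_per_stage} samples: {bad}")

    def subset_stages(self, keep: Sequence[str]) -> "ConcentrationMatrix":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.stage_labels) if s in keep_set]
        return ConcentrationMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            stage_labels=[self.stage_labels[i] for i in idx],
            replicate_ids=[self.replicate_ids[i] for i in idx],
            metabolite_names=list(self.metabolite_names),
        )

    def to_dataframe(self, stage_column: str = "stage", replicate_column: str = "replicate") -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample"),
                          columns=self.metabolite_names)
        df.insert(0, stage_column, self.stage_labels)
        df.insert(1, replicate_column, self.replicate_ids)
        return df

    def write_csv(self, path: str | Path, stage_column: str = "stage",
                  replicate_column: str = "replicate") -> None:
        # %.17g round-trips float64 exactly
        self.to_dataframe(stage_column, replicate_column).to_csv(path, float_format="%.17g")


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_concentration_table(
    path: str | Path,
    stage_column: str = "stage",
    replicate_column: str = "replicate",
    stage_sequence: StageSequence | None = None,
    missing: str = "reject",
) -> ConcentrationMatrix:
    """Read a delimited concentration table into a :class:`ConcentrationMatrix`.

    Layout: one header row; first column is the sample id; the columns named
    ``stage_column`` and ``replicate_column`` carry metadata; every remaining
    column is a metabolite. Row order is preserved and parsing is
    locale-independent (decimal point).

    Parameters
    ----------
    missing
        ``"reject"`` (default) fails on any empty/NA cell, naming it;
        ``"impute_half_min"`` replaces missing entries of a metabolite by half
        its smallest observed positive value.
    """
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    meta_cols = {header[0], stage_column, replicate_column}
    feature_cols = [c for c in header[1:] if c not in {stage_column, replicate_column}]
    dupes = sorted(m for m, c in Counter(feature_cols).items() if c > 1)
    if dupes:
        raise ValueError(f"duplicate metabolite columns: {dupes}")

    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip",
                     dtype={stage_column: str, replicate_column: str})
    if stage_column not in df.columns:
        raise ValueError(f"stage column {stage_column!r} not found in {path.name}")
    if replicate_column not in df.columns:
        raise ValueError(f"replicate column {replicate_column!r} not found in {path.name}")
    feats = df.drop(columns=[stage_column, replicate_column])

    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & feats.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric value {feats.iat[r, c]!r} at sample {feats.index[r]!r}, "
            f"metabolite {feats.columns[c]!r}"
        )
    if numeric.isna().any().any():
        if missing == "reject":
            r, c = np.argwhere(numeric.isna().values)[0]
            raise ValueError(
                f"missing value at sample {numeric.index[r]!r}, metabolite "
                f"{numeric.columns[c]!r} (policy 'reject'; use 'impute_half_min' to impute)"
            )
        elif missing == "impute_half_min":
            for col in numeric.columns:
                col_vals = numeric[col]
                if col_vals.isna().any():
                    pos = col_vals[col_vals > 0]
                    if pos.empty:
                        raise ValueError(
                            f"cannot impute metabolite {col!r}: no positive observed value"
                        )
                    numeric[col] = col_vals.fillna(pos.min() / 2.0)
        else:
            raise ValueError(f"unknown missing-value policy {missing!r}")

    cm = ConcentrationMatrix(
        values=numeric.values,
        sample_ids=[str(i) for i in numeric.index],
        stage_labels=list(df[stage_column].astype(str)),
        replicate_ids=list(df[replicate_column].astype(str)),
        metabolite_names=list(numeric.columns),
    )
    if stage_sequence is not None:
        cm.validate_against(stage_sequence)
    return cm


@dataclass
class AnnotationTable:
    """Metabolite -> compound-class mapping; unannotated names map to "unknown"."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.mapping.values():
            seen.setdefault(c, None)
        return list(seen)

    def get(self, name: str) -> str:
        return self.mapping.get(name, "unknown")


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a two-column delimited file ``metabolite,class``.

    A header row is optional and detected by the literal column names
    ("metabolite", "class"). Duplicate rows with identical classes collapse;
    conflicting duplicates are rejected.
    """
    path = Path(path)
    sep = _delimiter_for(path)
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=sep), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path.name}:{lineno}: expected 2 columns, got {len(row)}")
            name, cls = row[0].strip(), row[1].strip()
            if lineno == 1 and name.lower() in {"metabolite", "name", "feature"}:
                continue
            if name in mapping and mapping[name] != cls:
                raise ValueError(
                    f"conflicting classes for {name!r}: {mapping[name]!r} vs {cls!r}"
                )
            mapping[name] = cls
    return AnnotationTable(mapping)


def class_composition(
    annot: AnnotationTable, names: Sequence[str]
) -> dict[str, tuple[int, float]]:
    """Per-class count and percentage over the given metabolite names.

    Percentages are 100 * count / len(names) rounded to one decimal; names
    without an annotation count under class "unknown".
    """
    if len(names) == 0:
        raise ValueError("names must be non-empty")
    counts = Counter(annot.get(n) for n in names)
    total = len(names)
    return {
        cls: (cnt, round(100.0 * cnt / total, 1))
        for cls, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
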