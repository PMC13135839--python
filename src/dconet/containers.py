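"""Shared data model for the two-group multi-omics pipeline.

The pipeline compares a reference phenotype group ("fertile") against a
contrast group ("subfertile").  Fold changes are always contrast-over-
reference (subfertile/fertile), and network statistics are reported as
fertile minus subfertile where a difference is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRANSCRIPT = "transcript"
PROTEIN = "protein"
NORMALIZED = "normalized"  # log-scale normalized values, either layer
CROSS_OMICS = "cross_omics"

REFERENCE_GROUP = "fertile"
CONTRAST_GROUP = "subfertile"


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix for one omics layer.

    Counts (transcript layer) must be non-negative integers with no
    missing cells; abundances (protein layer) are non-negative reals and
    may contain NaN for missing measurements.
    """

    data: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in (TRANSCRIPT, PROTEIN, NORMALIZED):
            raise ValidationError(f"unknown omics layer: {self.layer!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate feature IDs: {dups}")
        if cols.duplicated().any():
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate sample IDs: {dups}")
        values = self.data.to_numpy(dtype=float)
        if self.layer == TRANSCRIPT:
            if np.isnan(values).any():
                raise ValidationError("count matrix contains missing values")
            if (values < 0).any():
                raise ValidationError("count matrix contains negative values")
            if not np.allclose(values, np.round(values)):
                raise ValidationError("count matrix contains non-integer values")
        elif self.layer == PROTEIN:
            finite = values[~np.isnan(values)]
            if (finite < 0).any():
                raise ValidationError("abundance matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(feature_ids)], self.layer)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.layer)


@dataclass
class SampleDesign:
    """Two-level group assignment for the samples of a study."""

    groups: pd.Series  # sample_id -> group label
    reference: str = REFERENCE_GROUP
    contrast: str = CONTRAST_GROUP

    def __post_init__(self) -> None:
        if self.groups.index.duplicated().any():
            raise ValidationError("duplicate sample IDs in design")
        levels = set(self.groups.unique())
        if levels != {self.reference, self.contrast}:
            raise ValidationError(
                f"design must contain exactly the levels "
                f"{{{self.reference!r}, {self.contrast!r}}}, got {sorted(levels)}"
            )
        for level in (self.reference, self.contrast):
            if (self.groups == level).sum() < 3:
                raise ValidationError(
                    f"group {level!r} has fewer than 3 samples; "
                    "correlation needs at least 3 points"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def n_in(self, group: str) -> int:
        return int((self.groups == group).sum())


@dataclass
class FeatureMeta:
    """Per-feature annotation: TF status, identification confidence and
    the cross-layer mapping (protein -> transcript-namespace ID)."""

    table: pd.DataFrame  # index feature_id; columns is_tf, confidence, maps_to

    REQUIRED = ("is_tf", "confidence", "maps_to")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"feature metadata missing column {col!r}")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate feature IDs in metadata")

    def tf_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_tf"].astype(bool)])

    def mapping(self) -> pd.Series:
        m = self.table["maps_to"].dropna()
        return m[m != ""]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics), preserving file order."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographic) ordering of an undirected edge."""
    if a == b:
        raise ValidationError(f"self-edge not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


EDGE_COLUMNS = ["feature_a", "feature_b", "r", "group", "layer"]


def edge_frame(records: list[tuple] | None = None) -> pd.DataFrame:
    """Build a canonical edge table (columns feature_a, feature_b, r,
    group, layer) from (a, b, r, group, layer) tuples."""
    rows = []
    for a, b, r, group, layer in records or []:
        a, b = canonical_edge(a, b)
        rows.append((a, b, float(r), group, layer))
    df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if not df.empty:
        df = df.sort_values(["feature_a", "feature_b"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


@dataclass
class PcitNetwork:
    """Edges retained for one phenotype group in one omics layer,
    together with bookkeeping counts from each filtering stage."""

    group: str
    layer: str
    edges: pd.DataFrame  # canonical edge table
    n_features: int = 0
    n_pcit_retained: int = 0
    n_p_significant: int = 0

    def degrees(self) -> pd.Series:
        if self.edges.empty:
            return pd.Series(dtype=int)
        counts = pd.concat(
            [self.edges["feature_a"], self.edges["feature_b"]]
        ).value_counts()
        return counts.sort_index()

    def nodes(self) -> set[str]:
        if self.edges.empty:
            return set()
        return set(self.edges["feature_a"]) | set(self.edges["feature_b"])

    def edge_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["feature_a"], self.edges["feature_b"]))
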