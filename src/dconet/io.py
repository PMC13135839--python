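"""Readers and writers for the plain-text formats the pipeline touches.

Matrices, designs, TF lists and ID mappings are tab-separated text;
gene sets are GMT; networks are exported as SIF or TSV edge lists.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    EDGE_COLUMNS,
    TRANSCRIPT,
    ExpressionMatrix,
    GeneSetCollection,
    SampleDesign,
    ValidationError,
)

logger = logging.getLogger(__name__)

MISSING_MARKERS = ("", "NA", "NaN", "nan")


def read_matrix(path: str | Path, layer: str) -> ExpressionMatrix:
    """Read a features-in-rows TSV matrix.

    First column holds feature IDs, header row holds sample IDs.
    Empty cells or "NA" are treated as missing (protein layer only).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(MISSING_MARKERS),
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if layer == TRANSCRIPT and df.isna().any().any():
        raise ValidationError(f"count matrix {path} contains missing cells")
    return ExpressionMatrix(df, layer)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data
    if matrix.layer == TRANSCRIPT:
        df = df.astype(int)
        df.to_csv(path, sep="\t")
    else:
        df.to_csv(path, sep="\t", float_format="%.6f", na_rep="NA")


def read_design(path: str | Path) -> SampleDesign:
    """Read a two-column TSV (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"design file {path} needs two columns")
    groups = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    return SampleDesign(groups)


def write_design(design: SampleDesign, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": design.groups.index, "group": design.groups.values}
    ).to_csv(path, sep="\t", index=False)


def read_tf_list(path: str | Path) -> list[str]:
    """Read a TF list: first TSV column holds feature IDs; a header line
    is tolerated if its first field is 'feature_id' or 'tf_id'."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            token = line.rstrip("\n").split("\t")[0].strip()
            if not token or token in ("feature_id", "tf_id"):
                continue
            ids.append(token)
    return ids


def read_mapping(path: str | Path) -> pd.Series:
    """Read a two-column TSV mapping protein ID -> transcript-layer ID."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: tab-separated name, description, members..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen = set()
            for m in fields[2:]:
                if not m:
                    continue
                if m in seen:
                    logger.warning("%s:%d: duplicate member %r in set %r",
                                   path, lineno, m, name)
                    continue
                seen.add(m)
                members.append(m)
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_edge_list(edges: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    """Write a canonical edge table as SIF ("a coexp b") or TSV
    (feature_a, feature_b, r to 6 decimals, group, layer)."""
    if dialect == "sif":
        with open(path, "w") as fh:
            for a, b in zip(edges["feature_a"], edges["feature_b"]):
                fh.write(f"{a} coexp {b}\n")
    elif dialect == "tsv":
        out = edges[EDGE_COLUMNS].copy()
        out["r"] = out["r"].map(lambda v: f"{v:.6f}")
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown edge-list dialect {dialect!r}")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"feature_a": str, "feature_b": str})
    df["r"] = df["r"].astype(float)
    return df


def match_cross_layer(
    transcripts: ExpressionMatrix,
    proteins: ExpressionMatrix,
    mapping: pd.Series,
) -> list[tuple[str, str]]:
    """Match transcripts to proteins through an ID mapping.

    ``mapping`` takes protein IDs to transcript-layer IDs.  One pair is
    produced per transcript with at least one mapped, quantified
    protein; when several proteins map to the same transcript the one
    with the highest median abundance is kept (ties broken by protein
    ID).  Unmatched features are silently excluded.
    """
    gene_ids = set(transcripts.feature_ids)
    prot_ids = set(proteins.feature_ids)
    candidates: dict[str, list[tuple[float, str]]] = {}
    for prot, gene in mapping.items():
        if prot not in prot_ids or gene not in gene_ids:
            continue
        med = float(np.nanmedian(proteins.data.loc[prot].to_numpy(dtype=float)))
        if np.isnan(med):
            med = -np.inf
        candidates.setdefault(gene, []).append((med, prot))
    pairs = []
    for gene in sorted(candidates):
        # max median; ties broken deterministically by protein ID
        best = max(candidates[gene], key=lambda t: (t[0], t[1]))
        pairs.append((gene, best[1]))
    return pairs
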