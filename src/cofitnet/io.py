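"""Readers and writers for the plain-text formats used across the pipeline.

Matrices are genes x cell-lines TSV with a header row of cell-line IDs;
gene sets travel as GMT (name, description, members...); pair lists and
ontologies as two-column TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x cell-line TSV matrix, validating IDs and finiteness."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dupes[:5]}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate cell-line IDs in {path}")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = df.index[~np.isfinite(values).all(axis=1)].tolist()
        raise ValueError(f"non-finite values in {path} for genes {bad[:5]}")
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    # full precision so a read-back matrix reproduces computations exactly
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_pair_list(path: str | Path) -> set[frozenset[str]]:
    """Read an unordered gene-pair list from two-column TSV (no header)."""
    pairs: set[frozenset[str]] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        a, b, *_ = line.split("\t")
        if a == b:
            raise ValueError(f"self-pair {a!r} in {path}")
        pairs.add(frozenset((a, b)))
    return pairs


def write_pair_list(pairs: set[frozenset[str]], path: str | Path) -> None:
    rows = sorted(tuple(sorted(p)) for p in pairs)
    Path(path).write_text("".join(f"{a}\t{b}\n" for a, b in rows))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, _desc, *genes = line.rstrip("\n").split("\t")
        sets[name] = set(genes)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name in sorted(sets):
        desc = (descriptions or {}).get(name, "na")
        members = "\t".join(sorted(sets[name]))
        lines.append(f"{name}\t{desc}\t{members}\n")
    Path(path).write_text("".join(lines))


def annotations_to_gmt(annotations: dict[str, set[str]]) -> dict[str, set[str]]:
    """Invert a gene -> terms map into term -> genes sets."""
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        for t in terms:
            out.setdefault(t, set()).add(gene)
    return out


def read_ontology(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["child", "parent"]:
        df.columns = ["child", "parent", *df.columns[2:]]
    return df[["child", "parent"]]


def write_ontology(ontology: pd.DataFrame, path: str | Path) -> None:
    ontology.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a weighted edge list (gene_a, gene_b, score) TSV with header."""
    return pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.8g")
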