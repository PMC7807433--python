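"""Readers and writers for the plain-text formats the pipeline touches.

OTU tables are TSV with OTU ids in the first column (``#OTU_ID`` by
convention), integer count columns, and a trailing ``taxonomy`` column.
Networks are written either as GraphML (via networkx) or as a TSV edge
list ``otu_a  otu_b  sign  score  p_merged  q`` that round-trips
bit-identically (floats serialized with repr precision).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    AssociationNetwork,
    Edge,
    OTUTable,
    ParseError,
    SampleMetadata,
)

_EDGE_COLUMNS = ("otu_a", "otu_b", "sign", "score", "p_merged", "q")

#: Diet vocabulary of the study system; unknown tokens are kept verbatim.
KNOWN_DIETS = frozenset(
    {"carnivore", "scale-eater", "omnivore", "planktivore", "herbivore", ""}
)


def read_otu_table(
    path: str | Path,
    id_column: str | None = None,
    taxonomy_column: str = "taxonomy",
) -> OTUTable:
    """Read an OTU count table from TSV.

    First column holds OTU ids (any header; ``#OTU_ID`` conventional),
    the last column taxonomy lineage strings (header configurable), and
    everything between integer counts per sample.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need at least an id column and one sample")
    id_col = id_column or df.columns[0]
    dup = df[id_col][df[id_col].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate OTU id {dup.iloc[0]!r}")
    has_tax = taxonomy_column in df.columns
    taxonomy = df[taxonomy_column].fillna("") if has_tax else pd.Series([""] * len(df))
    count_cols = [c for c in df.columns if c not in (id_col, taxonomy_column)]
    counts = np.empty((len(df), len(count_cols)), dtype=np.int64)
    for j, c in enumerate(count_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.values)[0])
            raise ParseError(
                f"{path}: non-numeric count at row {df[id_col].iloc[i]!r}, column {c!r}"
            )
        if np.any(col.values != np.floor(col.values)):
            i = int(np.flatnonzero(col.values != np.floor(col.values))[0])
            raise ParseError(
                f"{path}: non-integer count at row {df[id_col].iloc[i]!r}, column {c!r}"
            )
        if np.any(col.values < 0):
            i = int(np.flatnonzero(col.values < 0)[0])
            raise ParseError(
                f"{path}: negative count at row {df[id_col].iloc[i]!r}, column {c!r}"
            )
        counts[:, j] = col.values.astype(np.int64)
    return OTUTable(counts, list(df[id_col]), count_cols, list(taxonomy))


def write_otu_table(table: OTUTable, path: str | Path) -> None:
    df = table.to_frame()
    df.insert(0, "#OTU_ID", table.otu_ids)
    df["taxonomy"] = table.taxonomy
    df.to_csv(path, sep="\t", index=False)


_META_ALIASES = {
    "sample_id": ("sample_id", "#SampleID", "sample", "SampleID"),
    "lake": ("lake", "Lake"),
    "continent": ("continent", "Continent"),
    "species": ("species", "Species"),
    "diet": ("diet", "Diet"),
}


def read_metadata(
    path: str | Path, column_map: dict[str, str] | None = None
) -> SampleMetadata:
    """Read sample metadata (sample_id, lake, continent, species, diet).

    ``column_map`` overrides header names, e.g. ``{"diet": "Trophic"}``.
    Unknown diet tokens are preserved verbatim with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    column_map = column_map or {}
    resolved: dict[str, str] = {}
    for field, aliases in _META_ALIASES.items():
        if field in column_map:
            if column_map[field] not in df.columns:
                raise ParseError(f"{path}: mapped column {column_map[field]!r} absent")
            resolved[field] = column_map[field]
            continue
        hit = next((a for a in aliases if a in df.columns), None)
        if hit is None:
            if field == "diet":
                df["diet"] = ""
                hit = "diet"
            elif field == "species":
                df["species"] = ""
                hit = "species"
            else:
                raise ParseError(f"{path}: missing mandatory column {field!r}")
        resolved[field] = hit
    out = df[[resolved[f] for f in _META_ALIASES]].copy()
    out.columns = list(_META_ALIASES)
    unknown = sorted(set(out["diet"]) - KNOWN_DIETS)
    if unknown:
        warnings.warn(f"unknown diet tokens kept verbatim: {unknown}", stacklevel=2)
    out = out.set_index("sample_id")
    return SampleMetadata(out)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.rename_axis("sample_id").to_csv(path, sep="\t")


# -- networks -----------------------------------------------------------


def write_network(
    net: AssociationNetwork, path: str | Path, format: str = "edge_tsv"
) -> None:
    """Write a network as ``edge_tsv`` (round-trip exact) or ``graphml``."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
        return
    if format != "edge_tsv":
        raise ValueError(f"unknown network format {format!r}")
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_COLUMNS) + "\ttaxonomy_a\ttaxonomy_b\n")
        for e in net.edges:
            fh.write(
                f"{e.otu_a}\t{e.otu_b}\t{e.sign}\t{e.score!r}\t{e.p_merged!r}\t"
                f"{e.q!r}\t{net.taxonomy.get(e.otu_a, '')}\t"
                f"{net.taxonomy.get(e.otu_b, '')}\n"
            )


def read_network(path: str | Path, format: str | None = None) -> AssociationNetwork:
    """Inverse of :func:`write_network`; format inferred from suffix."""
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix == ".graphml" else "edge_tsv"
    if format == "graphml":
        return AssociationNetwork.from_networkx(nx.read_graphml(path))
    edges: list[Edge] = []
    taxonomy: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:6]) != _EDGE_COLUMNS:
            raise ParseError(f"{path}: unexpected edge-list header {header[:6]}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            a, b, sign = parts[0], parts[1], parts[2]
            edges.append(Edge(a, b, sign, float(parts[3]), float(parts[4]), float(parts[5])))
            if len(parts) >= 8:
                taxonomy[a] = parts[6]
                taxonomy[b] = parts[7]
    return AssociationNetwork(edges=edges, taxonomy=taxonomy, name=path.stem)
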