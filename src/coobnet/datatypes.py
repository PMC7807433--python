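"""Domain types shared by every stage of the co-occurrence pipeline.

The pipeline works on three in-memory containers:

* :class:`OTUTable` — an integer count matrix (rows = OTUs, columns =
  samples) with taxonomy lineage strings per OTU;
* :class:`SampleMetadata` — per-sample host labels (lake, continent,
  species, diet);
* :class:`AssociationNetwork` — an undirected, signed graph over OTU ids
  whose edges carry a consensus score, a merged p-value and a BH q-value.

Edge identity is canonical throughout: the unordered OTU pair is stored
lexicographically sorted, and two edges are "the same" across networks
if and only if both ids *and* the sign match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

COPRESENCE = "copresence"
EXCLUSION = "exclusion"
SIGNS = (COPRESENCE, EXCLUSION)

#: Taxonomic ranks parsed out of a greengenes-style lineage string.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIXES = {"k": 0, "p": 1, "c": 2, "o": 3, "f": 4, "g": 5, "s": 6}


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a ``k__X; p__Y; ...`` lineage string into per-rank fields.

    Unparseable or absent ranks are left empty rather than guessed.
    """
    fields = {r: "" for r in RANKS}
    if not lineage:
        return fields
    for token in lineage.split(";"):
        token = token.strip()
        if len(token) >= 3 and token[1:3] == "__" and token[0].lower() in _RANK_PREFIXES:
            fields[RANKS[_RANK_PREFIXES[token[0].lower()]]] = token[3:].strip()
    return fields


class ParseError(ValueError):
    """Raised when an input file violates a format or invariant."""


@dataclass
class OTUTable:
    """Integer OTU-by-sample count matrix with taxonomy annotations.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_otus, n_samples)``.
    otu_ids, sample_ids
        Unique row / column labels.
    taxonomy
        Raw lineage string per OTU (may be empty strings).
    """

    counts: np.ndarray
    otu_ids: list[str]
    sample_ids: list[str]
    taxonomy: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ParseError("counts must be integers (read counts)")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ParseError("counts must be non-negative")
        self.otu_ids = [str(x) for x in self.otu_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.taxonomy = [str(x) for x in self.taxonomy]
        n, m = self.counts.shape
        if len(self.otu_ids) != n:
            raise ValueError(f"{len(self.otu_ids)} otu_ids for {n} rows")
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {m} columns")
        if len(self.taxonomy) != n:
            raise ValueError("taxonomy length must match number of OTUs")
        for name, ids in (("otu_id", self.otu_ids), ("sample_id", self.sample_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise ParseError(f"duplicate {name}: {x!r}")
                seen.add(x)

    # -- convenience -----------------------------------------------------
    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def taxonomy_table(self) -> pd.DataFrame:
        """Per-rank parsed taxonomy, one row per OTU."""
        return pd.DataFrame(
            [parse_lineage(t) for t in self.taxonomy], index=self.otu_ids
        )

    def select_otus(self, keep: Iterable[str] | np.ndarray) -> "OTUTable":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {o: i for i, o in enumerate(self.otu_ids)}
            idx = np.array([pos[o] for o in keep], dtype=int)
        return OTUTable(
            self.counts[idx],
            [self.otu_ids[i] for i in idx],
            list(self.sample_ids),
            [self.taxonomy[i] for i in idx],
        )

    def select_samples(self, keep: Iterable[str]) -> "OTUTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return OTUTable(
            self.counts[:, idx],
            list(self.otu_ids),
            [self.sample_ids[i] for i in idx],
            list(self.taxonomy),
        )


@dataclass
class SampleMetadata:
    """Per-sample host annotation: lake, continent, species and diet.

    Backed by a DataFrame indexed by sample id; ``diet`` may be missing
    (empty string) for samples not used in diet analyses.
    """

    frame: pd.DataFrame

    REQUIRED = ("lake", "continent", "species", "diet")

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ParseError(f"duplicate sample_id: {dup!r}")
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ParseError(f"metadata missing mandatory column {col!r}")
        self.frame = self.frame.fillna("")
        missing = self.frame.index[
            (self.frame["lake"] == "") | (self.frame["continent"] == "")
        ]
        if len(missing):
            raise ParseError(f"sample {missing[0]!r} lacks lake/continent")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def __len__(self) -> int:
        return len(self.frame)

    def column(self, name: str) -> pd.Series:
        return self.frame[name]

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())

    def merge_diets(self, mapping: Mapping[str, str]) -> "SampleMetadata":
        """Relabel diets, e.g. fold scale-eaters into carnivores."""
        out = self.frame.copy()
        out["diet"] = out["diet"].map(lambda d: mapping.get(d, d))
        return SampleMetadata(out)


def canonical_edge(a: str, b: str, sign: str) -> tuple[str, str, str]:
    """Canonical sign-aware edge key: ids sorted lexicographically."""
    if a == b:
        raise ValueError(f"self-edge on {a!r}")
    if sign not in SIGNS:
        raise ValueError(f"unknown sign {sign!r}")
    return (a, b, sign) if a < b else (b, a, sign)


@dataclass
class Edge:
    """One undirected signed association with its evidence."""

    otu_a: str
    otu_b: str
    sign: str
    score: float
    p_merged: float
    q: float

    def __post_init__(self) -> None:
        self.otu_a, self.otu_b, self.sign = canonical_edge(
            self.otu_a, self.otu_b, self.sign
        )
        if not (np.isnan(self.q) or 0.0 <= self.q <= 1.0):
            raise ValueError(f"q out of [0,1]: {self.q}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.otu_a, self.otu_b, self.sign)


@dataclass
class AssociationNetwork:
    """Undirected signed co-occurrence graph over OTU ids.

    Nodes are exactly the OTUs participating in at least one edge;
    ``taxonomy`` maps node id -> lineage string (empty if unknown).
    """

    edges: list[Edge] = field(default_factory=list)
    taxonomy: dict[str, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for e in self.edges:
            if e.key in seen:
                raise ValueError(f"duplicate edge {e.key}")
            seen.add(e.key)
        nodes = self.node_ids
        self.taxonomy = {n: self.taxonomy.get(n, "") for n in nodes}

    @property
    def node_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.otu_a)
            seen.setdefault(e.otu_b)
        return sorted(seen)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_counts_by_sign(self) -> tuple[int, int]:
        """(copresence, exclusion) edge counts."""
        pos = sum(1 for e in self.edges if e.sign == COPRESENCE)
        return pos, len(self.edges) - pos

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {e.key for e in self.edges}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        for n in self.node_ids:
            g.add_node(n, taxonomy=self.taxonomy.get(n, ""))
        for e in self.edges:
            g.add_edge(
                e.otu_a, e.otu_b, sign=e.sign, score=e.score,
                p_merged=e.p_merged, q=e.q,
            )
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, name: str = "") -> "AssociationNetwork":
        edges = [
            Edge(
                a, b,
                d.get("sign", COPRESENCE),
                float(d.get("score", np.nan)),
                float(d.get("p_merged", np.nan)),
                float(d.get("q", np.nan)),
            )
            for a, b, d in g.edges(data=True)
        ]
        tax = {n: str(g.nodes[n].get("taxonomy", "")) for n in g.nodes}
        return cls(edges=edges, taxonomy=tax, name=name or str(g.name or ""))


@dataclass
class GroundTruth:
    """Planted structure from the synthetic-community generator.

    ``planted_edges`` maps a canonical sign-aware edge key to the latent
    correlation rho used when planting it; ``core_edges`` is the subset
    planted in every group; ``diet_effects`` maps ``(otu_id, diet)`` to a
    multiplicative abundance shift (> 0).
    """

    planted_edges: dict[tuple[str, str, str], float]
    core_edges: set[tuple[str, str, str]] = field(default_factory=set)
    diet_effects: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = self.core_edges - set(self.planted_edges)
        if extra:
            raise ValueError(f"core edges not planted: {sorted(extra)[:3]}")
        for k, s in self.diet_effects.items():
            if s <= 0:
                raise ValueError(f"non-positive diet shift for {k}")
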