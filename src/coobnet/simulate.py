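"""Synthetic gut-microbiota communities with planted association structure.

The generator emulates the study system — a few hundred OTUs observed in
fish gut samples partitioned over lakes on two continents, with nested
species labels and diet categories — while planting a known set of
pairwise associations and diet-driven abundance shifts, so every
downstream stage (inference, comparison, composition) can be scored
against ground truth.

Generative model (per sample in group g with diet d):

1. latent log-abundance ``z ~ MVN(mu_g + ln(diet_shift_d), Sigma)`` where
   ``Sigma_ij = +rho * sigma_i * sigma_j`` for planted positive pairs,
   ``-rho * sigma_i * sigma_j`` for planted negative pairs, 0 elsewhere,
   and ``Sigma_ii = sigma_i**2``;
2. relative abundances ``p = softmax(z)``;
3. counts ``~ Multinomial(depth, p)`` with ``depth ~ log-normal``.

Zero inflation emerges from the heavy-tailed OTU baselines interacting
with finite sequencing depth (the rare biosphere simply fails to be
sampled), not from a separate dropout mask.  The multinomial draw builds
compositional closure into the counts: column sums equal the drawn
depths exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import (
    COPRESENCE,
    EXCLUSION,
    AssociationNetwork,
    GroundTruth,
    OTUTable,
    SampleMetadata,
    canonical_edge,
)

import pandas as pd


@dataclass(frozen=True)
class PlantedPair:
    """A planted association between two OTU indices.

    ``lakes=None`` plants the pair in every group (a core association);
    otherwise only samples from the named lakes carry the correlation.
    """

    a: int
    b: int
    rho: float
    positive: bool = True
    lakes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie in (0,1), got {self.rho}")
        if self.a == self.b:
            raise ValueError("planted pair must join two distinct OTUs")


@dataclass(frozen=True)
class GroupSpec:
    """One host group (lake): sample size and optional diet allocation."""

    lake: str
    continent: str
    n_samples: int
    diet_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("group n_samples must be >= 1")
        if self.diet_counts and sum(self.diet_counts.values()) != self.n_samples:
            raise ValueError(
                f"{self.lake}: diet allocation must sum to n_samples"
            )


@dataclass
class SimConfig:
    """Full parameterization of one synthetic community draw."""

    n_otus: int
    groups: list[GroupSpec]
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    #: multiplicative abundance shift per (otu index, diet); > 0
    diet_shift: dict[tuple[int, str], float] = field(default_factory=dict)
    species_per_diet: int = 3
    #: per-OTU baseline log-abundance ~ baseline_cap - Exponential(scale
    #: = baseline_sd): a log-series-like rank-abundance curve whose heavy
    #: rare tail + finite depth produce the zero inflation of real data,
    #: while the bounded upper tail keeps any single taxon from
    #: dominating the compositional denominator
    baseline_sd: float = 2.5
    baseline_cap: float = 2.0
    #: latent per-OTU log-scale standard deviation sigma_i
    latent_sd: float = 1.0
    #: small per-(group, OTU) baseline jitter so lakes differ mildly
    group_effect_sd: float = 0.25
    #: baselines of planted-pair members are raised to at least this log
    #: abundance (None disables): an association planted on a taxon too
    #: rare to be observed is not a usable ground truth, and inference
    #: only ever runs on the non-rare community
    planted_min_baseline: float | None = 0.0
    depth_median: float = 50_000.0
    depth_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for (i, d), s in self.diet_shift.items():
            if s <= 0:
                raise ValueError(f"diet shift for (otu {i}, {d!r}) must be > 0")
        for p in self.planted_pairs:
            if not (0 <= p.a < self.n_otus and 0 <= p.b < self.n_otus):
                raise ValueError(f"planted pair ({p.a},{p.b}) outside OTU range")

    # -- study-mimicking default ----------------------------------------
    @classmethod
    def study_mimic(cls, seed: int = 0) -> "SimConfig":
        """Default configuration shaped like the study data.

        774 OTUs over nine lakes on two continents (277 samples, the
        study's per-lake sizes), diets assigned only in Tanganyika where
        dietary diversity is concentrated, 40 planted positive pairs
        (10 of them core across all lakes) plus 4 exclusions, and
        eight-fold herbivore/carnivore shifts on a subset of OTUs.
        """
        groups = [
            GroupSpec(
                "Tanganyika", "Africa", 73,
                {"carnivore": 17, "scale-eater": 7, "omnivore": 17,
                 "planktivore": 7, "herbivore": 25},
            ),
            GroupSpec("Barombi Mbo", "Africa", 43),
            GroupSpec("Apoyo", "America", 25),
            GroupSpec("Apoyeque", "America", 25),
            GroupSpec("Xiloa", "America", 43),
            GroupSpec("Masaya", "America", 14),
            GroupSpec("Asososca Leon", "America", 13),
            GroupSpec("Nicaragua", "America", 29),
            GroupSpec("Managua", "America", 12),
        ]
        rng = np.random.default_rng(seed + 774)
        order = rng.permutation(774)
        pairs: list[PlantedPair] = []
        lake_names = [g.lake for g in groups]
        for k in range(40):
            a, b = int(order[2 * k]), int(order[2 * k + 1])
            if k < 10:
                lakes = None  # core: planted everywhere
            else:
                lakes = frozenset(
                    rng.choice(lake_names, size=5, replace=False).tolist()
                )
            pairs.append(PlantedPair(a, b, rho=0.8, positive=True, lakes=lakes))
        for k in range(40, 44):
            a, b = int(order[2 * k]), int(order[2 * k + 1])
            pairs.append(PlantedPair(a, b, rho=0.8, positive=False, lakes=None))
        shifts: dict[tuple[int, str], float] = {}
        shifted = order[100:130]
        for i in shifted[:15]:
            shifts[(int(i), "herbivore")] = 8.0
        for i in shifted[15:]:
            shifts[(int(i), "carnivore")] = 8.0
            shifts[(int(i), "scale-eater")] = 8.0
        return cls(
            n_otus=774, groups=groups, planted_pairs=pairs,
            diet_shift=shifts, seed=seed,
        )


def disjoint_pairs(n_otus: int, n_pairs: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Draw non-overlapping OTU index pairs (keeps the planted covariance
    block-diagonal, hence positive-definite for any rho < 1)."""
    order = rng.permutation(n_otus)
    if 2 * n_pairs > n_otus:
        raise ValueError("not enough OTUs for that many disjoint pairs")
    return [(int(order[2 * k]), int(order[2 * k + 1])) for k in range(n_pairs)]


def _edge_key(cfg: SimConfig, p: PlantedPair) -> tuple[str, str, str]:
    sign = COPRESENCE if p.positive else EXCLUSION
    return canonical_edge(_otu_id(p.a), _otu_id(p.b), sign)


def _otu_id(i: int) -> str:
    return f"OTU-{i:05d}"


_PHYLA = (
    "Proteobacteria", "Firmicutes", "Planctomycetes", "Fusobacteria",
    "Bacteroidetes", "Actinobacteria", "Verrucomicrobia",
)


def _taxonomy_strings(n: int, rng: np.random.Generator) -> list[str]:
    phyla = rng.choice(len(_PHYLA), size=n)
    return [
        f"k__Bacteria; p__{_PHYLA[p]}; c__; o__; f__; g__; s__" for p in phyla
    ]


def _group_cov(cfg: SimConfig, lake: str, sigma: np.ndarray) -> np.ndarray:
    cov = np.diag(sigma**2)
    for p in cfg.planted_pairs:
        if p.lakes is not None and lake not in p.lakes:
            continue
        off = p.rho * sigma[p.a] * sigma[p.b] * (1.0 if p.positive else -1.0)
        cov[p.a, p.b] = cov[p.b, p.a] = off
    return cov


def generate_community(
    config: SimConfig,
) -> tuple[OTUTable, SampleMetadata, GroundTruth]:
    """Draw one synthetic community; same config (incl. seed) -> same output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_otus
    baseline = config.baseline_cap - rng.exponential(config.baseline_sd, size=n)
    # planted pairs share one baseline: an association only manifests in
    # profile-similarity measures when the partners live on a comparable
    # abundance scale, and a pair too rare to observe is no ground truth
    for p in config.planted_pairs:
        baseline[p.b] = baseline[p.a]
    if config.planted_min_baseline is not None and config.planted_pairs:
        planted_members = sorted(
            {p.a for p in config.planted_pairs} | {p.b for p in config.planted_pairs}
        )
        baseline[planted_members] = np.maximum(
            baseline[planted_members], config.planted_min_baseline
        )
    sigma = np.full(n, config.latent_sd)
    taxonomy = _taxonomy_strings(n, rng)
    otu_ids = [_otu_id(i) for i in range(n)]

    counts_cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict[str, str]] = []
    for g in config.groups:
        cov = _group_cov(config, g.lake, sigma)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                "planted covariance is not positive-definite; reduce rho or "
                "the overlap among planted pairs"
            ) from err
        mu_g = baseline + rng.normal(0.0, config.group_effect_sd, size=n)
        diets: list[str] = []
        if g.diet_counts:
            for d, k in g.diet_counts.items():
                diets.extend([d] * k)
        else:
            diets = [""] * g.n_samples
        for j, diet in enumerate(diets):
            mu = mu_g.copy()
            for (i, d), s in config.diet_shift.items():
                if d == diet:
                    mu[i] += np.log(s)
            z = mu + chol @ rng.standard_normal(n)
            z -= z.max()  # softmax stability
            p = np.exp(z)
            p /= p.sum()
            depth = max(
                1,
                int(round(np.exp(rng.normal(np.log(config.depth_median),
                                            config.depth_log_sd)))),
            )
            counts_cols.append(rng.multinomial(depth, p))
            sid = f"{g.lake.replace(' ', '_')}_s{j:03d}"
            sample_ids.append(sid)
            if diet:
                n_sp = max(1, config.species_per_diet)
                sp = f"{g.lake}_{diet}_sp{j % n_sp}"
            else:
                sp = f"{g.lake}_sp{j % max(1, config.species_per_diet)}"
            meta_rows.append(
                {"sample_id": sid, "lake": g.lake, "continent": g.continent,
                 "species": sp, "diet": diet}
            )

    table = OTUTable(
        np.column_stack(counts_cols), otu_ids, sample_ids, taxonomy
    )
    meta = SampleMetadata(
        pd.DataFrame(meta_rows).set_index("sample_id")
    )
    planted = {_edge_key(config, p): p.rho for p in config.planted_pairs}
    core = {_edge_key(config, p) for p in config.planted_pairs if p.lakes is None}
    shifts = {(_otu_id(i), d): s for (i, d), s in config.diet_shift.items()}
    truth = GroundTruth(planted_edges=planted, core_edges=core, diet_effects=shifts)
    return table, meta, truth


@dataclass(frozen=True)
class RecoveryScore:
    """Sign-aware precision/recall of an inferred network vs ground truth.

    ``precision`` is None (undefined) when the network has no edges.
    """

    precision: float | None
    recall: float
    n_true_positive: int
    n_inferred: int
    n_planted: int


def ground_truth_eval(
    net: AssociationNetwork, truth: GroundTruth, otu_universe: Sequence[str] | None = None
) -> RecoveryScore:
    """Score an inferred network against the planted edges, sign-aware."""
    planted = set(truth.planted_edges)
    if otu_universe is not None:
        universe = set(otu_universe)
        stray = [n for n in net.node_ids if n not in universe]
        if stray:
            raise ValueError(f"network node {stray[0]!r} outside OTU universe")
    inferred = net.edge_keys()
    tp = len(inferred & planted)
    precision = tp / len(inferred) if inferred else None
    recall = tp / len(planted) if planted else 0.0
    return RecoveryScore(precision, recall, tp, len(inferred), len(planted))


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Planted edges and diet effects as one tidy TSV."""
    rows = []
    for (a, b, sign), rho in sorted(truth.planted_edges.items()):
        rows.append(
            {"record": "edge", "otu_a": a, "otu_b": b, "sign": sign,
             "rho": rho, "core": (a, b, sign) in truth.core_edges,
             "diet": "", "shift": ""}
        )
    for (otu, diet), s in sorted(truth.diet_effects.items()):
        rows.append(
            {"record": "diet_effect", "otu_a": otu, "otu_b": "", "sign": "",
             "rho": "", "core": "", "diet": diet, "shift": s}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
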