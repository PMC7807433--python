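"""Ensemble co-occurrence network inference.

The estimator follows the CoNet-style ensemble recipe: four association
measures (Pearson, Spearman, Bray-Curtis dissimilarity, symmetrized
Kullback-Leibler dissimilarity) are computed over all OTU pairs of a
column-normalized abundance matrix; candidate edges are the pairs ranked
in every measure's top ``n_top`` for the same direction (copresence or
exclusion); edge significance comes from a permutation null with column
renormalization (the ReBoot safeguard against compositional artifacts)
plus a bootstrap stability screen; the four per-measure p-values are
merged with Brown's method for dependent tests and BH-corrected across
edges.

Polarity alignment
------------------
The measures live on different scales, so each is mapped monotonically
to an *aligned* score in [-1, 1] where +1 means strongest copresence:
correlations are left as-is, Bray-Curtis ``d`` maps to ``1 - 2 d`` and
symmetrized KL ``D`` to ``2 exp(-D) - 1``.  The consensus score of an
edge is the mean aligned score over the four measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    COPRESENCE,
    EXCLUSION,
    AssociationNetwork,
    Edge,
    OTUTable,
)
from .preprocess import KEEP_SUM_ID, column_normalize, occurrence_filter

MEASURES = ("pearson", "spearman", "bray_curtis", "kl")

#: pseudocount for KL row renormalization, as a fraction of the row mass
DEFAULT_EPS_FRAC = 1e-6


@dataclass
class ScoreMatrix:
    """Symmetric OTU x OTU association scores for one measure.

    ``similarity`` is True for correlations (high = copresent) and False
    for the dissimilarities.  The diagonal and undefined pairs are NaN.
    """

    measure: str
    values: np.ndarray
    similarity: bool

    def aligned(self) -> np.ndarray:
        return align_scores(self.measure, self.values)


def align_scores(measure: str, values: np.ndarray | float) -> np.ndarray | float:
    """Map raw measure values to the common [-1, 1] copresence scale."""
    if measure in ("pearson", "spearman"):
        return values
    if measure == "bray_curtis":
        return 1.0 - 2.0 * values
    if measure == "kl":
        return 2.0 * np.exp(-np.asarray(values, dtype=float)) - 1.0
    raise ValueError(f"unknown measure {measure!r}")


def _kl_probabilities(x: np.ndarray, eps_frac: float) -> np.ndarray:
    """Rows rescaled to sum 1 after adding eps_frac of the row mass."""
    x = np.asarray(x, dtype=float)
    mass = x.sum(axis=-1, keepdims=True)
    mass = np.where(mass > 0, mass, 1.0)
    p = x + eps_frac * mass / x.shape[-1]
    return p / p.sum(axis=-1, keepdims=True)


def symmetrized_kl(
    u: np.ndarray, v: np.ndarray, eps_frac: float = 0.0
) -> float:
    """Symmetrized Kullback-Leibler divergence of two abundance rows.

    Rows are rescaled to sum 1 (with the pseudocount convention) first;
    ``D = (KL(p||q) + KL(q||p)) / 2``.
    """
    p = _kl_probabilities(np.asarray(u, dtype=float), eps_frac)
    q = _kl_probabilities(np.asarray(v, dtype=float), eps_frac)
    return float(0.5 * ((p - q) * (np.log(p) - np.log(q))).sum())


def pairwise_association_scores(
    matrix: np.ndarray | pd.DataFrame,
    measure: str,
    eps_frac: float = DEFAULT_EPS_FRAC,
) -> ScoreMatrix:
    """All-pairs association scores between OTU rows.

    Pearson/Spearman are ordinary correlations across samples (constant
    rows yield NaN and are excluded from candidacy); Bray-Curtis is
    ``sum|u-v| / sum(u+v)``; KL is the symmetrized divergence after row
    renormalization with a small pseudocount.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    if measure in ("pearson", "spearman"):
        data = stats.rankdata(x, axis=1) if measure == "spearman" else x
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.corrcoef(data)
        sim = True
    elif measure == "bray_curtis":
        num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
        den = x.sum(axis=1)[:, None] + x.sum(axis=1)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = num / den
        sim = False
    elif measure == "kl":
        p = _kl_probabilities(x, eps_frac)
        logp = np.log(p)
        plogp = (p * logp).sum(axis=1)
        cross = p @ logp.T
        vals = 0.5 * (plogp[:, None] + plogp[None, :] - cross - cross.T)
        vals = np.maximum(0.5 * (vals + vals.T), 0.0)
        sim = False
    else:
        raise ValueError(f"unknown measure {measure!r}")
    np.fill_diagonal(vals, np.nan)
    return ScoreMatrix(measure, vals, sim)


@dataclass
class CandidateEdge:
    """One candidate association awaiting significance assessment."""

    i: int
    j: int
    otu_a: str
    otu_b: str
    direction: str
    raw_scores: dict[str, float]
    aligned_scores: dict[str, float]
    consensus: float
    p_values: dict[str, float] = field(default_factory=dict)
    stable: bool | None = None
    p_merged: float = np.nan
    q: float = np.nan


def select_candidate_edges(
    scores: dict[str, ScoreMatrix],
    otu_ids: list[str],
    n_top: int = 1000,
    mode: str = "both",
    eligible: np.ndarray | None = None,
) -> list[CandidateEdge]:
    """Intersect the four measures' top-ranked pairs, direction-aware.

    Per measure, after polarity alignment, the ``n_top`` highest-ranked
    pairs are copresence candidates and the ``n_top`` lowest-ranked are
    exclusion candidates (skipped in ``copresence_only`` mode): the
    direction is the end of the ranking a pair falls in, mirroring the
    ensemble tool's per-measure edge thresholds.  When the two ends
    would overlap (``2 n_top`` exceeding the number of pairs) a pair
    belongs to the end it sits closer to.  A pair survives iff it is a
    candidate under every measure with the same direction.  Ranking
    ties break by canonical pair order.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if mode not in ("both", "copresence_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if set(scores) != set(MEASURES):
        raise ValueError(f"need all four measures, got {sorted(scores)}")
    p = len(otu_ids)
    iu, ju = np.triu_indices(p, k=1)
    if eligible is not None:
        ok = eligible[iu] & eligible[ju]
        iu, ju = iu[ok], ju[ok]

    aligned = {m: scores[m].aligned()[iu, ju] for m in MEASURES}
    finite = np.ones(len(iu), dtype=bool)
    for m in MEASURES:
        finite &= np.isfinite(aligned[m])

    member: dict[str, np.ndarray] = {}
    n_finite = int(finite.sum())
    for direction in (COPRESENCE, EXCLUSION):
        if direction == EXCLUSION and mode == "copresence_only":
            continue
        in_all = finite.copy()
        for m in MEASURES:
            a = aligned[m]
            idx_fin = np.flatnonzero(finite)
            order = idx_fin[np.argsort(-a[idx_fin], kind="stable")]
            rank = np.empty(len(iu), dtype=int)
            rank[order] = np.arange(len(order))
            if direction == COPRESENCE:
                sel = finite & (rank < n_top) & (rank <= n_finite - 1 - rank)
            else:
                rev = n_finite - 1 - rank
                sel = finite & (rev < n_top) & (rev < rank)
            if m in ("pearson", "spearman"):
                # correlations have a meaningful zero: a copresence must
                # covary positively, an exclusion negatively
                sel &= (a > 0) if direction == COPRESENCE else (a < 0)
            in_all &= sel
        member[direction] = in_all

    out: list[CandidateEdge] = []
    for direction, mask in member.items():
        for k in np.flatnonzero(mask):
            i, j = int(iu[k]), int(ju[k])
            raw = {m: float(scores[m].values[i, j]) for m in MEASURES}
            al = {m: float(aligned[m][k]) for m in MEASURES}
            out.append(
                CandidateEdge(
                    i, j, otu_ids[i], otu_ids[j], direction,
                    raw, al, float(np.mean(list(al.values()))),
                )
            )
    out.sort(key=lambda c: (c.otu_a, c.otu_b, c.direction))
    return out


def _pair_aligned_scores(
    U: np.ndarray, V: np.ndarray, eps_frac: float
) -> dict[str, np.ndarray]:
    """Aligned scores for B row pairs at once; U, V have shape (B, n)."""
    out: dict[str, np.ndarray] = {}
    for measure in ("pearson", "spearman"):
        if measure == "spearman":
            A = stats.rankdata(U, axis=1)
            B = stats.rankdata(V, axis=1)
        else:
            A, B = U, V
        A = A - A.mean(axis=1, keepdims=True)
        B = B - B.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[measure] = (A * B).sum(axis=1) / np.sqrt(
                (A * A).sum(axis=1) * (B * B).sum(axis=1)
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.abs(U - V).sum(axis=1) / (U.sum(axis=1) + V.sum(axis=1))
    out["bray_curtis"] = 1.0 - 2.0 * bc
    P = _kl_probabilities(U, eps_frac)
    Q = _kl_probabilities(V, eps_frac)
    D = 0.5 * ((P - Q) * (np.log(P) - np.log(Q))).sum(axis=1)
    out["kl"] = 2.0 * np.exp(-D) - 1.0
    return out


def _gpd_tail_p(null: np.ndarray, obs: float, tail_frac: float = 0.1) -> float:
    """Tail p-value for ``obs`` beyond all permutation-null draws.

    Fits a generalized Pareto distribution to the exceedances over the
    null's (1 - tail_frac) quantile; the returned p is the tail mass
    beyond ``obs`` (floored at 1e-30 when the fitted support ends below
    the observation).
    """
    fin = null[np.isfinite(null)]
    if fin.size < 50 or fin.std() == 0:
        return 1.0
    thr = float(np.quantile(fin, 1.0 - tail_frac))
    exc = fin[fin > thr] - thr
    if exc.size < 20 or exc.std() == 0:
        return 1.0
    try:
        c, _, scale = stats.genpareto.fit(exc, floc=0)
        p = tail_frac * float(stats.genpareto.sf(obs - thr, c, loc=0, scale=scale))
    except Exception:
        z = (obs - fin.mean()) / fin.std()
        p = float(stats.norm.sf(z))
    return max(p, 1e-30)


def reboot_significance(
    matrix: np.ndarray | pd.DataFrame,
    candidates: list[CandidateEdge],
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
    eps_frac: float = DEFAULT_EPS_FRAC,
) -> list[CandidateEdge]:
    """Permutation p-values with column renormalization, plus bootstrap
    stability, for each candidate edge.

    The null permutes one OTU's values across samples and renormalizes
    every column (so the compositional constraint is re-imposed under
    the null); the one-sided p counts null consensus-direction scores at
    least as extreme as observed, with the +1 correction.  The bootstrap
    resamples samples with replacement; an edge is unstable — and later
    discarded — when the permutation-null mean consensus lies inside the
    bootstrap 95% percentile interval.

    Also attaches, per edge, the per-measure null p-value vectors needed
    by Brown's covariance estimate (shared permutations across measures).
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives too coarse a p-value resolution")
    x = np.asarray(matrix, dtype=float)
    n = x.shape[1]
    col_sums = x.sum(axis=0)
    rng = np.random.default_rng(seed)

    perm_idx = rng.permuted(
        np.broadcast_to(np.arange(n), (n_perm, n)).copy(), axis=1
    )
    boot_idx = rng.integers(0, n, size=(n_boot, n))

    for cand in candidates:
        u, v = x[cand.i], x[cand.j]
        # permutation null: permute u, renormalize columns
        u_perm = u[perm_idx]
        s = col_sums[None, :] - u[None, :] + u_perm
        s = np.where(s > 0, s, np.nan)
        null = _pair_aligned_scores(u_perm / s, np.broadcast_to(v, u_perm.shape) / s, eps_frac)
        # bootstrap: resample samples with replacement (columns travel whole)
        boot = _pair_aligned_scores(u[boot_idx], v[boot_idx], eps_frac)

        sign = 1.0 if cand.direction == COPRESENCE else -1.0
        null_p: dict[str, np.ndarray] = {}
        for m in MEASURES:
            obs = cand.aligned_scores[m]
            nl = np.where(np.isfinite(null[m]), null[m], -sign * np.inf)
            n_extreme = int(np.sum(sign * nl >= sign * obs))
            p_emp = (n_extreme + 1) / (n_perm + 1)
            if n_extreme == 0:
                # beyond Monte-Carlo resolution: extend with a
                # generalized-Pareto fit to the null's upper tail
                # (peaks-over-threshold), which stays calibrated for
                # skewed permutation nulls
                p_emp = min(p_emp, _gpd_tail_p(sign * nl, sign * obs))
            cand.p_values[m] = float(p_emp)
            # null p of each replicate within its own null distribution
            r = stats.rankdata(sign * nl, method="min")
            null_p[m] = (n_perm - r + 1.0) / (n_perm + 1.0)
        cand.null_p = null_p  # type: ignore[attr-defined]

        null_cons = np.nanmean(np.column_stack([null[m] for m in MEASURES]), axis=1)
        boot_cons = np.nanmean(np.column_stack([boot[m] for m in MEASURES]), axis=1)
        boot_cons = boot_cons[np.isfinite(boot_cons)]
        if boot_cons.size == 0:
            cand.stable = False
        else:
            lo, hi = np.percentile(boot_cons, [2.5, 97.5])
            cand.stable = not (lo <= np.nanmean(null_cons) <= hi)
    return candidates


def brown_merge(
    pvals: np.ndarray | list[float],
    null_pvals: np.ndarray | None = None,
    cov: np.ndarray | None = None,
    n_perm: int | None = None,
) -> float:
    """Brown's method for combining k dependent one-sided p-values.

    ``X = -2 sum ln p`` is approximated as ``c * chi2(k')`` with
    ``c = Var(X) / (2 E[X])`` and ``k' = 2 E[X]^2 / Var(X)``, where
    ``E[X] = 2k`` and ``Var(X) = 4k + 2 sum_{i<j} cov_ij``.  The
    pairwise covariances of ``-2 ln p`` are estimated from the
    per-measure permutation null p-value vectors (``null_pvals``, shape
    (k, n_perm)) unless an explicit ``cov`` matrix is given; with zero
    covariance the merge reduces exactly to Fisher's method.
    """
    p = np.asarray(pvals, dtype=float)
    k = p.size
    if np.any(p == 0):
        if n_perm is None:
            raise ValueError("p = 0 requires n_perm for clamping")
        warnings.warn("p = 0 clamped to 1/(n_perm+1)", stacklevel=2)
        p = np.maximum(p, 1.0 / (n_perm + 1))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if k == 1:
        return float(p[0])
    X = float(-2.0 * np.log(p).sum())
    E = 2.0 * k
    if cov is None:
        if null_pvals is None:
            cov_sum = 0.0
        else:
            nl = -2.0 * np.log(np.clip(np.asarray(null_pvals, dtype=float), 1e-300, 1.0))
            C = np.cov(nl)
            cov_sum = float(C[np.triu_indices(k, 1)].sum())
    else:
        cov_sum = float(np.asarray(cov)[np.triu_indices(k, 1)].sum())
    var = 4.0 * k + 2.0 * cov_sum
    var = max(var, 1e-12)
    c = var / (2.0 * E)
    k_prime = 2.0 * E * E / var
    return float(stats.chi2.sf(X / c, k_prime))


def bh_adjust(
    pvals: np.ndarray | list[float], m_total: int | None = None
) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserved.

    ``m_total`` sets the number of hypotheses when the supplied p-values
    are only the smallest of a larger family (every untested member
    implicitly has p = 1); with the default it equals ``len(pvals)``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if m_total is None or m_total <= p.size:
        return multipletests(p, method="fdr_bh")[1]
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_total / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def merge_and_adjust(
    candidates: list[CandidateEdge], n_perm: int, n_pairs: int | None = None
) -> list[CandidateEdge]:
    """Brown-merge each candidate's four p-values, then BH across edges.

    ``n_pairs`` is the number of OTU pairs examined during candidate
    selection; using it as the BH family size keeps the FDR honest with
    respect to the selection step (candidates are picked as the extreme
    tail of the very statistics being tested).
    """
    for c in candidates:
        null_p = getattr(c, "null_p", None)
        nl = None if null_p is None else np.array([null_p[m] for m in MEASURES])
        c.p_merged = brown_merge(
            [c.p_values[m] for m in MEASURES], null_pvals=nl, n_perm=n_perm
        )
    q = bh_adjust([c.p_merged for c in candidates], m_total=n_pairs)
    for c, qi in zip(candidates, q):
        c.q = float(qi)
    return candidates


def build_network(
    candidates: list[CandidateEdge],
    taxonomy: dict[str, str] | None = None,
    alpha: float = 0.05,
    name: str = "",
) -> AssociationNetwork:
    """Keep stable candidates with q < alpha; nodes are induced by edges."""
    edges = [
        Edge(c.otu_a, c.otu_b, c.direction, c.consensus, c.p_merged, c.q)
        for c in candidates
        if c.q < alpha and c.stable and KEEP_SUM_ID not in (c.otu_a, c.otu_b)
    ]
    return AssociationNetwork(edges=edges, taxonomy=taxonomy or {}, name=name)


# ---------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------


class CoOccurrenceModel:
    """Ensemble co-occurrence network estimator for one dataset.

    Parameters
    ----------
    matrix
        Column-normalized relative-abundance DataFrame (OTUs x samples);
        a keep-sum composite row may be present and is excluded from
        edge candidacy while still counting toward column totals.
    taxonomy
        Optional OTU id -> lineage string map carried onto the network.
    n_top, mode
        Candidate selection: per-measure list depth and whether to keep
        exclusion edges ("both") or only copresence ("copresence_only").

    Examples
    --------
    >>> model = CoOccurrenceModel.from_otu_table(table, name="Tanganyika")
    >>> res = model.fit(n_perm=1000, n_boot=1000, seed=1)
    >>> res.network.n_edges  # doctest: +SKIP
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        taxonomy: dict[str, str] | None = None,
        n_top: int = 1000,
        mode: str = "both",
        eps_frac: float = DEFAULT_EPS_FRAC,
        name: str = "",
    ) -> None:
        self.matrix = matrix
        self.taxonomy = taxonomy or {}
        self.n_top = n_top
        self.mode = mode
        self.eps_frac = eps_frac
        self.name = name
        self.otu_ids = [str(i) for i in matrix.index]
        self.eligible = np.array([o != KEEP_SUM_ID for o in self.otu_ids])

    @classmethod
    def from_otu_table(
        cls,
        table: OTUTable,
        min_occurrence_frac: float = 0.31,
        keep_sum: bool = True,
        n_top: int = 1000,
        mode: str = "both",
        name: str = "",
    ) -> "CoOccurrenceModel":
        """Occurrence-filter, column-normalize and wrap an OTU table."""
        filtered = occurrence_filter(table, min_occurrence_frac, keep_sum=keep_sum)
        norm = column_normalize(filtered)
        tax = dict(zip(filtered.otu_ids, filtered.taxonomy))
        return cls(norm, taxonomy=tax, n_top=n_top, mode=mode, name=name)

    def scores(self) -> dict[str, ScoreMatrix]:
        return {
            m: pairwise_association_scores(self.matrix, m, self.eps_frac)
            for m in MEASURES
        }

    def fit(
        self,
        n_perm: int = 1000,
        n_boot: int = 1000,
        alpha: float = 0.05,
        seed: int | None = None,
    ) -> "NetworkResults":
        scores = self.scores()
        candidates = select_candidate_edges(
            scores, self.otu_ids, self.n_top, self.mode, self.eligible
        )
        candidates = reboot_significance(
            self.matrix, candidates, n_perm, n_boot, seed, self.eps_frac
        )
        n_elig = int(self.eligible.sum())
        candidates = merge_and_adjust(
            candidates, n_perm, n_pairs=n_elig * (n_elig - 1) // 2
        )
        net = build_network(candidates, self.taxonomy, alpha, self.name)
        return NetworkResults(self, candidates, net, alpha, seed)


class NetworkResults:
    """Fitted co-occurrence network with its evidence tables."""

    def __init__(
        self,
        model: CoOccurrenceModel,
        candidates: list[CandidateEdge],
        network: AssociationNetwork,
        alpha: float,
        seed: int | None,
    ) -> None:
        self.model = model
        self.candidates = candidates
        self.network = network
        self.alpha = alpha
        self.seed = seed

    def candidate_table(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            row = {
                "otu_a": c.otu_a, "otu_b": c.otu_b, "direction": c.direction,
                "consensus": c.consensus, "p_merged": c.p_merged,
                "q": c.q, "stable": c.stable,
            }
            row.update({f"score_{m}": c.raw_scores[m] for m in MEASURES})
            row.update({f"p_{m}": c.p_values.get(m, np.nan) for m in MEASURES})
            rows.append(row)
        return pd.DataFrame(rows)

    def topology(self, seed: int = 0):
        from .topology import global_topology

        return global_topology(self.network, seed=seed)

    def summary(self, seed: int = 0) -> pd.DataFrame:
        """One Table-1-shaped row of dataset and network descriptors."""
        pos, neg = self.network.edge_counts_by_sign()
        row = {
            "dataset": self.model.name,
            "n_samples": self.model.matrix.shape[1],
            "n_otus": int(self.model.eligible.sum()),
            "n_nodes": self.network.n_nodes,
            "n_edges": self.network.n_edges,
            "n_edges_pos": pos,
            "n_edges_neg": neg,
        }
        if self.network.n_edges:
            topo = self.topology(seed=seed)
            row.update(
                {
                    "mean_degree": topo.mean_degree,
                    "clustering": topo.clustering_coefficient,
                    "path_length": topo.path_length,
                    "density": topo.density,
                    "n_modules": topo.n_modules,
                    "modularity": topo.modularity,
                }
            )
        return pd.DataFrame([row])
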