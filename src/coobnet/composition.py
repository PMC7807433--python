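"""Compositional analysis of host-trait (diet) effects on OTU abundances.

Count data from amplicon sequencing are compositional: only relative
information is meaningful.  This module therefore works in log-ratio
space: zeros are imputed with the count-zero-multiplicative (CZM)
scheme, compositions are clr-transformed (so the implicit geometry is
Aitchison's), ordination is a covariance PCA of the clr matrix,
group separation is tested with a PERMANOVA that admits a nested
species factor, and per-OTU differential abundance uses Dirichlet
Monte-Carlo effect sizes with Welch t-tests (ALDEx-style).

All matrices here are samples x OTUs (the transpose of
:class:`~coobnet.datatypes.OTUTable` counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AssociationNetwork
from .inference import bh_adjust


# ---------------------------------------------------------------------
# zero imputation and clr
# ---------------------------------------------------------------------


def czm_impute(counts: np.ndarray | pd.DataFrame, label: float = 0.65) -> np.ndarray:
    """Count-zero-multiplicative replacement; returns compositions.

    Zero cells of sample *j* become ``delta_j = label / depth_j`` (a
    fraction of the detection limit ``1/depth``); nonzero cells are the
    observed proportions multiplicatively shrunk by ``1 - z_j*delta_j``
    (``z_j`` = number of zeros) so each sample still sums to 1.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    depth = x.sum(axis=1)
    if np.any(depth == 0):
        raise ValueError(f"sample {int(np.argmax(depth == 0))} has all-zero counts")
    zeros = x == 0
    n_zero = zeros.sum(axis=1)
    delta = label / depth
    shrink = 1.0 - n_zero * delta
    if np.any(shrink <= 0):
        raise ValueError("imputed mass exceeds 1; lower the label parameter")
    comp = (x / depth[:, None]) * shrink[:, None]
    comp[zeros] = np.broadcast_to(delta[:, None], x.shape)[zeros]
    return comp


def clr_transform(comp: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Centered log-ratio: ln(x / geometric row mean); rows sum to 0."""
    x = np.asarray(comp, dtype=float)
    if np.any(x <= 0):
        raise ValueError("clr requires strictly positive compositions")
    logx = np.log(x)
    out = logx - logx.mean(axis=1, keepdims=True)
    if isinstance(comp, pd.DataFrame):
        return pd.DataFrame(out, index=comp.index, columns=comp.columns)
    return out


def aitchison_distance(clr: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Euclidean distances between clr rows (= Aitchison distances)."""
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(np.asarray(clr, dtype=float), metric="euclidean"))


# ---------------------------------------------------------------------
# PCA biplot
# ---------------------------------------------------------------------


@dataclass
class PCABiplot:
    """Covariance PCA of a clr matrix (the Aitchison biplot)."""

    sample_scores: pd.DataFrame
    otu_loadings: pd.DataFrame
    explained_variance: np.ndarray


def pca_biplot(clr: pd.DataFrame | np.ndarray) -> PCABiplot:
    """Column-centered, unscaled SVD of the clr matrix.

    Sample scores are ``U S`` and OTU loadings the right singular
    vectors; components are oriented so each one's largest-magnitude
    loading is positive (deterministic sign convention).  Euclidean
    distances among full-rank scores equal Aitchison distances.
    """
    X = np.asarray(clr, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    scores = U * s
    var = s**2
    expl = var / var.sum() if var.sum() > 0 else var
    cols = [f"PC{k + 1}" for k in range(len(s))]
    s_idx = clr.index if isinstance(clr, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    o_idx = clr.columns if isinstance(clr, pd.DataFrame) else pd.RangeIndex(X.shape[1])
    return PCABiplot(
        pd.DataFrame(scores, index=s_idx, columns=cols),
        pd.DataFrame(Vt.T, index=o_idx, columns=cols),
        expl,
    )


# ---------------------------------------------------------------------
# PERMANOVA with an optional nested factor
# ---------------------------------------------------------------------


def _ss_within(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def _pseudo_f(
    d2: np.ndarray, primary: np.ndarray, nested: np.ndarray | None
) -> tuple[float, dict[str, tuple[int, float]]]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    a = len(np.unique(primary))
    ss_w_primary = _ss_within(d2, primary)
    ss_primary = ss_total - ss_w_primary
    if nested is None:
        df_res = n - a
        ss_res = ss_w_primary
        parts = {"primary": (a - 1, ss_primary), "residual": (df_res, ss_res)}
    else:
        cells = np.unique(nested)
        b = len(cells)
        ss_w_cells = _ss_within(d2, nested)
        parts = {
            "primary": (a - 1, ss_primary),
            "nested": (b - a, ss_w_primary - ss_w_cells),
            "residual": (n - b, ss_w_cells),
        }
        df_res, ss_res = parts["residual"]
    df1 = a - 1
    if df_res <= 0 or ss_res <= 0:
        return float("inf"), parts
    f = (ss_primary / df1) / (ss_res / df_res)
    return float(f), parts


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    r_squared: dict[str, float]
    table: pd.DataFrame
    pairwise: pd.DataFrame | None = None


def permanova(
    dist: np.ndarray,
    primary_factor: np.ndarray | pd.Series,
    nested_factor: np.ndarray | pd.Series | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    strategy: str = "free",
    pairwise: bool = False,
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix.

    Sequential sum-of-squares partition (primary factor first, the
    nested factor's increment second); the pseudo-F for the primary
    factor is tested against the residual under free permutation of
    sample labels (``strategy="free"``) or permutation of whole
    nested-factor blocks (``strategy="blocks"``).  ``pairwise`` adds
    two-level contrasts with BH correction across contrasts.
    """
    d = np.asarray(dist, dtype=float)
    primary, plev = pd.factorize(pd.Series(primary_factor).astype(str))
    levels, counts = np.unique(primary, return_counts=True)
    if len(levels) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 levels with >= 2 samples each")
    nested = None
    if nested_factor is not None:
        nested, _ = pd.factorize(pd.Series(nested_factor).astype(str))
        for cell in np.unique(nested):
            if len(np.unique(primary[nested == cell])) > 1:
                raise ValueError("nested factor levels must not span primary levels")
    d2 = d**2
    f_obs, parts = _pseudo_f(d2, primary, nested)
    ss_total = sum(ss for _, ss in parts.values())
    rng = np.random.default_rng(seed)
    n = d.shape[0]
    count = 0
    for _ in range(n_perm):
        if strategy == "free" or nested is None:
            perm = rng.permutation(n)
            f_p, _ = _pseudo_f(d2, primary[perm], None if nested is None else nested[perm])
        elif strategy == "blocks":
            cells = np.unique(nested)
            cell_primary = np.array(
                [primary[nested == c][0] for c in cells]
            )
            shuffled = cell_primary[rng.permutation(len(cells))]
            new_primary = np.empty_like(primary)
            for c, lab in zip(cells, shuffled):
                new_primary[nested == c] = lab
            f_p, _ = _pseudo_f(d2, new_primary, nested)
        else:
            raise ValueError(f"unknown permutation strategy {strategy!r}")
        if f_p >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    r2 = {k: ss / ss_total for k, (_, ss) in parts.items()}
    table = pd.DataFrame(
        {
            "df": {k: df for k, (df, _) in parts.items()},
            "sum_sq": {k: ss for k, (_, ss) in parts.items()},
            "R2": r2,
        }
    )
    result = PermanovaResult(f_obs, float(p), r2, table)
    if pairwise:
        rows = []
        for i in range(len(plev)):
            for j in range(i + 1, len(plev)):
                mask = np.isin(primary, [i, j])
                sub = permanova(
                    d[np.ix_(mask, mask)],
                    primary[mask],
                    None if nested is None else nested[mask],
                    n_perm=n_perm,
                    seed=None if seed is None else seed + 1000 + i * 97 + j,
                    strategy=strategy,
                )
                rows.append(
                    {"level_a": plev[i], "level_b": plev[j],
                     "pseudo_f": sub.pseudo_f, "p": sub.p_value}
                )
        pw = pd.DataFrame(rows)
        pw["q"] = bh_adjust(pw["p"].values)
        result.pairwise = pw
    return result


# ---------------------------------------------------------------------
# ALDEx-style effect sizes
# ---------------------------------------------------------------------


def aldex_effect(
    counts: np.ndarray | pd.DataFrame,
    group_labels: np.ndarray | pd.Series,
    levels: tuple[str, str] | None = None,
    n_mc: int = 128,
    seed: int | None = None,
    otu_ids: list[str] | None = None,
    p_summary: str = "mean",
) -> pd.DataFrame:
    """Dirichlet Monte-Carlo differential-abundance effect sizes.

    Per instance, each sample's composition is drawn from
    ``Dirichlet(counts + 0.5)`` and clr-transformed; per OTU the
    between-group difference of means is divided by the larger of the
    two within-group dispersions (median absolute pairwise clr
    difference within a group), and a Welch t-test gives a p-value.
    The effect is the median ratio over instances; positive effect
    means relatively more abundant in ``levels[1]``.  Welch p-values
    are summarized across instances (mean by default) then
    BH-corrected across OTUs.
    """
    X = np.asarray(counts, dtype=float)
    labels = pd.Series(group_labels).astype(str).values
    if levels is None:
        levels = tuple(sorted(set(labels)))  # type: ignore[assignment]
    if len(levels) != 2:
        raise ValueError("exactly two group levels required")
    mask_a = labels == levels[0]
    mask_b = labels == levels[1]
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    keep = mask_a | mask_b
    if not keep.all():
        X, mask_a, mask_b = X[keep], mask_a[keep], mask_b[keep]
    if n_mc < 16:
        warnings.warn("n_mc < 16: effect estimates will be noisy", stacklevel=2)

    idx_a = np.flatnonzero(mask_a)
    idx_b = np.flatnonzero(mask_b)
    ia, ja = np.triu_indices(len(idx_a), k=1)
    ib, jb = np.triu_indices(len(idx_b), k=1)
    rng = np.random.default_rng(seed)
    n_otus = X.shape[1]
    ratios = np.empty((n_mc, n_otus))
    diffs = np.empty((n_mc, n_otus))
    wins = np.empty((n_mc, n_otus))
    pvals = np.empty((n_mc, n_otus))
    for t in range(n_mc):
        g = rng.standard_gamma(X + 0.5)
        comp = g / g.sum(axis=1, keepdims=True)
        logc = np.log(comp)
        clr = logc - logc.mean(axis=1, keepdims=True)
        ca, cb = clr[idx_a], clr[idx_b]
        diff = cb.mean(axis=0) - ca.mean(axis=0)
        disp_a = np.median(np.abs(ca[ia] - ca[ja]), axis=0)
        disp_b = np.median(np.abs(cb[ib] - cb[jb]), axis=0)
        win = np.maximum(disp_a, disp_b)
        ratios[t] = diff / np.maximum(win, 1e-12)
        diffs[t] = diff
        wins[t] = win
        pvals[t] = stats.ttest_ind(cb, ca, equal_var=False, axis=0).pvalue
    welch_p = np.mean(pvals, axis=0) if p_summary == "mean" else np.median(pvals, axis=0)
    out = pd.DataFrame(
        {
            "diff_btw": np.median(diffs, axis=0),
            "diff_win": np.median(wins, axis=0),
            "effect": np.median(ratios, axis=0),
            "welch_p": welch_p,
            "welch_q": bh_adjust(welch_p),
        }
    )
    if otu_ids is not None:
        out.index = pd.Index(otu_ids, name="otu_id")
    elif isinstance(counts, pd.DataFrame):
        out.index = counts.columns
    return out


# ---------------------------------------------------------------------
# per-group node summaries for network mapping
# ---------------------------------------------------------------------


def diet_node_summary(
    clr: pd.DataFrame,
    groups: pd.Series,
    net: AssociationNetwork,
) -> pd.DataFrame:
    """Median clr per network node per group, with a filled/hollow flag.

    A node is "filled" in a group when its median clr exceeds 0, i.e.
    the OTU sits above the sample geometric mean; ties (median exactly
    0) are hollow.  ``groups`` may hold any per-sample labels (diet or
    species), indexed like ``clr``'s rows.
    """
    nodes = net.node_ids
    missing = [n for n in nodes if n not in clr.columns]
    if missing:
        raise ValueError(f"network node {missing[0]!r} absent from clr matrix")
    groups = pd.Series(groups).astype(str)
    rows = []
    for g, idx in groups.groupby(groups).groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {g!r} has no samples")
        med = clr.loc[idx, nodes].median(axis=0)
        for node in nodes:
            m = float(med[node])
            rows.append(
                {"group": g, "otu_id": node, "median_clr": m, "filled": m > 0}
            )
    return pd.DataFrame(rows)
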