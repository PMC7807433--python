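"""Procrustes-matched force-directed layouts.

To display group-level abundance patterns on a network while keeping the
spatial intuition of an ordination, many force-directed
(Fruchterman-Reingold) layouts are generated under different seeds and
the one whose Procrustes superimposition onto the PCA node coordinates
leaves the smallest residual sum of squares is kept (and returned in
the target's frame, i.e. rotated/scaled like the ordination).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import AssociationNetwork


def fr_layout(net: AssociationNetwork | nx.Graph, seed: int = 0) -> pd.DataFrame:
    """2-D Fruchterman-Reingold coordinates, deterministic given seed."""
    g = net.to_networkx() if isinstance(net, AssociationNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_nodes() == 1:
        return pd.DataFrame([[0.0, 0.0]], index=list(g.nodes), columns=["x", "y"])
    pos = nx.spring_layout(g, seed=seed, dim=2)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        [pos[n] for n in nodes], index=nodes, columns=["x", "y"]
    )


@dataclass
class ProcrustesFit:
    ss: float
    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        centered = coords - coords.mean(axis=0)
        return self.scale * centered @ self.rotation + self.translation


def procrustes_ss(
    source: np.ndarray,
    target: np.ndarray,
    allow_reflection: bool = True,
) -> ProcrustesFit:
    """Similarity-Procrustes fit of ``source`` onto ``target``.

    Finds the translation, uniform scale and rotation (reflection
    allowed by default) minimizing the residual sum of squared
    distances; rows of the two configurations must correspond.
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape or X.shape[0] < 2:
        raise ValueError("configurations must share shape with >= 2 points")
    Yc = Y - Y.mean(axis=0)
    if not np.any(Yc):
        raise ValueError("degenerate target: all points coincide")
    Xc = X - X.mean(axis=0)
    normX2 = float((Xc**2).sum())
    if normX2 == 0:
        raise ValueError("degenerate source: all points coincide")
    U, s, Vt = np.linalg.svd(Xc.T @ Yc)
    d = np.ones(len(s))
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        d[-1] = -1.0
    R = U @ np.diag(d) @ Vt
    trace = float((s * d).sum())
    scale = trace / normX2
    ss = float((Yc**2).sum()) - trace**2 / normX2
    return ProcrustesFit(max(ss, 0.0), R, scale, Y.mean(axis=0))


@dataclass
class MatchedLayout:
    seed: int
    coords: pd.DataFrame
    ss: float


def match_layout(
    net: AssociationNetwork | nx.Graph,
    target_coords: pd.DataFrame,
    n_seeds: int = 5000,
    allow_reflection: bool = True,
) -> MatchedLayout:
    """Best Procrustes-matched FR layout over seeds 1..n_seeds.

    Returns the transformed layout of the seed with minimal residual
    SS (ties broken by the smallest seed).
    """
    g = net.to_networkx() if isinstance(net, AssociationNetwork) else net
    nodes = sorted(g.nodes)
    missing = [n for n in nodes if n not in target_coords.index]
    if missing:
        raise ValueError(f"target coordinates missing node {missing[0]!r}")
    target = target_coords.loc[nodes, ["x", "y"]].values \
        if set(("x", "y")) <= set(target_coords.columns) \
        else target_coords.loc[nodes].iloc[:, :2].values
    best: MatchedLayout | None = None
    for seed in range(1, n_seeds + 1):
        coords = fr_layout(g, seed=seed)
        fit = procrustes_ss(coords.loc[nodes].values, target, allow_reflection)
        if best is None or fit.ss < best.ss:
            fitted = fit.apply(coords.loc[nodes].values)
            best = MatchedLayout(
                seed, pd.DataFrame(fitted, index=nodes, columns=["x", "y"]), fit.ss
            )
    assert best is not None
    return best
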