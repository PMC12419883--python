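"""Phylogenetic eigenvector bases.

The weighted influence matrix ``B_w = B @ diag(w)`` (with per-edge weight
``w = sqrt(psi) * phi ** ((1 - a) / 2)``) is column-centered over the training
tips and decomposed by SVD.  The left singular vectors are the phylogenetic
eigenvectors used as regression descriptors; the right singular vectors and
singular values let any point on the training tree — in particular a held-out
tip's attachment point — be scored in the same coordinate system.

With steepness ``a = 0`` the uncentered weighted Gram matrix is exactly the
Brownian-motion covariance (shared root-path length) between tips; ``a = 1``
makes every edge count equally regardless of length (punctuated change).  The
global rate ``psi`` rescales all singular values and cancels out of scores
and predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .phylo_graph import InfluenceMatrix, TipLocation

__all__ = [
    "EdgeWeighting",
    "PEMBasis",
    "WeightingError",
    "DegenerateBasisError",
    "edge_weights",
    "build_pem",
    "location_scores",
    "estimate_steepness",
]


class WeightingError(ValueError):
    """Steepness/rate parameters outside their domain."""


class DegenerateBasisError(ValueError):
    """No singular value exceeds the rank tolerance."""


@dataclass(frozen=True)
class EdgeWeighting:
    """Global edge-weighting rule ``w(phi) = sqrt(psi) * phi**((1-a)/2)``.

    ``a`` (steepness) interpolates between Brownian-like, length-proportional
    influence at 0 and length-independent influence at 1; ``psi`` is a global
    rate with no effect on downstream predictions.
    """

    a: float = 0.0
    psi: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.a <= 1.0:
            raise WeightingError(f"steepness a={self.a} outside [0, 1]")
        if not self.psi > 0.0:
            raise WeightingError(f"rate psi={self.psi} must be positive")

    def weights(self, lengths: np.ndarray) -> np.ndarray:
        lengths = np.asarray(lengths, dtype=float)
        if np.any(lengths < 0):
            raise WeightingError("negative edge length")
        exponent = (1.0 - self.a) / 2.0
        if exponent == 0.0:
            # phi**0 == 1 for every phi, including zero-length edges.
            return np.full(lengths.shape, np.sqrt(self.psi))
        return np.sqrt(self.psi) * lengths**exponent


def edge_weights(lengths, weighting: EdgeWeighting) -> np.ndarray:
    return weighting.weights(lengths)


@dataclass
class PEMBasis:
    """Centered orthonormal eigenbasis of a weighted influence matrix."""

    U: np.ndarray                    # training tips x k, orthonormal columns
    d: np.ndarray                    # singular values, descending, > 0
    V: np.ndarray                    # edges x k
    means: np.ndarray                # column means of the weighted matrix
    weighting: EdgeWeighting
    tip_labels: list[str]
    infl: InfluenceMatrix = field(repr=False)

    @property
    def k(self) -> int:
        return self.U.shape[1]

    def to_dict(self) -> dict:
        return {
            "U": self.U.tolist(),
            "d": self.d.tolist(),
            "V": self.V.tolist(),
            "means": self.means.tolist(),
            "steepness": self.weighting.a,
            "rate": self.weighting.psi,
            "tip_labels": list(self.tip_labels),
        }


def build_pem(
    infl: InfluenceMatrix,
    weighting: EdgeWeighting | None = None,
    rel_tol: float = 1e-10,
) -> PEMBasis:
    """Decompose the centered, weighted influence matrix.

    Components whose singular value falls below ``rel_tol`` times the largest
    are discarded (rank deficiency vs round-off).  Column signs are fixed by
    making the largest-magnitude entry of each eigenvector positive, so the
    basis is bit-reproducible for identical input.
    """
    if weighting is None:
        weighting = EdgeWeighting()
    if infl.n_tips < 3:
        raise DegenerateBasisError(
            f"need at least 3 training tips, got {infl.n_tips}"
        )
    w = weighting.weights(infl.edge_lengths)
    bw = infl.matrix * w
    means = bw.mean(axis=0)
    centered = bw - means
    u, d, vt = np.linalg.svd(centered, full_matrices=False)
    if d.size == 0 or d[0] <= 0.0:
        raise DegenerateBasisError("weighted influence matrix is all zero")
    keep = d > rel_tol * d[0]
    u, d, v = u[:, keep], d[keep], vt[keep].T
    if d.size == 0:
        raise DegenerateBasisError("no singular value above tolerance")
    # Deterministic sign: largest-magnitude entry of each column positive.
    for j in range(d.size):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
            v[:, j] = -v[:, j]
    return PEMBasis(
        U=u,
        d=d,
        V=v,
        means=means,
        weighting=weighting,
        tip_labels=list(infl.tip_labels),
        infl=infl,
    )


def location_scores(basis: PEMBasis, loc: TipLocation) -> np.ndarray:
    """Score a tip location in the basis coordinate system.

    The target's influence row over the training edges carries the full
    weight ``w(phi)`` for every edge strictly above the attachment edge on the
    root path, the weight of the traversed portion ``w(traversed)`` on the
    attachment edge, and 0 elsewhere.  The pendant edge contributes nothing
    to point scores.  Scores are the centered row projected through
    ``V @ diag(1/d)``, so a training tip re-scored at its own position
    recovers its own row of ``U``.
    """
    infl = basis.infl
    edges = infl.tree.edges()
    if not 0 <= loc.edge_index < len(edges):
        raise IndexError(f"edge index {loc.edge_index} out of range")
    attach = edges[loc.edge_index]
    if not 0.0 <= loc.traversed <= attach.length + 1e-12:
        raise ValueError(
            f"traversed length {loc.traversed} outside attachment edge "
            f"of length {attach.length}"
        )
    index = {id(e): j for j, e in enumerate(edges)}
    w = basis.weighting.weights(infl.edge_lengths)
    row = np.zeros(len(edges))
    node = attach.parent
    while node is not None and node.parent is not None:
        row[index[id(node)]] = w[index[id(node)]]
        node = node.parent
    if loc.traversed > 0.0:
        row[loc.edge_index] = basis.weighting.weights(
            np.array([loc.traversed])
        )[0]
    return (row - basis.means) @ basis.V / basis.d


def estimate_steepness(
    infl: InfluenceMatrix,
    y: np.ndarray,
    psi: float = 1.0,
    grid: int = 21,
) -> float:
    """Maximum-likelihood steepness on [0, 1] for a response vector.

    The response (GLS-centered) is modelled as Gaussian with covariance
    ``sigma2 * B_w @ B_w.T``; ``sigma2`` is profiled out and ``a`` is found by
    bounded search seeded from a coarse grid.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (infl.n_tips,):
        raise ValueError("response length does not match training tips")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if infl.n_tips < 4:
        raise ValueError("need at least 4 tips to estimate steepness")

    n = infl.n_tips
    ones = np.ones(n)

    def negloglik(a: float) -> float:
        w = EdgeWeighting(a=a, psi=psi).weights(infl.edge_lengths)
        bw = infl.matrix * w
        cov = bw @ bw.T
        try:
            chol = np.linalg.cholesky(cov + 1e-12 * np.trace(cov) / n * np.eye(n))
        except np.linalg.LinAlgError:
            return np.inf
        solve = lambda b: np.linalg.solve(chol.T, np.linalg.solve(chol, b))
        mu = ones @ solve(y) / (ones @ solve(ones))
        r = y - mu
        sigma2 = r @ solve(r) / n
        if sigma2 <= 0:
            return np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        return 0.5 * (n * np.log(sigma2) + logdet + n * (1 + np.log(2 * np.pi)))

    candidates = np.linspace(0.0, 1.0, grid)
    best = min(candidates, key=negloglik)
    lo, hi = max(0.0, best - 0.1), min(1.0, best + 0.1)
    res = minimize_scalar(negloglik, bounds=(lo, hi), method="bounded")
    a_hat = float(res.x) if res.fun <= negloglik(best) else float(best)
    return min(1.0, max(0.0, a_hat))
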