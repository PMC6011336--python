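"""Non-metric multidimensional scaling of subjects.

Subjects are embedded in k=2 dimensions from their pairwise distances on
informative-site methylation profiles, by Kruskal's rank-based stress
minimization (isotonic regression of disparities inside SMACOF
majorization, as provided by scikit-learn).  Stress is Kruskal stress-1,
in [0, 1].  The first restart is initialized from classical (metric)
MDS for reproducibility; the remaining restarts are random, and the best
final stress wins.  Group confidence ellipses use the Gaussian
chi-square(2) quantile at the requested level (default 90%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from .datamodel import MethylationMatrix, ValidationError

__all__ = [
    "NMDSResult",
    "Ellipse",
    "subject_distance",
    "classical_mds",
    "nmds_embed",
    "confidence_ellipse",
]

_METRICS = {"euclidean", "braycurtis", "cityblock", "cosine"}


def subject_distance(
    matrix: MethylationMatrix, metric: str = "euclidean"
) -> np.ndarray:
    """Symmetric subjects x subjects distance matrix on percent scores.

    Euclidean by default (methylation scores are interval-scaled);
    Bray-Curtis is offered for parity with ecology-style ordination
    tooling.
    """
    if matrix.n_subjects < 3:
        raise ValidationError("ordination needs at least 3 subjects")
    if metric not in _METRICS:
        raise ValueError(f"unsupported metric {metric!r}")
    return squareform(pdist(matrix.scores.T, metric=metric))


def classical_mds(distances: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS via double-centered eigendecomposition;
    used as the deterministic NMDS starting configuration."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.maximum(vals[order], 0.0)
    return vecs[:, order] * np.sqrt(vals)


@dataclass
class Ellipse:
    group: str
    center: np.ndarray
    cov: np.ndarray
    level: float
    radius_scale: float  # sqrt(chi2.ppf(level, 2))
    degenerate: bool = False


@dataclass
class NMDSResult:
    coords: np.ndarray  # subjects x k, centered at the origin
    stress: float  # Kruskal stress-1
    converged: bool
    n_restarts: int
    restart_stresses: list[float] = field(default_factory=list)


def nmds_embed(
    distances: np.ndarray,
    k: int = 2,
    n_restarts: int = 4,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> NMDSResult:
    """Kruskal NMDS embedding; best of ``n_restarts`` retained.

    Non-convergence is reported through ``converged=False`` with the
    best coordinates found, never as an exception.  Deterministic given
    ``seed``.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T) or np.abs(np.diag(d)).max() > 1e-12:
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")

    rng = np.random.default_rng(seed)
    best_coords, best_stress, best_iter = None, np.inf, 0
    restart_stresses: list[float] = []
    for r in range(n_restarts):
        init = classical_mds(d, k) if r == 0 else None
        state = int(rng.integers(0, 2**31 - 1))
        coords, stress, n_iter = smacof(
            d,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            random_state=state,
            normalized_stress=True,
            return_n_iter=True,
        )
        restart_stresses.append(float(stress))
        if stress < best_stress:
            best_coords, best_stress, best_iter = coords, float(stress), n_iter
    assert best_coords is not None
    best_coords = best_coords - best_coords.mean(axis=0)
    return NMDSResult(
        coords=best_coords,
        stress=best_stress,
        converged=best_iter < max_iter,
        n_restarts=n_restarts,
        restart_stresses=restart_stresses,
    )


def confidence_ellipse(
    coords: np.ndarray,
    labels: np.ndarray,
    level: float = 0.90,
) -> dict[str, Ellipse]:
    """Per-group Gaussian confidence ellipses in the 2-D embedding.

    Center is the group mean; the shape matrix is the group covariance,
    to be drawn at Mahalanobis radius ``sqrt(chi2.ppf(level, 2))``.  A
    rank-deficient covariance flags the ellipse degenerate (it collapses
    to a segment or point).
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValidationError("ellipses are defined for 2-D embeddings")
    out: dict[str, Ellipse] = {}
    scale = float(np.sqrt(stats.chi2.ppf(level, df=2)))
    for g in np.unique(labels):
        pts = coords[labels == g]
        if pts.shape[0] < 3:
            raise ValidationError(
                f"group {g!r} needs at least 3 subjects for an ellipse"
            )
        cov = np.cov(pts.T)
        degenerate = bool(np.linalg.matrix_rank(cov, tol=1e-12) < 2)
        out[str(g)] = Ellipse(
            group=str(g),
            center=pts.mean(axis=0),
            cov=cov,
            level=level,
            radius_scale=scale,
            degenerate=degenerate,
        )
    return out
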