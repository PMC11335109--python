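"""Fuzzy c-means clustering of infant sleep quality.

Hand-written alternating optimization of the standard FCM objective

    J(U, V) = sum_i sum_k  u_ik^m  ||x_k - v_i||^2,

subject to each sample's memberships summing to one.  Setting the partial
derivatives to zero gives the classical coupled updates: memberships from
inverse relative squared distances raised to 1/(m-1), centers as
membership^m-weighted means.  Cluster count is chosen by the mean silhouette
of the hardened (argmax) labels, and for c=3 the clusters are mapped to an
ordinal good/moderate/poor sleep-quality label by their center coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_score

from .schema import SLEEP_QUALITY_LABELS, ConfigError, DyadlinkError

logger = logging.getLogger(__name__)

__all__ = ["FCMConfig", "FCMResult", "fcm_fit", "silhouette_curve", "label_sleep_quality"]


@dataclass(frozen=True)
class FCMConfig:
    """Settings of one FCM fit.

    ``m`` is the fuzzifier (m -> 1+ approaches hard k-means; 2 is the
    conventional default).  Convergence is declared when the largest absolute
    change of any membership between successive iterations drops below
    ``tol``.  ``n_restarts`` random row-stochastic initializations are run and
    the solution with the lowest final objective is kept.
    """

    c: int = 3
    m: float = 2.0
    tol: float = 1e-6
    max_iter: int = 300
    seed: int = 0
    n_restarts: int = 5

    def validate(self) -> None:
        if self.c < 2:
            raise ConfigError(f"cluster count c must be >= 2, got {self.c}")
        if self.m <= 1.0:
            raise ConfigError(f"fuzzifier m must be > 1, got {self.m}")
        if self.tol <= 0:
            raise ConfigError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1 or self.n_restarts < 1:
            raise ConfigError("max_iter and n_restarts must be >= 1")


@dataclass
class FCMResult:
    """Converged state of one FCM run (the best of the restarts)."""

    membership: np.ndarray          # (n, c), rows sum to 1
    centers: np.ndarray             # (c, d)
    objective_trajectory: np.ndarray  # J after each iteration
    hard_labels: np.ndarray         # argmax memberships, ties -> lowest index
    n_iter: int
    converged: bool

    @property
    def objective(self) -> float:
        return float(self.objective_trajectory[-1])


def _memberships_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update: u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1)).

    Samples coinciding with a center get membership 1 there (0 elsewhere);
    coincidence with several centers splits evenly among them.
    """
    n, c = d2.shape
    zero = d2 <= 0.0
    U = np.empty((n, c))
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
    ok = ~zero.any(axis=1)
    U[ok] = inv[ok] / inv[ok].sum(axis=1, keepdims=True)
    if not ok.all():
        rows = ~ok
        U[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    return U


def _objective(U: np.ndarray, d2: np.ndarray, m: float) -> float:
    return float(np.sum(U**m * d2))


def fcm_fit(X: np.ndarray, config: FCMConfig) -> FCMResult:
    """Fit fuzzy c-means on a (min-max normalized) feature matrix.

    Alternates center and membership updates from a seeded random
    row-stochastic membership matrix until the memberships stabilize.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ConfigError("X must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise ConfigError("X contains non-finite values")
    n, _ = X.shape
    c, m = config.c, config.m
    if n <= c:
        raise ConfigError(f"need more samples than clusters (n={n}, c={c})")
    if np.allclose(X, X[0]):
        raise DyadlinkError("all rows identical: clustering is degenerate")

    rng = np.random.default_rng(config.seed)
    best: FCMResult | None = None
    for _ in range(config.n_restarts):
        U = rng.dirichlet(np.ones(c), size=n)
        trajectory: list[float] = []
        converged = False
        it = 0
        for it in range(1, config.max_iter + 1):
            Um = U**m
            centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            U_new = _memberships_from_distances(d2, m)
            trajectory.append(_objective(U_new, d2, m))
            delta = float(np.abs(U_new - U).max())
            U = U_new
            if delta < config.tol:
                converged = True
                break
        result = FCMResult(
            membership=U,
            centers=centers,
            objective_trajectory=np.asarray(trajectory),
            hard_labels=np.argmax(U, axis=1),
            n_iter=it,
            converged=converged,
        )
        if best is None or result.objective < best.objective:
            best = result
    assert best is not None
    if not best.converged:
        logger.warning("FCM did not converge within %d iterations", config.max_iter)
    return best


def silhouette_curve(
    X: np.ndarray, c_range: range | list[int], config: FCMConfig | None = None
) -> list[tuple[int, float]]:
    """Mean silhouette of the hardened FCM labels for each candidate c.

    A candidate whose hardened labels leave a cluster empty (or collapse to a
    single cluster) is reported as NaN and logged rather than dropped, so the
    curve always covers the requested range.
    """
    config = config or FCMConfig()
    X = np.asarray(X, dtype=float)
    curve: list[tuple[int, float]] = []
    for c in c_range:
        if not 2 <= c <= len(X) - 1:
            raise ConfigError(f"candidate c={c} outside [2, n-1]")
        result = fcm_fit(X, FCMConfig(
            c=c, m=config.m, tol=config.tol, max_iter=config.max_iter,
            seed=config.seed, n_restarts=config.n_restarts,
        ))
        labels = result.hard_labels
        if len(np.unique(labels)) < c:
            logger.warning("c=%d: hardened labels leave an empty cluster", c)
            curve.append((c, float("nan")))
            continue
        curve.append((c, float(silhouette_score(X, labels))))
    return curve


def best_cluster_count(curve: list[tuple[int, float]]) -> int:
    """Argmax of the silhouette curve, ignoring NaN entries."""
    finite = [(s, c) for c, s in curve if np.isfinite(s)]
    if not finite:
        raise DyadlinkError("silhouette curve has no defined entries")
    # Ties resolve to the smaller (more parsimonious) cluster count.
    return max(finite, key=lambda t: (t[0], -t[1]))[1]


def label_sleep_quality(
    result: FCMResult, feature_names: list[str] | tuple[str, ...]
) -> np.ndarray:
    """Map a 3-cluster FCM result to ordinal good/moderate/poor labels.

    Clusters are ranked by center sleep time descending (longer uninterrupted
    sleep = better quality), ties broken by center wake count ascending.
    Returns one label string per sample.
    """
    if result.centers.shape[0] != 3:
        raise ConfigError(
            f"sleep-quality labelling requires c=3 clusters, got {result.centers.shape[0]}"
        )
    names = list(feature_names)
    for required in ("sleep_time", "wake_times"):
        if required not in names:
            raise ConfigError(f"feature_names must include '{required}'")
    st = result.centers[:, names.index("sleep_time")]
    wt = result.centers[:, names.index("wake_times")]
    order = sorted(range(3), key=lambda i: (-st[i], wt[i]))
    rank_of_cluster = {cluster: rank for rank, cluster in enumerate(order)}
    labels = np.array(SLEEP_QUALITY_LABELS, dtype=object)
    return labels[[rank_of_cluster[int(h)] for h in result.hard_labels]]
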