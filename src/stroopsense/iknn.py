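"""Informative k-nearest-neighbors (i-KNN) noisy-point filtering.

Each labelled point x_i is scored by how *informative* it is for its own
class.  For a neighbor count k, the k nearest neighbors of x_i receive an
informativeness

    P(x_j | x_i) = (1 / C_i) * d(x_j, x_i)^eta * Lambda(x_j)^(1 - eta)

where d is a Gaussian similarity kernel, eta is the fraction of x_i's k
neighbors sharing x_j's label, Lambda down-weights neighbors that sit close
to opposite-class members of the neighborhood, and C_i normalizes the k
values to sum to one.  The neighbors are ranked by informativeness, the
top-M labels are majority-voted into a prediction for x_i, and a binary
score records disagreement with the true label.  Averaging the score over
k in {3, 5, 7, 10} and M in [1, k] (25 settings) gives the mean score
s-bar in [0, 1]: points with high s-bar are isolated instances of one
class inside a dense region of the other, i.e. the least informative
points, and the worst fraction of them is discarded.

The literal kernel exp(-||dx||^2) underflows for standardized vectors in
tens to hundreds of dimensions (||dx||^2 grows linearly with dimension),
collapsing every similarity to zero.  The default therefore rescales the
squared distance by the median pairwise squared distance (the classic
median heuristic); the literal unit bandwidth remains available for
low-dimensional work and oracle checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import round_half_up
from .errors import (
    ClassDepletionError,
    DegenerateLabelsError,
    InvalidParameterError,
)

__all__ = [
    "NeighborhoodConfig",
    "InformativenessScores",
    "FilterResult",
    "kernel_distance",
    "lambda_weight",
    "informativeness",
    "mean_informativeness_score",
    "filter_points",
]

DEFAULT_K_VALUES = (3, 5, 7, 10)


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Settings for the i-KNN scoring and filtering pass.

    ``scope`` selects which points are candidates for discarding:
    ``"all-points"`` ranks every point (the worst 5% of the whole dataset
    go), while ``"cg-only"`` restricts discarding to control-group points
    (the reading in which only unvetted controls can be outliers).  Both
    readings are legitimate; all-points is the default.
    """

    k_values: tuple[int, ...] = DEFAULT_K_VALUES
    bandwidth_rule: str = "median-heuristic"  # or "literal" (bandwidth 1)
    standardize: bool = True
    discard_fraction: float = 0.05
    scope: str = "all-points"  # or "cg-only"

    def validate(self, n_points: int | None = None) -> None:
        if not self.k_values or any(k < 1 for k in self.k_values):
            raise InvalidParameterError("every k must be >= 1")
        if n_points is not None and any(k >= n_points for k in self.k_values):
            raise InvalidParameterError("every k must be < number of points")
        if not 0.0 <= self.discard_fraction < 1.0:
            raise InvalidParameterError("discard_fraction must lie in [0, 1)")
        if self.bandwidth_rule not in ("median-heuristic", "literal"):
            raise InvalidParameterError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if self.scope not in ("all-points", "cg-only"):
            raise InvalidParameterError(f"unknown scope {self.scope!r}")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """The (k, M) enumeration; 25 pairs under the defaults."""
        return [(k, m) for k in self.k_values for m in range(1, k + 1)]


@dataclass
class InformativenessScores:
    """Per-point binary scores for each (k, M) setting and their mean s-bar."""

    pairs: list[tuple[int, int]]
    scores: np.ndarray  # (n_points, n_pairs) binary
    s_bar: np.ndarray  # (n_points,) mean over pairs
    bandwidth: float


@dataclass
class FilterResult:
    retained: np.ndarray  # indices kept, in input order
    discarded: np.ndarray  # indices discarded, worst first
    scores: InformativenessScores
    config: NeighborhoodConfig = field(repr=False)


def kernel_distance(xi: np.ndarray, xj: np.ndarray, bandwidth: float = 1.0) -> float:
    """Gaussian similarity exp(-||xi - xj||^2 / bandwidth), in (0, 1].

    Bandwidth 1 reproduces the literal kernel exp(-||dx||^2).
    """
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    if xi.shape != xj.shape:
        raise ValueError(f"shape mismatch: {xi.shape} vs {xj.shape}")
    if bandwidth <= 0:
        raise InvalidParameterError("bandwidth must be positive")
    return float(np.exp(-np.sum((xi - xj) ** 2) / bandwidth))


def lambda_weight(
    j: int, neighbors: np.ndarray, labels: np.ndarray, similarities: np.ndarray
) -> float:
    """Weight of neighbor ``j`` against the opposite-class members of the
    neighborhood: the product over the k neighbors x_n of
    (1 - d(x_j, x_n) * (1 - delta(y_j, y_n))).

    Same-label neighbors contribute a factor of 1; an opposite-class
    neighbor coincident with x_j (similarity 1) zeroes the weight.

    Parameters
    ----------
    j : index of the candidate neighbor (a member of ``neighbors``)
    neighbors : the k neighbor indices of the reference point
    labels : class labels for all points
    similarities : full pairwise similarity matrix d
    """
    yj = labels[j]
    out = 1.0
    for n in neighbors:
        if labels[n] != yj:
            out *= 1.0 - similarities[j, n]
    return out


def _pairwise_sq_dists(x: np.ndarray) -> np.ndarray:
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return d2


def _bandwidth(d2: np.ndarray, rule: str) -> float:
    if rule == "literal":
        return 1.0
    off = d2[np.triu_indices_from(d2, k=1)]
    med = float(np.median(off)) if off.size else 1.0
    return med if med > 0 else 1.0


def _prepare(
    x: np.ndarray, config: NeighborhoodConfig
) -> tuple[np.ndarray, np.ndarray, float]:
    """Standardize, compute squared distances and the similarity matrix."""
    x = np.asarray(x, float)
    if config.standardize:
        mean = x.mean(axis=0)
        std = x.std(axis=0)
        std[std == 0] = 1.0  # constant features carry no distance information
        x = (x - mean) / std
    d2 = _pairwise_sq_dists(x)
    bw = _bandwidth(d2, config.bandwidth_rule)
    sim = np.exp(-d2 / bw)
    return d2, sim, bw


def informativeness(
    i: int,
    k: int,
    x: np.ndarray,
    labels: np.ndarray,
    config: NeighborhoodConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Informativeness P(x_j | x_i) of the k nearest neighbors of point i.

    Returns ``(neighbor_indices, probabilities)`` with the neighbors in
    increasing-distance order and the probabilities summing to one.  The
    point is never its own neighbor.
    """
    config = config or NeighborhoodConfig()
    labels = np.asarray(labels)
    d2, sim, _ = _prepare(np.asarray(x, float), config)
    nbrs = _neighbor_indices(d2, i, k)
    probs = _informativeness_from_sim(i, nbrs, labels, sim)
    return nbrs, probs


def _neighbor_indices(d2: np.ndarray, i: int, k: int) -> np.ndarray:
    """k nearest neighbors of i by squared distance, self excluded, index ties stable."""
    order = np.argsort(d2[i], kind="stable")
    order = order[order != i]
    return order[:k]


def _informativeness_from_sim(
    i: int, nbrs: np.ndarray, labels: np.ndarray, sim: np.ndarray
) -> np.ndarray:
    k = len(nbrs)
    nbr_labels = labels[nbrs]
    mass = np.empty(k)
    for pos, j in enumerate(nbrs):
        eta = float(np.mean(nbr_labels == labels[j]))
        lam = lambda_weight(j, nbrs, labels, sim)
        mass[pos] = sim[i, j] ** eta * lam ** (1.0 - eta)
    total = mass.sum()
    if total == 0.0:
        warnings.warn(
            f"all informativeness masses underflowed to 0 for point {i}; "
            "falling back to uniform weights",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full(k, 1.0 / k)
    return mass / total


def mean_informativeness_score(
    x: np.ndarray, labels: np.ndarray, config: NeighborhoodConfig | None = None
) -> InformativenessScores:
    """Binary disagreement scores over the (k, M) grid and their mean s-bar.

    For each (k, M): rank x_i's k neighbors by informativeness, majority-
    vote the top-M labels into a prediction, and score 1 on disagreement
    with the true label.  Vote ties (even M with split labels) resolve to
    the label of the single most informative neighbor.
    """
    config = config or NeighborhoodConfig()
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    n = len(x)
    config.validate(n_points=n)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise DegenerateLabelsError(f"need exactly two classes, got {len(classes)}")

    d2, sim, bw = _prepare(x, config)
    pairs = config.pairs
    scores = np.zeros((n, len(pairs)))
    for i in range(n):
        col = 0
        for k in config.k_values:
            nbrs = _neighbor_indices(d2, i, k)
            probs = _informativeness_from_sim(i, nbrs, labels, sim)
            # rank by informativeness, ties resolved toward the nearer neighbor
            ranked = sorted(range(k), key=lambda t: (-probs[t], t))
            ranked_labels = labels[nbrs[ranked]]
            for m in range(1, k + 1):
                top = ranked_labels[:m]
                counts = {c: int(np.sum(top == c)) for c in classes}
                best = max(counts.values())
                leaders = [c for c in classes if counts[c] == best]
                vote = leaders[0] if len(leaders) == 1 else ranked_labels[0]
                scores[i, col] = 0.0 if vote == labels[i] else 1.0
                col += 1
    return InformativenessScores(
        pairs=pairs, scores=scores, s_bar=scores.mean(axis=1), bandwidth=bw
    )


def filter_points(
    x: np.ndarray,
    labels: np.ndarray,
    config: NeighborhoodConfig | None = None,
    control_label="CG",
) -> FilterResult:
    """Discard the least informative fraction of the points.

    Points are sorted by s-bar descending (ties broken by stable input
    order) and the top ``round(discard_fraction * n)`` are discarded; under
    ``scope="cg-only"`` only control-labelled points are candidates and the
    count is taken against the control-group size.  Refuses to empty a
    class.
    """
    config = config or NeighborhoodConfig()
    labels = np.asarray(labels)
    scores = mean_informativeness_score(x, labels, config)
    n = len(labels)
    if config.scope == "cg-only":
        candidates = np.flatnonzero(labels == control_label)
        n_discard = round_half_up(config.discard_fraction * len(candidates))
    else:
        candidates = np.arange(n)
        n_discard = round_half_up(config.discard_fraction * n)
    order = candidates[np.argsort(-scores.s_bar[candidates], kind="stable")]
    discarded = order[:n_discard]
    retained = np.setdiff1d(np.arange(n), discarded)
    for c in np.unique(labels):
        if not np.any(labels[retained] == c):
            raise ClassDepletionError(f"discarding would remove every {c!r} point")
    return FilterResult(
        retained=retained, discarded=discarded, scores=scores, config=config
    )
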