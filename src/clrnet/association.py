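"""Pairwise gene–gene association estimators.

Seven symmetric estimators over a pair of expression profiles of length m:

``pearson``
    Product-moment correlation.
``spearman``
    Pearson on average ranks.
``kendall``
    Kendall's tau-b (tie corrected), via scipy.
``theil_sen``
    A bounded, symmetric association built from the Theil–Sen median
    pairwise slope: both profiles are standardized, the median slope is
    taken in each direction, and the score is the sign-consistent geometric
    mean of the two, clipped to [−1, 1].  (Theil–Sen proper estimates a
    slope, not a correlation; the symmetrization is this package's
    construction.)
``weighted_rank``
    Weighted product-moment correlation of the two rank vectors with
    top-emphasis weights, by default w_k = m − r_k + 1 averaged over the
    two profiles' ranks so the score stays symmetric in (x, y).
``mutual_information``
    Plug-in MI in bits from an equal-width joint histogram; default bin
    count ⌈√m⌉ clamped to [2, 20].
``mic``
    Maximal information coefficient: maximal grid-normalized mutual
    information over grid resolutions a×b ≤ B(m) = m^0.6, with the usual
    dynamic-programming column optimization against an equipartitioned
    row axis, candidate-clump cap c = 15.

Every correlation-type estimator returns 0 (not NaN) for a zero-variance
profile: a constant probe carries no association evidence, and downstream
matrices must stay finite.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._kernels import median_pairwise_slope, mic_kernel
from .partition import partition_rows

__all__ = [
    "AssociationMatrix",
    "METHODS",
    "pearson",
    "spearman",
    "kendall",
    "theil_sen_assoc",
    "weighted_rank",
    "mutual_information",
    "mic",
    "default_mi_bins",
    "association_matrix",
]


@dataclass
class AssociationMatrix:
    """Symmetric gene × gene similarity scores for one estimator."""

    gene_ids: list[str]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        n = len(self.gene_ids)
        if self.scores.shape != (n, n):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match {n} genes"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# scalar estimators


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("profiles must be 1-D vectors")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("profiles must be finite")
    return x, y


def _require_m(x, m_min: int) -> None:
    if x.shape[0] < m_min:
        raise ValueError(f"need at least {m_min} samples, got {x.shape[0]}")


def _corr_centered(xc: np.ndarray, yc: np.ndarray) -> float:
    nx = math.sqrt(float(xc @ xc))
    ny = math.sqrt(float(yc @ yc))
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(float(xc @ yc) / (nx * ny), -1.0, 1.0))


def pearson(x, y) -> float:
    """Product-moment correlation in [−1, 1]; 0 for zero-variance input."""
    x, y = _pair(x, y)
    _require_m(x, 3)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    return _corr_centered(x - x.mean(), y - y.mean())


def spearman(x, y) -> float:
    """Pearson correlation of average ranks (ties get average ranks)."""
    x, y = _pair(x, y)
    _require_m(x, 3)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return _corr_centered(rx - rx.mean(), ry - ry.mean())


def kendall(x, y) -> float:
    """Kendall's tau-b in [−1, 1]; 0 for zero-variance input."""
    x, y = _pair(x, y)
    _require_m(x, 3)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    tau = stats.kendalltau(x, y).statistic
    if not math.isfinite(tau):
        return 0.0
    return float(np.clip(tau, -1.0, 1.0))


def _standardize(v: np.ndarray) -> np.ndarray | None:
    if np.all(v == v[0]):
        return None
    sd = v.std()
    if sd == 0.0:  # distinct values whose spread underflows
        return None
    return (v - v.mean()) / sd


def theil_sen_assoc(x, y) -> float:
    """Symmetric bounded Theil–Sen association in [−1, 1].

    β_yx is the median of all pairwise slopes of standardized y on
    standardized x (pairs with equal x excluded) and β_xy symmetrically;
    the score is sign(β_yx)·min(1, √(β_yx·β_xy)), or 0 when the two
    directional slopes disagree in sign or either profile is constant.
    """
    x, y = _pair(x, y)
    _require_m(x, 3)
    xs = _standardize(x)
    ys = _standardize(y)
    if xs is None or ys is None:
        return 0.0
    b_yx, n1 = median_pairwise_slope(xs, ys)
    b_xy, n2 = median_pairwise_slope(ys, xs)
    if n1 == 0 or n2 == 0:
        return 0.0
    prod = b_yx * b_xy
    if prod <= 0.0:
        return 0.0
    return float(math.copysign(min(1.0, math.sqrt(prod)), b_yx))


def _weighted_rank_from_ranks(
    rx: np.ndarray, ry: np.ndarray, weights: np.ndarray | None
) -> float:
    m = rx.shape[0]
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return 0.0
    if weights is None:
        w = ((m - rx + 1.0) + (m - ry + 1.0)) / 2.0
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != rx.shape:
            raise ValueError("weights must match profile length")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    ws = w.sum()
    mx = float((w * rx).sum() / ws)
    my = float((w * ry).sum() / ws)
    dx = rx - mx
    dy = ry - my
    vx = float((w * dx * dx).sum())
    vy = float((w * dy * dy).sum())
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = float((w * dx * dy).sum())
    return float(np.clip(cov / math.sqrt(vx * vy), -1.0, 1.0))


def weighted_rank(x, y, weights=None) -> float:
    """Weighted Spearman with top-emphasis weights.

    With ``weights=None`` each observation gets w_k = m − r_k + 1 averaged
    over its rank in x and its rank in y (so the highest-expressed samples
    dominate and the score is symmetric in its arguments).  A custom
    positive weight vector may be supplied instead.
    """
    x, y = _pair(x, y)
    _require_m(x, 3)
    return _weighted_rank_from_ranks(stats.rankdata(x), stats.rankdata(y), weights)


def default_mi_bins(m: int) -> int:
    """Default histogram resolution: ⌈√m⌉ clamped to [2, 20]."""
    return int(min(20, max(2, math.ceil(math.sqrt(m)))))


def _bin_indices(v: np.ndarray, bins: int) -> np.ndarray:
    lo = v.min()
    rng = v.max() - lo
    if rng == 0.0:
        return np.zeros(v.shape[0], dtype=np.int64)
    idx = ((v - lo) / rng * bins).astype(np.int64)
    return np.minimum(idx, bins - 1)


def _mi_from_indices(ix: np.ndarray, iy: np.ndarray, bins: int) -> float:
    m = ix.shape[0]
    joint = np.bincount(ix * bins + iy, minlength=bins * bins).astype(np.float64)
    joint /= m
    joint = joint.reshape(bins, bins)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def mutual_information(x, y, bins: int | None = None) -> float:
    """Plug-in mutual information in bits from an equal-width joint histogram."""
    x, y = _pair(x, y)
    if bins is None:
        bins = default_mi_bins(x.shape[0])
    if bins < 2:
        raise ValueError(f"need at least 2 bins, got {bins}")
    return _mi_from_indices(_bin_indices(x, bins), _bin_indices(y, bins), bins)


def mic(x, y, alpha: float = 0.6, c: float = 15.0) -> float:
    """Maximal information coefficient in [0, 1].

    The grid budget is B = max(m^alpha, 4) (the floor keeps the 2×2 grid
    admissible at very small m); grids are optimized by equipartitioning
    one axis and dynamic programming on the other, in both orientations.
    """
    x, y = _pair(x, y)
    _require_m(x, 3)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    B = max(float(x.shape[0]) ** alpha, 4.0)
    return float(
        mic_kernel(np.ascontiguousarray(x), np.ascontiguousarray(y), B, float(c))
    )


# ---------------------------------------------------------------------------
# full-matrix assembly


class _PairwiseEstimator:
    """Estimator with an optional per-gene precompute for matrix assembly."""

    def __init__(self, **params):
        if params:
            raise TypeError(f"unexpected parameters {sorted(params)}")

    def prepare(self, values: np.ndarray):
        return values

    def score(self, aux, i: int, j: int) -> float:  # pragma: no cover - abstract
        raise NotImplementedError


class _CenteredCorr(_PairwiseEstimator):
    transform = staticmethod(lambda rows: rows)

    def prepare(self, values):
        t = self.transform(values)
        centered = t - t.mean(axis=1, keepdims=True)
        norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
        norms[np.all(t == t[:, :1], axis=1)] = 0.0  # exactly constant rows
        return centered, norms

    def score(self, aux, i, j):
        centered, norms = aux
        if norms[i] == 0.0 or norms[j] == 0.0:
            return 0.0
        return float(
            np.clip(float(centered[i] @ centered[j]) / (norms[i] * norms[j]), -1.0, 1.0)
        )


class _Pearson(_CenteredCorr):
    pass


class _Spearman(_CenteredCorr):
    transform = staticmethod(lambda rows: np.apply_along_axis(stats.rankdata, 1, rows))


class _Kendall(_PairwiseEstimator):
    def score(self, aux, i, j):
        return kendall(aux[i], aux[j])


class _TheilSen(_PairwiseEstimator):
    def prepare(self, values):
        const = np.all(values == values[:, :1], axis=1)
        sd = values.std(axis=1, keepdims=True)
        safe = np.where(sd == 0.0, 1.0, sd)
        std = (values - values.mean(axis=1, keepdims=True)) / safe
        return std, const

    def score(self, aux, i, j):
        std, const = aux
        if const[i] or const[j]:
            return 0.0
        b_yx, n1 = median_pairwise_slope(std[i], std[j])
        b_xy, n2 = median_pairwise_slope(std[j], std[i])
        if n1 == 0 or n2 == 0:
            return 0.0
        prod = b_yx * b_xy
        if prod <= 0.0:
            return 0.0
        return float(math.copysign(min(1.0, math.sqrt(prod)), b_yx))


class _WeightedRank(_PairwiseEstimator):
    def __init__(self, weights=None):
        self.weights = weights

    def prepare(self, values):
        return np.apply_along_axis(stats.rankdata, 1, values)

    def score(self, aux, i, j):
        return _weighted_rank_from_ranks(aux[i], aux[j], self.weights)


class _MutualInformation(_PairwiseEstimator):
    def __init__(self, bins=None):
        self.bins = bins

    def prepare(self, values):
        bins = self.bins if self.bins is not None else default_mi_bins(values.shape[1])
        if bins < 2:
            raise ValueError(f"need at least 2 bins, got {bins}")
        idx = np.stack([_bin_indices(row, bins) for row in values])
        return idx, bins

    def score(self, aux, i, j):
        idx, bins = aux
        return _mi_from_indices(idx[i], idx[j], bins)


class _Mic(_PairwiseEstimator):
    def __init__(self, alpha=0.6, c=15.0):
        self.alpha = alpha
        self.c = c

    def prepare(self, values):
        return np.ascontiguousarray(values), np.all(
            values == values[:, :1], axis=1
        ), max(float(values.shape[1]) ** self.alpha, 4.0)

    def score(self, aux, i, j):
        values, const, B = aux
        if const[i] or const[j]:
            return 0.0
        return float(mic_kernel(values[i], values[j], B, float(self.c)))


METHODS: dict[str, type[_PairwiseEstimator]] = {
    "pearson": _Pearson,
    "spearman": _Spearman,
    "kendall": _Kendall,
    "theil_sen": _TheilSen,
    "weighted_rank": _WeightedRank,
    "mutual_information": _MutualInformation,
    "mic": _Mic,
}


def association_matrix(
    matrix, method: str, workers: int = 1, **params
) -> AssociationMatrix:
    """Assemble the symmetric association matrix for one estimator.

    Every unordered pair is computed exactly once, following the balanced
    row-partition plan; the result is identical for any worker count (the
    plan fixes which row owns which pair, and workers only split rows).

    Parameters
    ----------
    matrix : ExpressionMatrix
        Validated expression matrix with ≥ 2 genes and ≥ 3 samples.
    method : str
        One of ``METHODS``.
    workers : int
        Thread count; purely an execution hint, never changes the result.
    **params
        Estimator parameters (``bins`` for mutual_information, ``weights``
        for weighted_rank, ``alpha``/``c`` for mic).
    """
    if method not in METHODS:
        raise ValueError(
            f"unknown method {method!r}; valid methods: {', '.join(sorted(METHODS))}"
        )
    n, m = matrix.values.shape
    if n < 2:
        raise ValueError(f"need at least 2 genes, got {n}")
    if m < 3:
        raise ValueError(f"need at least 3 samples, got {m}")
    est = METHODS[method](**params)
    aux = est.prepare(matrix.values)
    plan = partition_rows(n, min(workers, n))
    scores = np.zeros((n, n), dtype=np.float64)

    def run_rows(rows):
        out = []
        for i in rows:
            for j in plan.assignment[i]:
                out.append((i, int(j), est.score(aux, i, int(j))))
        return out

    if plan.p == 1:
        results = run_rows(range(n))
    else:
        with ThreadPoolExecutor(max_workers=plan.p) as pool:
            futures = [
                pool.submit(run_rows, plan.rows_for_worker(w)) for w in range(plan.p)
            ]
            results = [t for f in futures for t in f.result()]
    for i, j, s in results:
        scores[i, j] = s
        scores[j, i] = s
    return AssociationMatrix(list(matrix.gene_ids), scores, method)
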