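"""CLR background correction, pair-level z-scoring, and network thresholding.

The context likelihood of relatedness (CLR) transform corrects each raw
association score against the empirical background of its two genes: for
gene i, let μ_i and σ_i be the mean and standard deviation of row i's
off-diagonal scores; the rectified per-gene score is
u_i(j) = max(0, (A_ij − μ_i)/σ_i), and the CLR score combines both genes in
quadrature, z_ij = √(u_i(j)² + u_j(i)²).

Because the full-network distribution of CLR scores is close to normal,
pair-level cutoffs are applied on standardized scores: the off-diagonal
values are centred and scaled by their own empirical mean and standard
deviation, and edges below the preset cutoff are discarded (ties at the
cutoff are retained).  Genome-scale case cutoffs such as 4.3 and 3.8 live
on this standardized scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .association import AssociationMatrix, association_matrix
from .io import EdgeList, ExpressionMatrix
from .partition import PartitionPlan, ordered_pair_count, pair_count, partition_rows

__all__ = [
    "ZScoreNetwork",
    "PartitionPlan",
    "pair_count",
    "ordered_pair_count",
    "partition_rows",
    "clr_transform",
    "standardize_scores",
    "threshold_network",
    "network_pair_scores",
    "infer_network",
]


@dataclass
class ZScoreNetwork:
    """Symmetric pair scores after CLR correction.

    ``standardized`` distinguishes raw CLR output (non-negative by
    construction) from the standardized stage, whose values are centred
    and may be negative.
    """

    gene_ids: list[str]
    z: np.ndarray
    method: str
    standardized: bool = False

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        n = len(self.gene_ids)
        if self.z.shape != (n, n):
            raise ValueError(f"z shape {self.z.shape} does not match {n} genes")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def clr_transform(assoc: AssociationMatrix) -> ZScoreNetwork:
    """Apply the CLR background correction to a symmetric association matrix.

    Rows with zero background variance contribute u = 0 (a flat background
    carries no relatedness evidence), so an all-equal association matrix
    maps to an all-zero network.
    """
    A = assoc.scores
    n = assoc.n_genes
    if not np.array_equal(A, A.T):
        raise ValueError("association matrix must be symmetric")
    if not np.all(np.isfinite(A)):
        raise ValueError("association matrix must be finite")
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    denom = n - 1
    mu = off.sum(axis=1) / denom
    # two-pass variance over off-diagonal entries (cancellation-safe)
    dev = off - mu[:, None]
    np.fill_diagonal(dev, 0.0)
    sigma = np.sqrt((dev * dev).sum(axis=1) / denom)
    # a row whose background is flat up to rounding carries no evidence
    flat = sigma <= 1e-12 * np.maximum(1.0, np.abs(off).max(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (off - mu[:, None]) / sigma[:, None]
    u[flat, :] = 0.0
    u = np.maximum(u, 0.0)
    np.fill_diagonal(u, 0.0)
    z = np.sqrt(u**2 + u.T**2)
    np.fill_diagonal(z, 0.0)
    return ZScoreNetwork(list(assoc.gene_ids), z, assoc.method, standardized=False)


def standardize_scores(network: ZScoreNetwork) -> ZScoreNetwork:
    """Standardize off-diagonal pair scores against their own mean and sd.

    The resulting values are the pair-level z-scores that cutoffs are
    applied to; negative values are retained (thresholding removes them).
    A degenerate all-equal input standardizes to all zeros.
    """
    n = network.n_genes
    if n < 2 or pair_count(n) < 2:
        raise ValueError("need at least 2 gene pairs to standardize")
    iu = np.triu_indices(n, k=1)
    vals = network.z[iu]
    mu = vals.mean()
    sd = vals.std()
    out = np.zeros_like(network.z)
    if sd > 1e-12 * max(1.0, float(np.abs(vals).max())):
        out = (network.z - mu) / sd
        np.fill_diagonal(out, 0.0)
    return ZScoreNetwork(
        list(network.gene_ids), out, network.method, standardized=True
    )


def threshold_network(network: ZScoreNetwork, cutoff: float) -> EdgeList:
    """Keep every pair whose score is ≥ cutoff, canonically ordered."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    n = network.n_genes
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if network.z[i, j] >= cutoff:
                edges.append((network.gene_ids[i], network.gene_ids[j], network.z[i, j]))
    return EdgeList(edges, cutoff=cutoff)


def network_pair_scores(network: ZScoreNetwork) -> dict[tuple[str, str], float]:
    """All C(n,2) pair scores keyed by canonical (a < b) gene-ID pairs."""
    n = network.n_genes
    out = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = network.gene_ids[i], network.gene_ids[j]
            if b < a:
                a, b = b, a
            out[(a, b)] = float(network.z[i, j])
    return out


def infer_network(
    matrix: ExpressionMatrix,
    method: str,
    cutoff: float,
    workers: int = 1,
    **params,
) -> EdgeList:
    """Full inference pipeline: associate → CLR → standardize → threshold.

    The output is identical for any worker count: the association stage
    computes each unordered pair exactly once under the partition plan, and
    every later stage is deterministic.
    """
    assoc = association_matrix(matrix, method, workers=workers, **params)
    return threshold_network(standardize_scores(clr_transform(assoc)), cutoff)
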