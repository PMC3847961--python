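"""Deterministic balanced partitioning of the unordered gene-pair workload.

For n genes there are n(n−1)/2 unordered pairs.  To spread them evenly over
rows (and rows over workers) without computing any pair twice, row i owns
the pairs {i, (i+d) mod n} for d = 1..⌊(n−1)/2⌋; when n is even the n/2
antipodal pairs {i, i+n/2} are owned by the rows i < n/2.  Every unordered
pair lies at exactly one circular distance from exactly one of its
endpoints' ownership windows, so coverage and uniqueness hold by
construction, and per-row loads differ by at most one.  Rows are dealt to
workers round-robin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PartitionPlan", "pair_count", "ordered_pair_count", "partition_rows"]


def pair_count(n: int) -> int:
    """Number of unordered gene pairs, n(n−1)/2."""
    if n < 2:
        raise ValueError(f"need at least 2 genes, got {n}")
    return n * (n - 1) // 2


def ordered_pair_count(n: int) -> int:
    """Number of ordered gene pairs, n(n−1)."""
    if n < 2:
        raise ValueError(f"need at least 2 genes, got {n}")
    return n * (n - 1)


@dataclass
class PartitionPlan:
    """Row-ownership plan for all unordered pairs of ``n`` items.

    ``assignment[i]`` is the array of column indices j whose pair {i, j}
    row i owns; ``worker_of_row[i]`` maps each row to one of ``p`` workers.
    """

    n: int
    p: int
    assignment: list[np.ndarray]
    worker_of_row: np.ndarray

    def rows_for_worker(self, w: int) -> np.ndarray:
        return np.flatnonzero(self.worker_of_row == w)

    def pairs(self):
        """All owned pairs in deterministic (row-major) order."""
        for i, js in enumerate(self.assignment):
            for j in js:
                yield i, int(j)


def partition_rows(n: int, p: int) -> PartitionPlan:
    """Build the circular balanced plan for ``n`` genes and ``p`` workers."""
    if n < 2:
        raise ValueError(f"need at least 2 genes, got {n}")
    if p < 1:
        raise ValueError(f"need at least 1 worker, got {p}")
    if p > n:
        raise ValueError(f"more workers ({p}) than genes ({n})")
    half = (n - 1) // 2
    assignment = []
    for i in range(n):
        js = [(i + d) % n for d in range(1, half + 1)]
        if n % 2 == 0 and i < n // 2:
            js.append(i + n // 2)
        assignment.append(np.array(js, dtype=np.int64))
    worker_of_row = np.arange(n, dtype=np.int64) % p
    return PartitionPlan(n=n, p=p, assignment=assignment, worker_of_row=worker_of_row)
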