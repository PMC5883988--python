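"""Signed Pearson connectivity matrices and proportional thresholding.

Builds region-by-region correlation matrices from time-series panels,
averages them across subjects, and binarizes them into signed networks
under two proportional-threshold schemes:

* ``absolute`` — keep the top fraction of pairs ranked by ``|r|``; each
  kept link carries the sign of its correlation.
* ``signed`` — keep the top fraction of positive pairs (by ``r``) and,
  independently, the top fraction of negative pairs (by ``-r``).

The retained fraction of all possible region pairs is the network
*cost* (density).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesPanel",
    "ConnectivityMatrix",
    "SignedBinaryNetwork",
    "pearson_connectivity",
    "group_average",
    "threshold_absolute",
    "threshold_signed",
    "absolute_cost_grid",
    "positive_cost_grid",
    "negative_cost_grid",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round-half-up to an integer (0.5 -> 1, 1.5 -> 2).

    Used for converting ``cost * n_pairs`` into a link count; the
    convention is fixed so thresholded networks are reproducible.
    """
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesPanel:
    """One subject's region activation time series (timepoints x regions)."""

    values: np.ndarray
    region_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("panel values must be a 2-D timepoints x regions array")
        t, r = self.values.shape
        if t < 3:
            raise ValueError(f"panel needs at least 3 timepoints, got {t}")
        if r < 2:
            raise ValueError(f"panel needs at least 2 regions, got {r}")
        if len(self.region_labels) != r:
            raise ValueError(
                f"{len(self.region_labels)} labels for {r} region columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"panel {self.subject_id!r} contains missing values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def zero_variance_regions(self) -> list[str]:
        """Labels of constant columns (flagged before correlation)."""
        sd = self.values.std(axis=0)
        return [lab for lab, s in zip(self.region_labels, sd) if s == 0.0]


@dataclass
class ConnectivityMatrix:
    """Symmetric signed correlation matrix over regions; diagonal is 1."""

    values: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != r:
            raise ValueError("connectivity values must be square")
        if len(self.region_labels) != r:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        off = self.values[~np.eye(r, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal entries must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        r = self.n_regions
        return r * (r - 1) // 2

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle entries in row-major (i, j) order."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


@dataclass
class SignedBinaryNetwork:
    """Ternary adjacency in {-1, 0, +1} with cost metadata."""

    adjacency: np.ndarray
    positive_cost: float
    negative_cost: float
    scheme: str
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        if not np.issubdtype(self.adjacency.dtype, np.integer):
            self.adjacency = self.adjacency.astype(np.int8)
        r = self.adjacency.shape[0]
        if self.adjacency.ndim != 2 or self.adjacency.shape[1] != r:
            raise ValueError("adjacency must be square")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-links are not allowed")
        if not np.isin(self.adjacency, (-1, 0, 1)).all():
            raise ValueError("adjacency entries must be in {-1, 0, +1}")
        if self.scheme not in ("absolute", "signed"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not self.region_labels:
            self.region_labels = [f"r{i}" for i in range(r)]

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_positive_links(self) -> int:
        return int((np.triu(self.adjacency, k=1) == 1).sum())

    @property
    def n_negative_links(self) -> int:
        return int((np.triu(self.adjacency, k=1) == -1).sum())

    def link_pairs(self) -> set[tuple[int, int]]:
        """Set of (i, j), i < j, carrying a nonzero link."""
        iu, ju = np.triu_indices(self.n_regions, k=1)
        keep = self.adjacency[iu, ju] != 0
        return set(zip(iu[keep].tolist(), ju[keep].tolist()))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def pearson_connectivity(panel: TimeSeriesPanel) -> ConnectivityMatrix:
    """Pearson-correlate all region pairs of one panel.

    Raises
    ------
    ValueError
        If any region column has zero variance (the correlation would be
        undefined); the message names the offending regions.
    """
    bad = panel.zero_variance_regions()
    if bad:
        raise ValueError(
            f"zero-variance region column(s) in panel {panel.subject_id!r}: "
            + ", ".join(bad)
        )
    corr = np.corrcoef(panel.values, rowvar=False)
    # corrcoef can drift to 1 + eps on perfectly collinear columns
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return ConnectivityMatrix(corr, list(panel.region_labels))


def group_average(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Entry-wise mean of individual connectivity matrices."""
    if not matrices:
        raise ValueError("no matrices to average")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != ref.values.shape:
            raise ValueError("matrices have mismatched dimensions")
        if m.region_labels != ref.region_labels:
            raise ValueError("matrices have mismatched region labels")
    mean = np.mean([m.values for m in matrices], axis=0)
    np.fill_diagonal(mean, 1.0)
    return ConnectivityMatrix(mean, list(ref.region_labels))


def _ranked_pairs(conn: ConnectivityMatrix, key: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pair indices sorted by descending key, ties by (i, j)."""
    iu, ju = np.triu_indices(conn.n_regions, k=1)
    # lexsort: last key is primary; (i, j) ascending breaks ties deterministically
    order = np.lexsort((ju, iu, -key))
    return iu[order], ju[order]


def threshold_absolute(conn: ConnectivityMatrix, cost: float) -> SignedBinaryNetwork:
    """Keep the ``round(cost * n_pairs)`` pairs with largest ``|r|``.

    Each retained link carries the sign of its correlation; realized
    positive/negative fractions are recorded on the result.
    """
    if not 0.0 < cost <= 1.0:
        raise ValueError(f"cost must be in (0, 1], got {cost}")
    n_links = round_half_up(cost * conn.n_pairs)
    vals = conn.values
    iu, ju = _ranked_pairs(conn, np.abs(vals[np.triu_indices(conn.n_regions, k=1)]))
    sel_i, sel_j = iu[:n_links], ju[:n_links]
    adj = np.zeros_like(vals, dtype=np.int8)
    signs = np.sign(vals[sel_i, sel_j]).astype(np.int8)
    if np.any(signs == 0):
        # r exactly 0 selected only when cost forces it; count it positive
        logger.warning("threshold_absolute selected %d zero-correlation pairs",
                       int((signs == 0).sum()))
        signs[signs == 0] = 1
    adj[sel_i, sel_j] = signs
    adj[sel_j, sel_i] = signs
    n_pos = int((signs == 1).sum())
    n_neg = int((signs == -1).sum())
    p = conn.n_pairs
    return SignedBinaryNetwork(
        adj,
        positive_cost=n_pos / p,
        negative_cost=n_neg / p,
        scheme="absolute",
        region_labels=list(conn.region_labels),
    )


def threshold_signed(
    conn: ConnectivityMatrix, positive_cost: float, negative_cost: float
) -> SignedBinaryNetwork:
    """Keep top positive pairs and top negative pairs at separate costs.

    ``round(positive_cost * n_pairs)`` pairs with the largest positive r
    become +1 links; ``round(negative_cost * n_pairs)`` pairs with the
    most negative r become -1 links. The two selections are disjoint by
    construction. If a sign's supply is insufficient, all available pairs
    of that sign are taken and a warning is logged.
    """
    for name, c in (("positive_cost", positive_cost), ("negative_cost", negative_cost)):
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {c}")
    if positive_cost + negative_cost > 1.0 + 1e-12:
        raise ValueError("positive_cost + negative_cost must not exceed 1")

    p = conn.n_pairs
    vals = conn.values
    triu = vals[np.triu_indices(conn.n_regions, k=1)]
    adj = np.zeros_like(vals, dtype=np.int8)

    for sign, cost, key in (
        (1, positive_cost, triu),
        (-1, negative_cost, -triu),
    ):
        want = round_half_up(cost * p)
        if want == 0:
            continue
        iu, ju = _ranked_pairs(conn, key)
        valid = vals[iu, ju] * sign > 0
        avail_i, avail_j = iu[valid], ju[valid]
        if avail_i.size < want:
            logger.warning(
                "requested %d %s links but only %d pairs of that sign exist; "
                "taking all available",
                want, "positive" if sign == 1 else "negative", avail_i.size,
            )
            want = avail_i.size
        sel_i, sel_j = avail_i[:want], avail_j[:want]
        assert np.all(adj[sel_i, sel_j] == 0), "sign selections must be disjoint"
        adj[sel_i, sel_j] = sign
        adj[sel_j, sel_i] = sign

    return SignedBinaryNetwork(
        adj,
        positive_cost=positive_cost,
        negative_cost=negative_cost,
        scheme="signed",
        region_labels=list(conn.region_labels),
    )


# ---------------------------------------------------------------------------
# cost grids
# ---------------------------------------------------------------------------
# The absolute grid spans 5%..100% in 5% steps (20 nonempty levels); the
# signed grids include the 0% level (0..70% -> 15 levels for positive
# links, 0..30% -> 7 levels for negative links) so that the positive x
# negative factorial has 15 * 7 = 105 cells.


def absolute_cost_grid() -> list[float]:
    """20 cost levels: 5% to 100% in 5% steps (0% excluded)."""
    return [pct / 100.0 for pct in range(5, 101, 5)]


def positive_cost_grid() -> list[float]:
    """15 positive-cost levels: 0% to 70% in 5% steps."""
    return [pct / 100.0 for pct in range(0, 71, 5)]


def negative_cost_grid() -> list[float]:
    """7 negative-cost levels: 0% to 30% in 5% steps."""
    return [pct / 100.0 for pct in range(0, 31, 5)]
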