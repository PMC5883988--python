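"""Scoring simulated activity against an empirical connectivity target.

The pipeline per parameter combination is: simulate -> correlate the
raster columns into a simulated connectivity matrix -> Pearson-correlate
its upper triangle with the target's upper triangle (goodness-of-fit)
-> repeat over seeded replicates and average. ``sweep`` runs that
protocol over a parameter/cost grid and reports the argmax.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .connectivity import (
    ConnectivityMatrix,
    SignedBinaryNetwork,
    absolute_cost_grid,
    negative_cost_grid,
    positive_cost_grid,
    threshold_absolute,
    threshold_signed,
)
from .dynamics import ActivityRaster, SERParams, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "FitScore",
    "SweepGrid",
    "SweepResult",
    "raster_connectivity",
    "positive_part",
    "goodness_of_fit",
    "replicate_fit",
    "sweep",
    "series1_grid",
    "series2_grid",
    "series3_grid",
]


@dataclass(frozen=True)
class FitScore:
    """Mean/SD of the goodness-of-fit over replicates."""

    mean_r: float
    sd_r: float
    n_replicates: int
    n_undefined: int = 0

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.mean_r <= 1.0 + 1e-12:
            raise ValueError(f"mean_r outside [-1, 1]: {self.mean_r}")
        if self.sd_r < 0:
            raise ValueError("sd_r must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def raster_connectivity(raster: ActivityRaster) -> ConnectivityMatrix:
    """Column-wise Pearson correlation of an activity raster.

    Constant columns (nodes that never or always fire) would make the
    correlation undefined; their entries are set to 0 and a count is
    logged so matrix dimensions stay fixed across replicates.
    """
    if raster.n_steps < 3:
        raise ValueError("raster needs at least 3 steps to correlate")
    x = raster.values.astype(float)
    sd = x.std(axis=0)
    constant = sd == 0.0
    n_constant = int(constant.sum())
    if n_constant:
        logger.debug("raster has %d constant column(s); correlations set to 0",
                     n_constant)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    labels = [f"r{i}" for i in range(raster.n_regions)]
    return ConnectivityMatrix(corr, labels)


def positive_part(conn: ConnectivityMatrix) -> ConnectivityMatrix:
    """Copy of a connectivity matrix with negative off-diagonals zeroed."""
    vals = np.where(conn.values > 0, conn.values, 0.0)
    np.fill_diagonal(vals, 1.0)
    return ConnectivityMatrix(vals, list(conn.region_labels))


def goodness_of_fit(
    sim: ConnectivityMatrix,
    target: ConnectivityMatrix,
    target_mode: str = "positive",
) -> float:
    """Pearson r between upper-triangle entries of two matrices.

    ``target_mode="positive"`` (default) zeroes the target's negative
    entries before comparing, so simulations are scored against the
    positive connectivity pattern; ``"signed"`` uses the full target.
    Returns NaN (logged) when either vector has zero variance.
    """
    if sim.values.shape != target.values.shape:
        raise ValueError("sim and target dimensions differ")
    if sim.region_labels != target.region_labels and (
        len(sim.region_labels) != len(target.region_labels)
    ):
        raise ValueError("sim and target labels differ")
    if target_mode not in ("positive", "signed"):
        raise ValueError(f"unknown target_mode {target_mode!r}")
    a = sim.upper_triangle()
    b = target.upper_triangle()
    if target_mode == "positive":
        b = np.where(b > 0, b, 0.0)
    if a.std() == 0.0 or b.std() == 0.0:
        logger.debug("goodness_of_fit undefined: zero variance in a triangle vector")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def replicate_fit(
    network: SignedBinaryNetwork,
    params: SERParams,
    target: ConnectivityMatrix,
    n_replicates: int = 100,
    n_steps: int = 200,
    base_seed: int = 0,
    target_mode: str = "positive",
) -> FitScore:
    """Run the simulate/correlate/score protocol over seeded replicates.

    Replicate k uses seed ``base_seed + k``. Undefined scores (degenerate
    rasters) are excluded from the mean with their count reported; if
    every replicate is undefined an error is raised.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    scores = []
    for k in range(n_replicates):
        raster = simulate(network, params, n_steps=n_steps, seed=base_seed + k)
        r = goodness_of_fit(raster_connectivity(raster), target, target_mode)
        scores.append(r)
    scores = np.asarray(scores, dtype=float)
    ok = np.isfinite(scores)
    n_undef = int((~ok).sum())
    if n_undef:
        logger.warning("%d/%d replicates gave undefined goodness-of-fit",
                       n_undef, n_replicates)
    if not ok.any():
        raise ValueError("all replicates produced undefined goodness-of-fit")
    kept = scores[ok]
    return FitScore(
        mean_r=float(kept.mean()),
        sd_r=float(kept.std(ddof=0)),
        n_replicates=n_replicates,
        n_undefined=n_undef,
    )


# ---------------------------------------------------------------------------
# sweep harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepGrid:
    """Cartesian parameter/cost grid for a sweep.

    For scheme "absolute", ``costs`` enumerates total-density levels; for
    scheme "signed", ``positive_costs`` x ``negative_costs`` enumerates
    the factorial of per-sign levels. ``pi_values`` is used for the
    locked couple pi_p = pi_n (the default protocol); unlock by passing
    explicit ``pi_p_values``/``pi_n_values``.
    """

    scheme: str = "absolute"
    costs: tuple[float, ...] = ()
    positive_costs: tuple[float, ...] = ()
    negative_costs: tuple[float, ...] = ()
    sop_values: tuple[float, ...] = (0.25,)
    nep_values: tuple[float, ...] = (0.25,)
    pi_values: tuple[float, ...] = (0.1,)
    pi_p_values: tuple[float, ...] = ()
    pi_n_values: tuple[float, ...] = ()

    def combinations(self) -> list[dict]:
        """Enumerate grid cells as flat parameter dicts."""
        if self.scheme == "absolute":
            cost_cells = [
                {"cost": c, "positive_cost": None, "negative_cost": None}
                for c in self.costs
            ]
        elif self.scheme == "signed":
            cost_cells = [
                {"cost": None, "positive_cost": pc, "negative_cost": nc}
                for pc, nc in itertools.product(self.positive_costs, self.negative_costs)
            ]
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.pi_p_values or self.pi_n_values:
            pi_cells = [
                {"pi_p": pp, "pi_n": pn}
                for pp, pn in itertools.product(self.pi_p_values, self.pi_n_values)
            ]
        else:
            pi_cells = [{"pi_p": v, "pi_n": v} for v in self.pi_values]
        combos = []
        for cost_cell, sop, nep, pi_cell in itertools.product(
            cost_cells, self.sop_values, self.nep_values, pi_cells
        ):
            combos.append({"sop": sop, "nep": nep, **pi_cell, **cost_cell,
                           "scheme": self.scheme})
        if not combos:
            raise ValueError("empty sweep grid")
        return combos


@dataclass
class SweepResult:
    """Tidy per-combination fit table plus the best combination."""

    table: pd.DataFrame
    base_seed: int
    n_replicates: int
    n_steps: int
    best: dict = field(init=False)

    def __post_init__(self) -> None:
        idx = int(self.table["mean_r"].idxmax())
        self.best = self.table.loc[idx].to_dict()


def _network_for(combo: dict, conn: ConnectivityMatrix) -> SignedBinaryNetwork:
    if combo["scheme"] == "absolute":
        return threshold_absolute(conn, combo["cost"])
    return threshold_signed(conn, combo["positive_cost"], combo["negative_cost"])


def _run_combo(
    index: int,
    combo: dict,
    conn: ConnectivityMatrix,
    target: ConnectivityMatrix,
    n_replicates: int,
    n_steps: int,
    base_seed: int,
    target_mode: str,
) -> dict:
    params = SERParams(sop=combo["sop"], nep=combo["nep"],
                       pi_p=combo["pi_p"], pi_n=combo["pi_n"])
    network = _network_for(combo, conn)
    # per-combination seed block: independent of execution order, so
    # parallel and serial sweeps are bit-identical
    seed = base_seed + index * n_replicates
    score = replicate_fit(network, params, target,
                          n_replicates=n_replicates, n_steps=n_steps,
                          base_seed=seed, target_mode=target_mode)
    return {
        "combo": index, **combo,
        "mean_r": score.mean_r, "sd_r": score.sd_r,
        "n_replicates": score.n_replicates, "n_undefined": score.n_undefined,
        "base_seed": seed,
    }


def sweep(
    grid: SweepGrid,
    conn: ConnectivityMatrix,
    target: ConnectivityMatrix,
    n_replicates: int = 100,
    n_steps: int = 200,
    base_seed: int = 0,
    target_mode: str = "positive",
    checkpoint: str | Path | None = None,
    n_jobs: int = 1,
) -> SweepResult:
    """Score every grid cell and report the argmax.

    Combinations are independent (per-combination seed blocks); with
    ``checkpoint`` set, finished rows are appended to a CSV and an
    interrupted sweep resumes from it.
    """
    combos = grid.combinations()
    done: dict[int, dict] = {}
    ckpt = Path(checkpoint) if checkpoint else None
    if ckpt is not None and ckpt.exists():
        prev = pd.read_csv(ckpt)
        for _, row in prev.iterrows():
            done[int(row["combo"])] = row.to_dict()
        logger.info("resuming sweep: %d/%d combinations already done",
                    len(done), len(combos))

    todo = [(i, c) for i, c in enumerate(combos) if i not in done]
    args = dict(conn=conn, target=target, n_replicates=n_replicates,
                n_steps=n_steps, base_seed=base_seed, target_mode=target_mode)
    if n_jobs == 1 or len(todo) <= 1:
        rows = []
        for i, c in todo:
            row = _run_combo(i, c, **args)
            rows.append(row)
            if ckpt is not None:
                pd.DataFrame([row]).to_csv(ckpt, mode="a", index=False,
                                           header=not ckpt.exists())
    else:
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_run_combo)(i, c, **args) for i, c in todo
        )
        if ckpt is not None:
            pd.DataFrame(rows).to_csv(ckpt, mode="a", index=False,
                                      header=not ckpt.exists())

    table = pd.DataFrame(sorted([*done.values(), *rows], key=lambda r: r["combo"]))
    table = table.reset_index(drop=True)
    return SweepResult(table=table, base_seed=base_seed,
                       n_replicates=n_replicates, n_steps=n_steps)


# ---------------------------------------------------------------------------
# the three protocol series
# ---------------------------------------------------------------------------


def series1_grid() -> SweepGrid:
    """Coarse exploration: 20 absolute-threshold costs x sop/nep in
    {0.25, 0.50, 0.75} x locked pi in 0.1..1.0 (step 0.1)."""
    return SweepGrid(
        scheme="absolute",
        costs=tuple(absolute_cost_grid()),
        sop_values=(0.25, 0.50, 0.75),
        nep_values=(0.25, 0.50, 0.75),
        pi_values=tuple(round(0.1 * k, 10) for k in range(1, 11)),
    )


def series2_grid() -> SweepGrid:
    """Refinement in the low-parameter range: sop/nep 0.025..0.25 (step
    0.025), locked pi in {0.025, 0.05, 0.075, 0.1}, absolute costs."""
    return SweepGrid(
        scheme="absolute",
        costs=tuple(absolute_cost_grid()),
        sop_values=tuple(round(0.025 * k, 10) for k in range(1, 11)),
        nep_values=tuple(round(0.025 * k, 10) for k in range(1, 11)),
        pi_values=(0.025, 0.05, 0.075, 0.1),
    )


def series3_grid(sop: float = 0.025, nep: float = 0.225, pi: float = 0.1) -> SweepGrid:
    """Signed-threshold factorial: 15 positive x 7 negative cost levels
    at fixed dynamics parameters (defaults are the optimum of series 2)."""
    return SweepGrid(
        scheme="signed",
        positive_costs=tuple(positive_cost_grid()),
        negative_costs=tuple(negative_cost_grid()),
        sop_values=(sop,),
        nep_values=(nep,),
        pi_values=(pi,),
    )
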