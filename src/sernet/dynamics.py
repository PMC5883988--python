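"""SER (susceptible-excited-refractory) agent dynamics on signed networks.

Every region is an agent cycling through three states: S (can be
excited), E (active for exactly one step), R (recovering). At each
synchronous step an agent is summarized by three binary fields:

* ``phi_s`` — 1 iff the agent is susceptible;
* ``phi_p`` — 1 iff the mean activity of its positively linked
  neighbors reaches the threshold ``pi_p``;
* ``phi_n`` — likewise for negatively linked neighbors vs ``pi_n``.

The transition rules, keyed by (phi_s, phi_p, phi_n):

====== ====== ====== =================================
phi_s  phi_p  phi_n  transition
====== ====== ====== =================================
0      any    any    E -> R always; R -> S w.p. ``nep``
1      0      0      S -> E w.p. ``sop``
1      1      1      S -> E w.p. ``sop``
1      0      1      S -> S (suppressed)
1      1      0      S -> E always (driven)
====== ====== ====== =================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import SignedBinaryNetwork

__all__ = [
    "S", "E", "R",
    "SERParams",
    "AgentFields",
    "ActivityRaster",
    "random_states",
    "local_fields",
    "transition",
    "simulate",
]

# state codes
S, E, R = 0, 1, 2


@dataclass(frozen=True)
class SERParams:
    """The four model parameters.

    sop : spontaneous excitation probability of a susceptible node
    nep : recovery probability of a refractory node
    pi_p : threshold on the mean activity of positive neighbors
    pi_n : threshold on the mean activity of negative neighbors
    comparison : "ge" (default) binarizes with avg >= pi; "gt" with avg > pi
    """

    sop: float
    nep: float
    pi_p: float
    pi_n: float
    comparison: str = "ge"

    def __post_init__(self) -> None:
        for name in ("sop", "nep", "pi_p", "pi_n"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.comparison not in ("ge", "gt"):
            raise ValueError(f"comparison must be 'ge' or 'gt', got {self.comparison!r}")


@dataclass
class AgentFields:
    """Binary per-node fields (phi_s, phi_p, phi_n) for one step."""

    phi_s: np.ndarray
    phi_p: np.ndarray
    phi_n: np.ndarray


@dataclass
class ActivityRaster:
    """Binary steps x regions record of excited states (E = 1)."""

    values: np.ndarray
    params: SERParams
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("raster must be 2-D (steps x regions)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("raster entries must be 0/1")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def random_states(n_nodes: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random S/E/R state per node."""
    return rng.integers(0, 3, size=n_nodes).astype(np.int8)


def _binarize(avg: np.ndarray, pi: float, comparison: str) -> np.ndarray:
    if comparison == "ge":
        return avg >= pi
    return avg > pi


def local_fields(
    states: np.ndarray, network: SignedBinaryNetwork, params: SERParams
) -> AgentFields:
    """Compute the (phi_s, phi_p, phi_n) fields from the current states.

    For each node, the positive (negative) neighbor average is the
    fraction of its positively (negatively) linked neighbors currently
    excited. Nodes without neighbors of a sign get phi = 0 for that
    sign regardless of the threshold (no modulation).
    """
    states = np.asarray(states)
    if states.shape[0] != network.n_regions:
        raise ValueError("state vector length does not match network size")
    active = (states == E).astype(float)
    pos = (network.adjacency == 1)
    neg = (network.adjacency == -1)
    pos_deg = pos.sum(axis=1).astype(float)
    neg_deg = neg.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg_p = np.where(pos_deg > 0, pos.astype(float) @ active / np.maximum(pos_deg, 1), 0.0)
        avg_n = np.where(neg_deg > 0, neg.astype(float) @ active / np.maximum(neg_deg, 1), 0.0)
    phi_p = _binarize(avg_p, params.pi_p, params.comparison) & (pos_deg > 0)
    phi_n = _binarize(avg_n, params.pi_n, params.comparison) & (neg_deg > 0)
    return AgentFields(
        phi_s=(states == S),
        phi_p=phi_p,
        phi_n=phi_n,
    )


def transition(
    fields: AgentFields,
    states: np.ndarray,
    params: SERParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply the transition rules synchronously to every node."""
    states = np.asarray(states)
    assert np.array_equal(fields.phi_s, states == S), "phi_s inconsistent with states"
    n = states.shape[0]
    u = rng.random(n)
    new = states.copy()

    # phi_s = 0 rows: E -> R unconditionally; R -> S with probability nep
    new[states == E] = R
    recover = (states == R) & (u < params.nep)
    new[recover] = S

    # phi_s = 1 rows
    sus = states == S
    driven = sus & fields.phi_p & ~fields.phi_n            # (1,1,0): S -> E always
    suppressed = sus & ~fields.phi_p & fields.phi_n        # (1,0,1): S -> S
    spontaneous = sus & ~driven & ~suppressed & (u < params.sop)  # (1,0,0)/(1,1,1)
    new[driven | spontaneous] = E
    return new


def simulate(
    network: SignedBinaryNetwork,
    params: SERParams,
    n_steps: int = 200,
    seed: int = 0,
    initial_states: np.ndarray | None = None,
) -> ActivityRaster:
    """Run ``n_steps`` synchronous updates and record the activity raster.

    Initial states are uniform random over {S, E, R} from the seeded
    stream unless ``initial_states`` is supplied. The raster has one row
    per update (the initial condition is not recorded); identical seeds
    give bit-identical rasters.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    rng = np.random.default_rng(seed)
    n = network.n_regions
    if initial_states is None:
        states = random_states(n, rng)
    else:
        states = np.asarray(initial_states, dtype=np.int8).copy()
        if states.shape != (n,) or not np.isin(states, (S, E, R)).all():
            raise ValueError("initial_states must be a length-n vector of S/E/R codes")

    # adjacency masks are fixed; hoist them out of the step loop
    pos = (network.adjacency == 1).astype(float)
    neg = (network.adjacency == -1).astype(float)
    pos_deg = pos.sum(axis=1)
    neg_deg = neg.sum(axis=1)
    has_pos = pos_deg > 0
    has_neg = neg_deg > 0
    pos_deg_safe = np.maximum(pos_deg, 1.0)
    neg_deg_safe = np.maximum(neg_deg, 1.0)

    raster = np.empty((n_steps, n), dtype=np.int8)
    for t in range(n_steps):
        active = (states == E).astype(float)
        avg_p = pos @ active / pos_deg_safe
        avg_n = neg @ active / neg_deg_safe
        phi_p = _binarize(avg_p, params.pi_p, params.comparison) & has_pos
        phi_n = _binarize(avg_n, params.pi_n, params.comparison) & has_neg

        u = rng.random(n)
        new = states.copy()
        new[states == E] = R
        new[(states == R) & (u < params.nep)] = S
        sus = states == S
        driven = sus & phi_p & ~phi_n
        suppressed = sus & ~phi_p & phi_n
        spontaneous = sus & ~driven & ~suppressed & (u < params.sop)
        new[driven | spontaneous] = E

        states = new
        raster[t] = states == E
    return ActivityRaster(raster, params=params, seed=seed)
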