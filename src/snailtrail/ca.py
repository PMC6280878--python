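"""Stochastic lattice cellular automaton of corneal angiogenesis.

Two agent types live on the (R+1) x (R+1) lattice: active tip cells (TCs)
performing a biased random walk toward the TAF source, and passive
endothelial/stalk cells (ECs) deposited at every site a TC vacates (the
"snail-trail").  New TCs appear through TAF-stimulated branching; TCs are
annihilated by tip-to-tip anastomosis (both models) and tip-to-sprout
anastomosis (Model 2 only).

Random sequential update.  One discrete step consists of a motility phase
followed by a branching phase.  In the motility phase, N_bar (the TC count
at the start of the step) selections are drawn uniformly with replacement
from the currently-alive TCs, each processed by :func:`attempt_move`.  In
the branching phase, N_bar is re-read and the same number of selections is
processed by :func:`attempt_branch`.  An agent killed mid-phase leaves the
sampling pool immediately; if the pool empties, the remaining selections
of that phase are skipped without consuming random draws.

RNG contract.  All randomness in a realization comes from a single
MT19937 stream (``numpy.random.RandomState``), consumed in this fixed
order per event:

1. selection: ``idx = int(u * n_alive)`` with one uniform ``u``;
2. motility/branching gate: one uniform against ``P_m`` (or ``P_b``);
3. move direction: one uniform against the cumulative direction
   probabilities, ordered (x+, x-, y+, y-);
4. resolution: one uniform against ``a_n`` when the target holds a TC, or
   against ``a_e`` when it holds an EC in Model 2 and is not a self-loop.
   Aborted boundary moves and prohibited self-loops consume no extra draw.

The numba kernel in :mod:`snailtrail._kernels` consumes the identical
stream in the identical order, so both engines produce bit-identical
realizations from the same seed (asserted in the test suite).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .config import CAConfig, TAFField, ConfigError

__all__ = [
    "LatticeState", "MoveOutcome", "Agent",
    "init_lattice", "direction_probabilities", "attempt_move",
    "attempt_branch", "step", "run_realization", "run_ensemble",
]


class CAError(RuntimeError):
    """Internal consistency error in the CA state."""


@dataclass
class Agent:
    """A live tip cell: lattice position and the trail of sites where it
    has deposited ECs since its creation (used for the Model 2 self-loop
    prohibition).  Daughter TCs created by branching start with empty
    trails."""
    i: int
    j: int
    trail: set = field(default_factory=set)


@dataclass(frozen=True)
class MoveOutcome:
    """Outcome of one motility attempt.

    kind is one of: moved, excluded_tc, excluded_ec, tip_tip, tip_sprout,
    selfloop_aborted, boundary_aborted, no_attempt.  The EC-related kinds
    (excluded_ec, tip_sprout, selfloop_aborted) can only occur in Model 2.
    """
    kind: str
    origin: tuple | None = None
    target: tuple | None = None


class LatticeState:
    """Full microstate of one CA realization.

    Attributes
    ----------
    K : int
        Discrete time index.
    tc_grid : (R+1, R+1) int8 array
        TC indicator per site (at most one TC per site in both models).
    ec_grid : (R+1, R+1) int64 array
        EC count per site; restricted to {0, 1} in Model 2.
    agents : dict[int, Agent]
        Registry of live TCs keyed by id.
    alive : list[int]
        Ids of live TCs in sampling-pool order (swap-remove on death).
    """

    def __init__(self, R: int, rng: np.random.RandomState):
        self.R = R
        self.K = 0
        self.tc_grid = np.zeros((R + 1, R + 1), dtype=np.int8)
        self.ec_grid = np.zeros((R + 1, R + 1), dtype=np.int64)
        self.agents: dict[int, Agent] = {}
        self.alive: list[int] = []
        self._slot: dict[int, int] = {}
        self._next_id = 0
        self.rng = rng

    # -- registry bookkeeping -------------------------------------------------

    def spawn(self, i: int, j: int) -> int:
        aid = self._next_id
        self._next_id += 1
        self.agents[aid] = Agent(i, j)
        self._slot[aid] = len(self.alive)
        self.alive.append(aid)
        self.tc_grid[i, j] = 1
        return aid

    def kill(self, aid: int) -> None:
        """Swap-remove ``aid`` from the sampling pool and the registry."""
        ag = self.agents.pop(aid)
        self.tc_grid[ag.i, ag.j] = 0
        slot = self._slot.pop(aid)
        last = self.alive.pop()
        if last != aid:
            self.alive[slot] = last
            self._slot[last] = slot

    @property
    def n_tc(self) -> int:
        return len(self.alive)

    @property
    def n_ec(self) -> int:
        return int(self.ec_grid.sum())

    def check_consistency(self) -> None:
        grid_count = int(self.tc_grid.sum())
        if grid_count != len(self.agents):
            raise CAError("tc_grid and agent registry disagree on TC count")
        for aid, ag in self.agents.items():
            if self.tc_grid[ag.i, ag.j] != 1:
                raise CAError(f"agent {aid} at ({ag.i},{ag.j}) not on tc_grid")

    def snapshot(self) -> tuple[np.ndarray, np.ndarray]:
        return self.tc_grid.copy(), self.ec_grid.copy()


def init_lattice(config: CAConfig, rng: np.random.RandomState | None = None) -> LatticeState:
    """Initial condition: TCs at alternating sites of the limbus column,
    (i=0, j=1, 3, ..., R-1); no ECs anywhere; K = 0.

    R must be even so the alternating placement tiles the column exactly,
    yielding R/2 tip cells.
    """
    if config.R % 2 != 0:
        raise ConfigError("alternating TC placement requires even R")
    state = LatticeState(config.R, rng or np.random.RandomState(config.seed))
    for j in range(1, config.R, 2):
        state.spawn(0, j)
    return state


def direction_probabilities(taf: TAFField, k: float, site: tuple[int, int]) -> np.ndarray:
    """Movement probabilities (x+, x-, y+, y-) for a TC at ``site``.

    Biased random walk: each component is (1 +- k * dc) / 4 with dc the
    central difference of the TAF field in that direction (one-sided at the
    lattice edge).  For the linear field c_i = i*h the transverse components
    are exactly 1/4.  Components must land in [0, 1] (they always sum to 1);
    a violation means k is too large for the field gradient.
    """
    i, j = site
    p_plus, p_minus = taf.gradient_stencil(k)
    probs = np.array([p_plus[i], p_minus[i], 0.25, 0.25])
    if probs.min() < -1e-12 or probs.max() > 1.0 + 1e-12:
        raise ConfigError(
            f"direction probabilities {probs} outside [0,1]: k too large for TAF gradient"
        )
    return np.clip(probs, 0.0, 1.0)


def _neighbor(i: int, j: int, d: int) -> tuple[int, int]:
    if d == 0:
        return i + 1, j
    if d == 1:
        return i - 1, j
    if d == 2:
        return i, j + 1
    return i, j - 1


_stencil_cache: dict = {}


def _cached_stencil(config: CAConfig):
    key = (config.R, config.k)
    if key not in _stencil_cache:
        _stencil_cache[key] = config.taf().gradient_stencil(config.k)
    return _stencil_cache[key]


def attempt_move(state: LatticeState, agent_id: int, config: CAConfig,
                 rng: np.random.RandomState) -> MoveOutcome:
    """One motility attempt for a live TC; see module docstring for rules
    and draw order."""
    ag = state.agents.get(agent_id)
    if ag is None:
        raise CAError(f"attempt_move on unknown/dead agent {agent_id}")
    if rng.random_sample() >= config.P_m:
        return MoveOutcome("no_attempt", (ag.i, ag.j), None)

    p_plus, p_minus = _cached_stencil(config)
    i, j = ag.i, ag.j
    u = rng.random_sample()
    if u < p_plus[i]:
        d = 0
    elif u < p_plus[i] + p_minus[i]:
        d = 1
    elif u < p_plus[i] + p_minus[i] + 0.25:
        d = 2
    else:
        d = 3
    ti, tj = _neighbor(i, j, d)
    origin, target = (i, j), (ti, tj)

    if not (0 <= ti <= state.R and 0 <= tj <= state.R):
        # TCs are not permitted to cross lattice boundaries.
        return MoveOutcome("boundary_aborted", origin, target)

    if state.tc_grid[ti, tj]:
        if rng.random_sample() < config.a_n:
            # Tip-to-tip anastomosis: both TCs removed; the mover deposits
            # an EC at its origin and the target TC is replaced by an EC.
            other = _agent_at(state, ti, tj)
            state.kill(agent_id)
            state.kill(other)
            state.ec_grid[i, j] += 1
            state.ec_grid[ti, tj] += 1
            return MoveOutcome("tip_tip", origin, target)
        return MoveOutcome("excluded_tc", origin, target)

    if config.mode == 2 and state.ec_grid[ti, tj]:
        if (ti, tj) in ag.trail:
            # Self-loops (anastomosis with an EC this TC deposited) are
            # prohibited; the move is aborted without an anastomosis draw.
            return MoveOutcome("selfloop_aborted", origin, target)
        if rng.random_sample() < config.a_e:
            # Tip-to-sprout anastomosis: the TC is removed, deposits an EC
            # at its origin; the target EC remains.
            state.kill(agent_id)
            state.ec_grid[i, j] += 1
            return MoveOutcome("tip_sprout", origin, target)
        return MoveOutcome("excluded_ec", origin, target)

    # Vacant target: snail-trail move, EC left behind at the origin.
    state.tc_grid[i, j] = 0
    state.tc_grid[ti, tj] = 1
    ag.i, ag.j = ti, tj
    state.ec_grid[i, j] += 1
    ag.trail.add((i, j))
    return MoveOutcome("moved", origin, target)


def _agent_at(state: LatticeState, i: int, j: int) -> int:
    for aid, ag in state.agents.items():
        if ag.i == i and ag.j == j:
            return aid
    raise CAError(f"no agent found at ({i},{j}) despite tc_grid occupancy")


def attempt_branch(state: LatticeState, agent_id: int, config: CAConfig,
                   rng: np.random.RandomState) -> str:
    """One branching attempt: with probability P_b = P_p * c_i the TC tries
    to branch, placing daughters at (i, j-1) and (i, j+1) and removing
    itself, provided BOTH transverse neighbours are vacant (no TC in
    Model 1; no TC and no EC in Model 2).  Branching at the transverse
    edges (j=0 or j=R) is blocked, and never creates ECs.

    Returns one of {"branched", "blocked", "no_attempt"}.
    """
    ag = state.agents.get(agent_id)
    if ag is None:
        raise CAError(f"attempt_branch on unknown/dead agent {agent_id}")
    i, j = ag.i, ag.j
    P_b = config.P_p * (i * config.h)
    if rng.random_sample() >= P_b:
        return "no_attempt"
    if j - 1 < 0 or j + 1 > state.R:
        return "blocked"
    for tj in (j - 1, j + 1):
        if state.tc_grid[i, tj]:
            return "blocked"
        if config.mode == 2 and state.ec_grid[i, tj]:
            return "blocked"
    state.kill(agent_id)
    state.spawn(i, j - 1)
    state.spawn(i, j + 1)
    return "branched"


def step(state: LatticeState, config: CAConfig,
         rng: np.random.RandomState | None = None) -> LatticeState:
    """Advance the CA by one discrete time step (in place; returns state).

    Phase 1: N_bar motility selections (N_bar = TC count at step start).
    Phase 2: N_bar' branching selections (N_bar' re-read after motility).
    """
    rng = rng if rng is not None else state.rng
    n_bar = state.n_tc
    for _ in range(n_bar):
        n_alive = state.n_tc
        if n_alive == 0:
            break
        idx = int(rng.random_sample() * n_alive)
        if idx == n_alive:  # guard against u == 1.0
            idx = n_alive - 1
        attempt_move(state, state.alive[idx], config, rng)
    n_bar2 = state.n_tc
    for _ in range(n_bar2):
        n_alive = state.n_tc
        if n_alive == 0:
            break
        idx = int(rng.random_sample() * n_alive)
        if idx == n_alive:
            idx = n_alive - 1
        attempt_branch(state, state.alive[idx], config, rng)
    state.K += 1
    return state


def run_realization(config: CAConfig, seed: int, record_K: list[int],
                    engine: str = "numba"):
    """Run one realization, returning per-time snapshots.

    Parameters
    ----------
    record_K : sorted list of discrete times (each <= K_max) at which to
        record deep copies of (tc_grid, ec_grid).
    engine : "numba" (fast kernel) or "python" (reference implementation).
        Both produce bit-identical output for the same seed.

    Returns
    -------
    list of (tc_grid, ec_grid) int arrays, one per entry of record_K.
    """
    record_K = list(record_K)
    if record_K != sorted(record_K):
        raise ValueError("record_K must be sorted")
    if record_K and record_K[-1] > config.K_max:
        raise ValueError("record_K entries must be <= K_max")
    if engine == "numba":
        from ._kernels import run_realization_numba
        tc, ec = run_realization_numba(config, seed, np.asarray(record_K, dtype=np.int64))
        return [(tc[r], ec[r]) for r in range(len(record_K))]
    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")

    rng = np.random.RandomState(seed)
    state = init_lattice(config, rng)
    out = []
    targets = iter(record_K)
    nxt = next(targets, None)
    while nxt is not None and nxt == 0:
        out.append(state.snapshot())
        nxt = next(targets, None)
    K_stop = record_K[-1] if record_K else 0
    for K in range(1, K_stop + 1):
        step(state, config, rng)
        while nxt is not None and nxt == K:
            out.append(state.snapshot())
            nxt = next(targets, None)
    return out


def run_ensemble(config: CAConfig, M: int, base_seed: int, record_K: list[int],
                 engine: str = "numba"):
    """Run M independent realizations (realization m uses seed
    base_seed + m) and return the ensemble summary of site- and
    column-averaged occupancies.

    Returns an :class:`snailtrail.averaging.EnsembleSummary`; the full
    site averages n_bar, e_bar (ensemble means per site) are attached.
    """
    from .averaging import EnsembleSummary

    if M < 1:
        raise ValueError("M must be >= 1")
    R = config.R
    n_rec = len(record_K)
    n_sum = np.zeros((n_rec, R + 1, R + 1))
    e_sum = np.zeros((n_rec, R + 1, R + 1))
    for m in range(M):
        snaps = run_realization(config, base_seed + m, record_K, engine=engine)
        for r, (tc, ec) in enumerate(snaps):
            n_sum[r] += tc
            e_sum[r] += ec
    n_bar = n_sum / M
    e_bar = e_sum / M
    # Column averages: the 1/(M(R+1)) normalization over realizations and
    # the transverse (j) direction.
    N = n_bar.sum(axis=2) / (R + 1)
    E = e_bar.sum(axis=2) / (R + 1)
    times = config.tau * np.asarray(record_K, dtype=float)
    x = np.linspace(0.0, 1.0, R + 1)
    return EnsembleSummary(times=times, x_grid=x, N=N, E=E, M=M,
                           config=config, n_bar=n_bar, e_bar=e_bar)
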