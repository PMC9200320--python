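"""Temperature replica-exchange Monte Carlo scheduler.

Runs parallel Metropolis chains at a ladder of inverse temperatures with
periodic configuration exchanges between adjacent replicas.  The scheduler
is generic over a *system* (energy + symmetric move proposal), so the same
machinery drives both docking poses and the 1-D toy systems used to verify
Boltzmann correctness.

Exchange criterion: the standard T-REMC Metropolis rule
``min{1, exp[(beta_i - beta_j) * (E_i - E_j)]}``.  On an accepted exchange
the participating replicas swap configurations (poses and energies; the
betas stay with the ladder slots), and a snapshot of the coldest replica is
stored as a candidate.
"""

from __future__ import annotations

import copy as _copy
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .sample import MobileSelection, MoveSchedule, build_selection, propose_move
from .structmodel import CoarsePose

logger = logging.getLogger(__name__)

KCAL_BETAS = (1.0 / 1.5, 1.0 / 3.0, 1.0 / 5.0)  # cold -> hot, kcal^-1 mol


@dataclass(frozen=True)
class ReplicaLadder:
    """Inverse temperatures stored cold to hot (strictly decreasing beta)."""

    betas: tuple[float, ...] = KCAL_BETAS
    swap_interval: int = 1000

    def __post_init__(self):
        if self.swap_interval < 1:
            raise ValueError("swap_interval must be >= 1")
        if any(b <= 0 for b in self.betas):
            raise ValueError("betas must be positive")
        if any(b2 > b1 for b1, b2 in zip(self.betas, self.betas[1:])):
            raise ValueError("betas must be ordered cold (largest) to hot")

    @property
    def n_replicas(self) -> int:
        return len(self.betas)


def metropolis_accept(delta_e: float, beta: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-beta * delta_e)); one uniform draw."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if delta_e <= 0:
        rng.uniform()  # keep the stream in lockstep regardless of outcome
        return True
    return rng.uniform() < math.exp(-beta * delta_e)


def swap_accept_prob(e_i: float, e_j: float, beta_i: float, beta_j: float) -> float:
    """Standard T-REMC exchange probability min{1, exp[(b_i - b_j)(E_i - E_j)]}."""
    if beta_i <= 0 or beta_j <= 0:
        raise ValueError("betas must be positive")
    return min(1.0, math.exp((beta_i - beta_j) * (e_i - e_j)))


# ---------------------------------------------------------------------------
# systems


class System:
    """Minimal interface the scheduler needs: energy + symmetric proposal."""

    def energy(self, state) -> float:
        raise NotImplementedError

    def propose(self, state, rng: np.random.Generator):
        raise NotImplementedError

    def copy_state(self, state):
        return _copy.deepcopy(state)


class QuadraticToySystem(System):
    """1-D harmonic toy: E(x) = 0.5 k x^2, Gaussian steps.

    Closed-form Boltzmann moments: <E> = 1/(2 beta), Var(x) = 1/(k beta).
    """

    def __init__(self, k: float = 1.0, step_sigma: float = 1.0):
        self.k = k
        self.step_sigma = step_sigma

    def energy(self, state: float) -> float:
        return 0.5 * self.k * state * state

    def propose(self, state: float, rng: np.random.Generator) -> float:
        return state + rng.normal(0.0, self.step_sigma)

    def copy_state(self, state: float) -> float:
        return state


class DockingSystem(System):
    """Docking pose system: composite score energy + mixed rigid/backbone moves.

    ``energy_fn`` maps a pose to a float (the composite low-resolution score
    by default; any callable such as a funnel fixture works).  The mobile
    selection is recomputed every ``reselect_interval`` trials for the
    automatic interface modes ("on-the-fly"); the directed mode is static.
    """

    def __init__(
        self,
        energy_fn,
        schedule: MoveSchedule | None = None,
        selection_mode: str = "interface_8",
        directed: set | None = None,
        reselect_interval: int = 1000,
        min_fragment_len: int = 3,
    ):
        self.energy_fn = energy_fn
        self.schedule = schedule or MoveSchedule()
        self.selection_mode = selection_mode
        self.directed = directed
        self.reselect_interval = max(1, reselect_interval)
        self.min_fragment_len = min_fragment_len
        self._selections: dict[int, tuple[int, MobileSelection]] = {}
        self._trials_seen: dict[int, int] = {}

    def energy(self, state: CoarsePose) -> float:
        return float(self.energy_fn(state))

    def _selection_for(self, state: CoarsePose, slot: int) -> MobileSelection:
        count = self._trials_seen.get(slot, 0)
        cached = self._selections.get(slot)
        if cached is None or count - cached[0] >= self.reselect_interval:
            sel = build_selection(
                state, self.selection_mode, self.directed, self.min_fragment_len
            )
            self._selections[slot] = (count, sel)
            return sel
        return cached[1]

    def propose(self, state: CoarsePose, rng: np.random.Generator, slot: int = 0) -> CoarsePose:
        sel = self._selection_for(state, slot)
        self._trials_seen[slot] = self._trials_seen.get(slot, 0) + 1
        return propose_move(state, sel, self.schedule, rng)

    def copy_state(self, state: CoarsePose) -> CoarsePose:
        return state.copy()  # residue tuples are shared immutably


# ---------------------------------------------------------------------------
# records and configuration


@dataclass
class CandidateRecord:
    state: object
    energy: float
    replica: int
    trajectory: int
    trial: int
    serial: int


@dataclass
class ExchangeEvent:
    trial: int
    pair: tuple[int, int]
    accepted: bool


@dataclass
class TrajectoryResult:
    candidates: list[CandidateRecord]
    events: list[ExchangeEvent]
    energy_traces: list[list[float]]  # per replica slot, sampled at swap rounds
    attempt_counts: dict[tuple[int, int], int]
    accept_counts: dict[tuple[int, int], int]
    move_accepts: list[int]
    move_attempts: list[int]


@dataclass(frozen=True)
class RunConfig:
    n_trajectories: int = 8
    n_trials: int = 250_000
    ladder: ReplicaLadder = field(default_factory=ReplicaLadder)
    schedule: MoveSchedule = field(default_factory=MoveSchedule)
    selection_mode: str = "interface_8"
    seed: int = 0
    store_all_replicas: bool = False
    drift_check_tol: float = 1e-4

    def __post_init__(self):
        if self.n_trajectories < 1 or self.n_trials < 1:
            raise ValueError("counts must be >= 1")


class EnergyDriftError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# trajectory execution


def run_trajectory(
    system: System,
    start_state,
    config: RunConfig,
    trajectory_seed: int,
    trajectory_index: int = 0,
    serial_start: int = 0,
) -> TrajectoryResult:
    """One replica-exchange trajectory.

    Each replica runs ``swap_interval`` Metropolis trials at its beta, then
    every adjacent pair is attempted once per exchange round (even pairs
    first on even rounds, odd pairs first on odd rounds).  Accepted swaps
    exchange configurations; after each round in which the swap touching the
    coldest slot was accepted, a snapshot of the coldest replica is stored.
    """
    ladder = config.ladder
    n_rep = ladder.n_replicas
    ss = np.random.SeedSequence(entropy=trajectory_seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_rep + 1)]
    swap_rng = streams[-1]

    states = [system.copy_state(start_state) for _ in range(n_rep)]
    energies = [system.energy(s) for s in states]

    candidates: list[CandidateRecord] = []
    events: list[ExchangeEvent] = []
    traces: list[list[float]] = [[] for _ in range(n_rep)]
    attempt_counts: dict[tuple[int, int], int] = {}
    accept_counts: dict[tuple[int, int], int] = {}
    move_accepts = [0] * n_rep
    move_attempts = [0] * n_rep
    serial = serial_start

    takes_slot = isinstance(system, DockingSystem)
    n_rounds = config.n_trials // ladder.swap_interval
    leftover = config.n_trials - n_rounds * ladder.swap_interval

    def run_block(n_steps: int) -> None:
        for r in range(n_rep):
            rng = streams[r]
            beta = ladder.betas[r]
            state, e = states[r], energies[r]
            for _ in range(n_steps):
                prop = (
                    system.propose(state, rng, slot=r) if takes_slot else system.propose(state, rng)
                )
                e_new = system.energy(prop)
                move_attempts[r] += 1
                if metropolis_accept(e_new - e, beta, rng):
                    state, e = prop, e_new
                    move_accepts[r] += 1
            states[r], energies[r] = state, e

    trial = 0
    for rnd in range(n_rounds):
        run_block(ladder.swap_interval)
        trial += ladder.swap_interval

        # energy drift trap: cached vs recomputed
        for r in range(n_rep):
            e_chk = system.energy(states[r])
            if abs(e_chk - energies[r]) > config.drift_check_tol:
                raise EnergyDriftError(
                    f"replica {r}: cached {energies[r]!r} vs recomputed {e_chk!r}"
                )
            traces[r].append(energies[r])

        pairs = [(i, i + 1) for i in range(n_rep - 1)]
        even = [p for p in pairs if p[0] % 2 == 0]
        odd = [p for p in pairs if p[0] % 2 == 1]
        ordered = even + odd if rnd % 2 == 0 else odd + even
        any_swap_accepted = False
        # snapshot the relaxed cold state before any exchange replaces it;
        # states are shared immutably so this is just a reference
        pre_cold_state, pre_cold_energy = states[0], energies[0]
        for i, j in ordered:
            p = swap_accept_prob(energies[i], energies[j], ladder.betas[i], ladder.betas[j])
            accepted = swap_rng.uniform() < p
            attempt_counts[(i, j)] = attempt_counts.get((i, j), 0) + 1
            events.append(ExchangeEvent(trial=trial, pair=(i, j), accepted=accepted))
            if accepted:
                accept_counts[(i, j)] = accept_counts.get((i, j), 0) + 1
                states[i], states[j] = states[j], states[i]
                energies[i], energies[j] = energies[j], energies[i]
                any_swap_accepted = True

        # one coldest-replica candidate per round with a successful swap
        if any_swap_accepted or config.store_all_replicas:
            if config.store_all_replicas:
                snaps = [(r, system.copy_state(states[r]), energies[r]) for r in range(n_rep)]
            else:
                snaps = [(0, system.copy_state(pre_cold_state), pre_cold_energy)]
            for r, snap, e in snaps:
                candidates.append(
                    CandidateRecord(
                        state=snap,
                        energy=e,
                        replica=r,
                        trajectory=trajectory_index,
                        trial=trial,
                        serial=serial,
                    )
                )
                serial += 1

    if leftover:
        run_block(leftover)

    return TrajectoryResult(
        candidates=candidates,
        events=events,
        energy_traces=traces,
        attempt_counts=attempt_counts,
        accept_counts=accept_counts,
        move_accepts=move_accepts,
        move_attempts=move_attempts,
    )


@dataclass
class SimulationResult:
    candidates: list[CandidateRecord]
    trajectories: list[TrajectoryResult]
    diagnostics: dict


def run_simulation(system: System, start_state, config: RunConfig) -> SimulationResult:
    """Run ``n_trajectories`` independent trajectories and merge candidates.

    Trajectory k is seeded from a counter-based substream of the master
    seed, so the merged result is independent of execution order.
    """
    results: list[TrajectoryResult] = []
    merged: list[CandidateRecord] = []
    serial = 0
    for k in range(config.n_trajectories):
        res = run_trajectory(
            system,
            start_state,
            config,
            trajectory_seed=(config.seed * 1_000_003 + k) % (2**31),
            trajectory_index=k,
            serial_start=serial,
        )
        serial += len(res.candidates)
        results.append(res)
        merged.extend(res.candidates)
        logger.info(
            "trajectory %d: %d candidates, move acceptance %s",
            k,
            len(res.candidates),
            [
                f"{a}/{n}" for a, n in zip(res.move_accepts, res.move_attempts)
            ],
        )

    n_rep = config.ladder.n_replicas
    attempt = {}
    accept = {}
    for res in results:
        for pair, c in res.attempt_counts.items():
            attempt[pair] = attempt.get(pair, 0) + c
        for pair, c in res.accept_counts.items():
            accept[pair] = accept.get(pair, 0) + c
    exchange_rates = {
        f"{i}-{j}": (accept.get((i, j), 0) / attempt[(i, j)]) if attempt.get((i, j)) else 0.0
        for (i, j) in sorted(attempt)
    }
    traces = [np.concatenate([r.energy_traces[s] for r in results]) if results else np.array([])
              for s in range(n_rep)]
    hist_overlap = {}
    for s in range(n_rep - 1):
        a, b = traces[s], traces[s + 1]
        if len(a) and len(b):
            lo = min(a.min(), b.min())
            hi = max(a.max(), b.max())
            if hi <= lo:
                hi = lo + 1.0
            bins = np.linspace(lo, hi, 30)
            ha, _ = np.histogram(a, bins=bins, density=True)
            hb, _ = np.histogram(b, bins=bins, density=True)
            width = bins[1] - bins[0]
            hist_overlap[f"{s}-{s + 1}"] = float(np.sum(np.minimum(ha, hb)) * width)
    diagnostics = {
        "exchange_acceptance": exchange_rates,
        "energy_mean_per_slot": [float(t.mean()) if len(t) else float("nan") for t in traces],
        "energy_histogram_overlap": hist_overlap,
        "n_candidates": len(merged),
    }
    return SimulationResult(candidates=merged, trajectories=results, diagnostics=diagnostics)
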