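"""Monte-Carlo engines: shotgun sampling and temperature replica exchange.

The building block is a plain Metropolis step over an abstract state (a
rigid-body pose for docking, an integer state index on toy landscapes),
driven by a symmetric-proposal mover and a scalar energy function.  Two
protocols are built on top of it:

* the *shotgun* protocol — many independent short trajectories (500 steps
  by default), each from a fresh random placement, with step sizes adapted
  every 50 steps toward a 50% acceptance rate; the lowest-energy
  conformation visited is the decoy;
* *ReplicaDock* — coupled replicas on a 3-level inverse-temperature
  ladder, neighbor swaps attempted every 1,000 steps (alternating even/odd
  adjacent pairs), the flat-bottom encounter restraint added to the
  sampling energy, and snapshots of all levels recorded every 1,000 steps.
  At the stated cadence 4 trajectories produce exactly
  ``4 x 3 x n_steps/1000`` decoys (60,000 at 5x10^6 steps).

Half of the sampling (half the shotgun decoys; 2 of 4 replica
trajectories) uses the capped contact term, the other half the uncapped
one.  Step-size adaptation is used only in the shotgun protocol; replica
trajectories keep fixed move parameters so stationarity is exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .centroid_energy import (
    EncounterParams,
    EnergyBreakdown,
    ScoreWeights,
    StatPotentialTable,
    make_energy_fn,
    total_interchain_cen,
)
from .model_io import CentroidModel, DecoyTable, ValidationError
from .rigid_geometry import (
    MoveParams,
    RigidPose,
    perturb_rigid_body,
    random_initial_placement,
)

logger = logging.getLogger("replidock")

#: default inverse-temperature ladder (REU^-1), coldest first; calibrated on
#: the shipped toy complex so the coldest level is bound-dominated, the
#: hottest unbound-dominated, and adjacent exchange rates sit near 25%
DEFAULT_BETAS = (1.8, 0.75, 0.3)


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass
class MCState:
    """One Metropolis chain: current state, its energy, and bookkeeping."""

    pose: object
    energy: float
    beta: float
    step: int = 0
    best_pose: object = None
    best_energy: float = math.inf
    n_accepted: int = 0
    n_proposed: int = 0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValidationError("inverse temperature must be positive")
        if self.best_pose is None:
            self.best_pose = self.pose
            self.best_energy = self.energy

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else 0.0


@dataclass(frozen=True)
class TemperatureLadder:
    """Strictly decreasing positive inverse temperatures, coldest first."""

    betas: tuple = DEFAULT_BETAS

    def __post_init__(self):
        b = tuple(float(x) for x in self.betas)
        object.__setattr__(self, "betas", b)
        if any(x <= 0 for x in b):
            raise ValidationError("all inverse temperatures must be positive")
        if any(b[i] <= b[i + 1] for i in range(len(b) - 1)):
            raise ValidationError("ladder must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.betas)

    @property
    def middle(self) -> float:
        return self.betas[len(self.betas) // 2]


@dataclass
class DecoyRecord:
    """One snapshot: pose, energy breakdown and provenance."""

    pose: RigidPose
    energies: EnergyBreakdown
    level: int
    step: int
    traj: int
    capped: bool


@dataclass
class ShotgunConfig:
    """Shotgun protocol parameters (one decoy per independent trajectory)."""

    n_steps: int = 500
    adapt_every: int = 50
    beta: float | None = None  # default: middle ladder level
    move_params: MoveParams = field(default_factory=MoveParams)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    tables: StatPotentialTable | None = None
    capped_fraction: float = 0.5

    def resolved_beta(self) -> float:
        return self.beta if self.beta is not None else TemperatureLadder().middle


@dataclass
class ReplicaConfig:
    """ReplicaDock protocol parameters."""

    n_trajectories: int = 4
    ladder: TemperatureLadder = field(default_factory=TemperatureLadder)
    n_steps: int = 5_000_000
    swap_stride: int = 1000
    snapshot_stride: int = 1000
    capped_fraction: float = 0.5
    move_params: MoveParams = field(default_factory=MoveParams)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    tables: StatPotentialTable | None = None
    encounter_gap: float = 8.0
    encounter_k: float = 0.25

    def __post_init__(self):
        if self.n_steps % self.swap_stride or self.n_steps % self.snapshot_stride:
            raise ValidationError("strides must divide n_steps")
        if not 0.0 <= self.capped_fraction <= 1.0:
            raise ValidationError("capped_fraction must be in [0, 1]")

    @property
    def expected_records(self) -> int:
        """Closed-form record count: trajectories x levels x snapshots."""
        return self.n_trajectories * len(self.ladder) * (
            self.n_steps // self.snapshot_stride
        )


# ---------------------------------------------------------------------------
# Metropolis
# ---------------------------------------------------------------------------

def metropolis_step(state: MCState, mover, energy_fn, rng: np.random.Generator) -> MCState:
    """One Metropolis update: propose, accept with min(1, exp(-beta dE)).

    The mover must have a symmetric proposal density.  A non-finite
    proposed energy rejects the move with a logged warning.  On rejection
    the pose is left untouched; the best-so-far is updated on acceptance.
    """
    proposal = mover(state.pose, rng)
    e = energy_fn(proposal)
    state.step += 1
    state.n_proposed += 1
    if not math.isfinite(e):
        logger.warning("rejecting proposal with non-finite energy at step %d", state.step)
        return state
    d_e = e - state.energy
    if d_e <= 0.0 or rng.random() < math.exp(-state.beta * d_e):
        state.pose = proposal
        state.energy = e
        state.n_accepted += 1
        if e < state.best_energy:
            state.best_energy = e
            state.best_pose = proposal
    return state


def adapt_step_size(params: MoveParams, recent_acceptance: float) -> MoveParams:
    """Multiplicative step-size controller toward 50% acceptance.

    Both magnitudes scale by ``recent_acceptance / 0.5`` clamped to
    [0.5, 2.0] per adjustment, bounded below by 1e-4.
    """
    if not 0.0 <= recent_acceptance <= 1.0:
        raise ValidationError("acceptance fraction must be in [0, 1]")
    factor = min(2.0, max(0.5, recent_acceptance / 0.5))
    return MoveParams(
        translation_sigma=max(1e-4, params.translation_sigma * factor),
        rotation_magnitude=max(1e-4, params.rotation_magnitude * factor),
    )


def run_adaptive_mc(
    pose0,
    energy_fn,
    n_steps: int,
    params: MoveParams,
    beta: float,
    rng: np.random.Generator,
    adapt_every: int = 50,
    mover_factory=None,
):
    """A single adaptive Metropolis trajectory (the shotgun inner loop).

    Returns ``(state, params, last_window_acceptance)`` where ``state``
    carries the lowest-energy pose visited.
    """
    if mover_factory is None:
        mover_factory = lambda p: (  # noqa: E731
            lambda pose, r: perturb_rigid_body(pose, p, r)
        )
    state = MCState(pose=pose0, energy=energy_fn(pose0), beta=beta)
    params = params.copy()
    mover = mover_factory(params)
    window_accepted = 0
    window_start = 0
    last_window = 0.0
    for i in range(1, n_steps + 1):
        before = state.n_accepted
        metropolis_step(state, mover, energy_fn, rng)
        window_accepted += state.n_accepted - before
        if adapt_every and i % adapt_every == 0:
            last_window = window_accepted / (i - window_start)
            params = adapt_step_size(params, last_window)
            mover = mover_factory(params)
            window_accepted = 0
            window_start = i
    return state, params, last_window


def run_shotgun(
    model: CentroidModel,
    n_decoys: int,
    config: ShotgunConfig | None = None,
    rng: np.random.Generator | None = None,
) -> DecoyTable:
    """Shotgun sampling: independent 500-step adaptive minimizations.

    Each decoy starts from a fresh random placement (slid into contact)
    and records the lowest-energy conformation visited.  Decoys up to
    ``capped_fraction`` of the total are scored with the capped contact
    term, the rest uncapped.
    """
    if n_decoys < 1:
        raise ValidationError("n_decoys must be >= 1")
    config = config or ShotgunConfig()
    rng = rng if rng is not None else np.random.default_rng()
    beta = config.resolved_beta()
    n_capped = round(n_decoys * config.capped_fraction)
    records = []
    for i in range(n_decoys):
        capped = i < n_capped
        weights = config.weights.with_cap(capped)
        energy_fn = make_energy_fn(model, weights, config.tables)
        pose0 = random_initial_placement(model, rng)
        state, _, _ = run_adaptive_mc(
            pose0, energy_fn, config.n_steps, config.move_params, beta, rng,
            adapt_every=config.adapt_every,
        )
        breakdown = total_interchain_cen(model, state.best_pose, weights, config.tables)
        records.append(
            DecoyRecord(
                pose=state.best_pose, energies=breakdown,
                level=0, step=state.step, traj=i, capped=capped,
            )
        )
    return DecoyTable.from_records(records, meta={"protocol": "shotgun"})


# ---------------------------------------------------------------------------
# Replica exchange
# ---------------------------------------------------------------------------

def attempt_swap(state_i: MCState, state_j: MCState, rng: np.random.Generator) -> bool:
    """Attempt a replica swap between two temperature levels.

    Accepted with probability min(1, exp((beta_i - beta_j)(E_i - E_j)));
    on acceptance the poses (and energies, and best-so-far bookkeeping of
    the configurations) are exchanged between the levels.
    """
    if state_i.beta == state_j.beta:
        raise ValidationError("swap requires distinct inverse temperatures")
    exponent = (state_i.beta - state_j.beta) * (state_i.energy - state_j.energy)
    if exponent >= 0.0 or rng.random() < math.exp(exponent):
        state_i.pose, state_j.pose = state_j.pose, state_i.pose
        state_i.energy, state_j.energy = state_j.energy, state_i.energy
        for s in (state_i, state_j):
            if s.energy < s.best_energy:
                s.best_energy = s.energy
                s.best_pose = s.pose
        return True
    return False


@dataclass
class ExchangeStats:
    """Per-adjacent-pair swap bookkeeping."""

    attempts: np.ndarray
    accepts: np.ndarray

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.attempts > 0, self.accepts / np.maximum(self.attempts, 1), np.nan)


def run_replica_exchange(
    states: list[MCState],
    mover,
    energy_fn,
    n_steps: int,
    swap_stride: int,
    rng: np.random.Generator,
    snapshot_stride: int | None = None,
    on_snapshot=None,
) -> ExchangeStats:
    """Generic coupled-replica engine over any state space.

    Every ``swap_stride`` steps, adjacent-pair swaps are attempted with an
    alternating even/odd phase (standard replica-exchange practice that
    preserves detailed balance).  ``on_snapshot(step, states)`` fires every
    ``snapshot_stride`` steps.
    """
    n_levels = len(states)
    stats = ExchangeStats(
        attempts=np.zeros(max(n_levels - 1, 1), dtype=int),
        accepts=np.zeros(max(n_levels - 1, 1), dtype=int),
    )
    swap_event = 0
    for step in range(1, n_steps + 1):
        for s in states:
            metropolis_step(s, mover, energy_fn, rng)
        if swap_stride and step % swap_stride == 0:
            phase = swap_event % 2
            for i in range(phase, n_levels - 1, 2):
                stats.attempts[i] += 1
                if attempt_swap(states[i], states[i + 1], rng):
                    stats.accepts[i] += 1
            swap_event += 1
        if snapshot_stride and on_snapshot and step % snapshot_stride == 0:
            on_snapshot(step, states)
    return stats


def run_replica_dock(
    model: CentroidModel,
    config: ReplicaConfig | None = None,
    rng: np.random.Generator | None = None,
) -> DecoyTable:
    """ReplicaDock: replica-exchange rigid-body docking.

    Each trajectory runs the full ladder of coupled replicas with the
    encounter restraint added to the sampling energy; snapshots of every
    level are recorded each ``snapshot_stride`` steps, so the record count
    is exactly ``n_trajectories * n_levels * n_steps / snapshot_stride``.
    """
    config = config or ReplicaConfig()
    rng = rng if rng is not None else np.random.default_rng()
    encounter = EncounterParams.from_model(
        model, gap=config.encounter_gap, k=config.encounter_k
    )
    n_capped = round(config.n_trajectories * config.capped_fraction)
    records: list[DecoyRecord] = []
    all_rates = []
    for traj in range(config.n_trajectories):
        capped = traj < n_capped
        weights = config.weights.with_cap(capped)
        energy_fn = make_energy_fn(model, weights, config.tables, encounter)
        states = []
        for beta in config.ladder.betas:
            pose = random_initial_placement(model, rng)
            e = energy_fn(pose)
            if not math.isfinite(e):
                raise ValidationError(
                    f"non-finite initial energy in trajectory {traj}"
                )
            states.append(MCState(pose=pose, energy=e, beta=beta))

        def snapshot(step, states, _traj=traj, _capped=capped, _w=weights):
            for level, s in enumerate(states):
                breakdown = total_interchain_cen(
                    model, s.pose, _w, config.tables, encounter
                )
                records.append(
                    DecoyRecord(
                        pose=s.pose, energies=breakdown,
                        level=level, step=step, traj=_traj, capped=_capped,
                    )
                )

        mover = lambda pose, r: perturb_rigid_body(pose, config.move_params, r)  # noqa: E731
        stats = run_replica_exchange(
            states, mover, energy_fn,
            n_steps=config.n_steps, swap_stride=config.swap_stride, rng=rng,
            snapshot_stride=config.snapshot_stride, on_snapshot=snapshot,
        )
        rates = stats.rates
        all_rates.append(rates)
        logger.info(
            "trajectory %d exchange rates per adjacent pair: %s",
            traj, np.array2string(rates, precision=3),
        )
    table = DecoyTable.from_records(
        records,
        meta={
            "protocol": "replica",
            "n_trajectories": config.n_trajectories,
            "betas": ",".join(f"{b:g}" for b in config.ladder.betas),
            "exchange_rates": ";".join(
                np.array2string(r, precision=3) for r in all_rates
            ),
        },
    )
    assert len(table) == config.expected_records
    return table


# ---------------------------------------------------------------------------
# Post-hoc filtering and ladder tuning
# ---------------------------------------------------------------------------

def filter_decoys(
    table: DecoyTable,
    energy_cutoff: float = 10.0,
    drop_coldest: bool = False,
    drop_hottest: bool = True,
    top_k: int | None = None,
) -> DecoyTable:
    """Post-hoc decoy selection.

    Removes the excluded temperature level(s), drops rows with total
    interchain score strictly above ``energy_cutoff``, and optionally
    keeps the ``top_k`` lowest-total rows (ties broken by trajectory id,
    then step).  An empty result is returned with a warning.
    """
    if len(table) == 0:
        raise ValidationError("cannot filter an empty decoy table")
    df = table.df
    keep = np.ones(len(df), dtype=bool)
    levels = df["level"].to_numpy()
    if drop_hottest and levels.max() > levels.min():
        keep &= levels != levels.max()
    if drop_coldest and levels.max() > levels.min():
        keep &= levels != levels.min()
    keep &= df["total"].to_numpy() <= energy_cutoff
    out = df[keep]
    if top_k is not None and len(out) > top_k:
        out = out.sort_values(
            ["total", "traj", "step"], kind="mergesort"
        ).head(top_k)
    if len(out) == 0:
        logger.warning("all decoys removed by filtering")
        return DecoyTable(df.iloc[0:0], meta=table.meta)
    return DecoyTable(out.reset_index(drop=True), meta=table.meta)


def tune_ladder(
    model: CentroidModel,
    beta_cold: float | None = None,
    n_levels: int = 3,
    target_rate: float = 0.25,
    pilot_steps: int = 4000,
    swap_stride: int = 200,
    rng: np.random.Generator | None = None,
    tolerance: float = 0.05,
    max_iter: int = 8,
) -> TemperatureLadder:
    """Adjust a geometric ladder to a target adjacent exchange rate.

    The ladder is parameterized as ``beta_i = beta_cold * r^i`` and the
    spacing ratio ``r`` is bisected against the mean adjacent exchange
    rate measured on short pilot replica runs (closer temperatures raise
    the rate).
    """
    rng = rng if rng is not None else np.random.default_rng()
    if beta_cold is None:
        beta_cold = DEFAULT_BETAS[0]

    def rate_for(ratio: float) -> float:
        betas = tuple(beta_cold * ratio**i for i in range(n_levels))
        config = ReplicaConfig(
            n_trajectories=1,
            ladder=TemperatureLadder(betas),
            n_steps=pilot_steps,
            swap_stride=swap_stride,
            snapshot_stride=pilot_steps,
        )
        table = run_replica_dock(model, config, rng)
        rates = [
            float(x)
            for x in table.meta["exchange_rates"].strip("[]").split()
        ]
        return float(np.mean(rates))

    lo, hi = 0.05, 0.95
    ratio = 0.5
    for _ in range(max_iter):
        ratio = 0.5 * (lo + hi)
        r = rate_for(ratio)
        if abs(r - target_rate) <= tolerance:
            break
        if r < target_rate:
            lo = ratio  # spacing too wide; bring temperatures closer
        else:
            hi = ratio
    betas = tuple(beta_cold * ratio**i for i in range(n_levels))
    return TemperatureLadder(betas)
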