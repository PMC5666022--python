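"""Trial execution: sequencing the sub-models per model variant.

One time step of the full threshold-modified (TM) model is:

    spawn -> move down -> structural removal + weight calculation
          -> warning signals -> threshold coordination
          -> local pattern calculation -> fall

TM_STABLE and TM_UNSTABLE share this ordering with a restricted
coordination rule; NTM goes straight from warning signals to the fall
check.  Local-pattern estimates are therefore always one step old when
coordination consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lattice import DropletEvent, World, compute_weights
from .params import SimParams
from . import submodels as sm


@dataclass
class TrialResult:
    """Event log and per-step metrics of one trial."""
    trial: int
    events: list          # DropletEvent, time-ordered
    eq4_log: list         # (t, agent_id) structural removals
    metrics: pd.DataFrame  # t, n_inactive, n_active, width, height
    world: World = field(repr=False, default=None)

    @property
    def event_times(self) -> np.ndarray:
        return np.array([e.t for e in self.events], dtype=int)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([e.size for e in self.events], dtype=int)


def trial_rng(master_seed: int, trial: int) -> np.random.Generator:
    """Per-trial generator derived from (master_seed, trial).

    The splitting rule is positional, so increasing the trial count never
    reshuffles earlier trials.
    """
    return np.random.default_rng([int(master_seed), int(trial)])


def run_trial(params: SimParams, trial: int = 0,
              rng: np.random.Generator | None = None,
              collect_metrics: bool = True,
              check_invariants: bool = False) -> TrialResult:
    """Run one seeded trial of ``params.time_length`` steps."""
    if rng is None:
        rng = trial_rng(params.seed, trial)
    world = World(rod=params.rod)
    coordinated = params.variant != "NTM"
    rows = []
    for t in range(1, params.time_length + 1):
        world.t = t
        sm.spawn_agents(world, params, rng)
        sm.move_down_step(world, params, rng)
        sm.remove_unsupported(world)
        compute_weights(world)
        sm.warning_signal_step(world, rng)
        if coordinated:
            sm.threshold_coordination_step(world, params)
            sm.local_pattern_step(world)
        sm.fall_step(world, rng)
        if collect_metrics:
            width, height = world.extent()
            rows.append((t, len(world.inactive), len(world.active),
                         width, height))
        if check_invariants:
            world.check_invariants()
    metrics = pd.DataFrame(
        rows, columns=["t", "n_inactive", "n_active", "width", "height"])
    return TrialResult(trial=trial, events=list(world.droplet_events),
                       eq4_log=list(world.removed_log), metrics=metrics,
                       world=world)


def run_trials(params: SimParams, n_trials: int | None = None,
               collect_metrics: bool = True) -> list[TrialResult]:
    """Run ``n_trials`` independent trials (default ``params.n_trials``)."""
    n = params.n_trials if n_trials is None else n_trials
    return [run_trial(params, trial=i, collect_metrics=collect_metrics)
            for i in range(n)]


def events_frame(results: list[TrialResult]) -> pd.DataFrame:
    """Flatten event logs into the CSV schema
    ``trial,t,event_type,size,trigger_id`` (droplets and structural
    removals interleaved in time order)."""
    rows = []
    for r in results:
        for e in r.events:
            rows.append((r.trial, e.t, "droplet", e.size, e.trigger_id))
        for (t, aid) in r.eq4_log:
            rows.append((r.trial, t, "eq4_removal", 1, aid))
    df = pd.DataFrame(
        rows, columns=["trial", "t", "event_type", "size", "trigger_id"])
    return df.sort_values(["trial", "t"], kind="stable").reset_index(drop=True)


def metrics_frame(results: list[TrialResult]) -> pd.DataFrame:
    """Concatenate per-step metrics with a leading ``trial`` column."""
    frames = []
    for r in results:
        df = r.metrics.copy()
        df.insert(0, "trial", r.trial)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
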