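"""Run-level simulation parameters and configuration validation.

Defaults reproduce the standard operating point of the model: one agent
enters per time step from a single-site rod, descends with probability 0.9
(0.05 each sideways), settles with weight threshold 5, and a trial lasts
1000 steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

VARIANTS = ("TM", "NTM", "TM_STABLE", "TM_UNSTABLE")

#: Default rod location (a single lattice site agents enter from).
ROD = (500, 500)


class ConfigError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


@dataclass(frozen=True)
class SimParams:
    """All parameters of one simulation experiment.

    Attributes
    ----------
    phi : int
        Agents entering the system per time step (>= 1).
    prob_y_minus, prob_x_plus, prob_x_minus : float
        Movement probabilities of active agents (must sum to 1).
    threshold0 : float
        Initial weight threshold assigned to an agent when it settles.
    time_length : int
        Time steps per trial.
    n_trials : int
        Number of independent trials in an experiment.
    variant : str
        "TM" (full threshold coordination), "NTM" (none),
        "TM_STABLE" (raise-only), "TM_UNSTABLE" (collapse-only).
    entry_positions : tuple of (x, y)
        Candidate entry sites, sampled uniformly per entering agent.  Each
        must lie on the rod row or at most two rows below it.
    rod : (x, y)
        The rod site.  Agents never occupy sites above its row.
    seed : int
        Master seed; per-trial generators are derived from (seed, trial).
    """

    phi: int = 1
    prob_y_minus: float = 0.9
    prob_x_plus: float = 0.05
    prob_x_minus: float = 0.05
    threshold0: float = 5.0
    time_length: int = 1000
    n_trials: int = 100
    variant: str = "TM"
    entry_positions: tuple = ((500, 500),)
    rod: tuple = ROD
    seed: int = 0

    def __post_init__(self):
        if self.phi < 1:
            raise ConfigError(f"phi must be >= 1 (got {self.phi})")
        probs = (self.prob_y_minus, self.prob_x_plus, self.prob_x_minus)
        if any(p < 0 for p in probs):
            raise ConfigError(f"movement probabilities must be >= 0 (got {probs})")
        if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise ConfigError(
                f"prob_y_minus + prob_x_plus + prob_x_minus must equal 1 "
                f"(got {sum(probs):.6g})"
            )
        if not self.threshold0 > 0:
            raise ConfigError(f"threshold0 must be > 0 (got {self.threshold0})")
        if self.time_length < 1:
            raise ConfigError(f"time_length must be >= 1 (got {self.time_length})")
        if self.n_trials < 1:
            raise ConfigError(f"n_trials must be >= 1 (got {self.n_trials})")
        if self.variant not in VARIANTS:
            raise ConfigError(
                f"variant must be one of {VARIANTS} (got {self.variant!r})"
            )
        if not self.entry_positions:
            raise ConfigError("entry_positions must not be empty")
        object.__setattr__(
            self, "entry_positions",
            tuple((int(x), int(y)) for x, y in self.entry_positions),
        )
        rod_y = self.rod[1]
        for (x, y) in self.entry_positions:
            if y > rod_y:
                raise ConfigError(
                    f"entry position ({x}, {y}) lies above the rod row (y={rod_y})"
                )
            if y < rod_y - 2:
                raise ConfigError(
                    f"entry position ({x}, {y}) lies more than 2 rows below "
                    f"the rod row (y={rod_y})"
                )

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


#: Mapping from flat config-file keys to SimParams field names.
_KEY_MAP = {
    "phi": "phi",
    "prob_y_minus": "prob_y_minus",
    "prob_x_plus": "prob_x_plus",
    "prob_x_minus": "prob_x_minus",
    "threshold": "threshold0",
    "threshold0": "threshold0",
    "time_length": "time_length",
    "n_trials": "n_trials",
    "variant": "variant",
    "entry_positions": "entry_positions",
    "rod": "rod",
    "seed": "seed",
}


def validate_config(raw: dict | None) -> SimParams:
    """Build :class:`SimParams` from a flat key-value mapping.

    Omitted keys take the default values; unknown keys and invariant
    violations raise :class:`ConfigError` naming the offending key.
    """
    raw = dict(raw or {})
    kwargs = {}
    for key, value in raw.items():
        if key not in _KEY_MAP:
            raise ConfigError(f"unknown configuration key {key!r}")
        kwargs[_KEY_MAP[key]] = value
    if "entry_positions" in kwargs:
        kwargs["entry_positions"] = tuple(
            tuple(p) for p in kwargs["entry_positions"]
        )
    if "rod" in kwargs:
        kwargs["rod"] = tuple(kwargs["rod"])
    try:
        return SimParams(**kwargs)
    except TypeError as exc:  # e.g. non-numeric value
        raise ConfigError(str(exc)) from exc
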