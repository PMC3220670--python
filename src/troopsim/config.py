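"""Model configuration.

Every tunable parameter of the simulator lives in :class:`ModelConfig`:
the physical field, perception, grouping, contest and avoidance
parameters, the model-variant switch, the timing regime and all the
robustness toggles.  Defaults are the standard study conditions for a
group of 30 agents.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

VARIANTS = ("fleeing", "avoidance", "avoidance_fleeing_control", "velocity")
TIMING_REGIMES = ("exponential", "uniform")
AVOIDANCE_MODES = ("discrete", "probabilistic")


@dataclass(frozen=True)
class ModelConfig:
    """All parameters of one simulation run.

    Distances are meters, angles degrees, times in simulation steps
    (one step is one "second").

    Parameters
    ----------
    variant:
        ``fleeing`` — contests and rank-dependent fleeing only;
        ``avoidance`` — fleeing plus proactive avoidance of potential
        aggressors at a distance; ``avoidance_fleeing_control`` —
        avoidance with every pairwise win chance forced to 0.5 (removes
        rank-dependent fleeing); ``velocity`` — no avoidance, win
        chances 0.5, agents differ only in step length.
    """

    # --- environment / group ---
    L: float = 300.0            # field side length (torus)
    n_agents: int = 30          # N, group size
    init_sigma: float = 10.0    # SD of the initial Gaussian placement

    # --- perception ---
    pers_dist: float = 4.0      # encounter ("personal") radius
    near_dist: float = 20.0     # grouping radius
    max_dist: float = 50.0      # maximum perceivable distance
    view_angle: float = 120.0   # default view cone
    min_others: int = 3         # preferred number of neighbors in view

    # --- cohesion ---
    far_dist: float = 110.0     # max tolerated distance to furthest member
    fission_restricted: bool = True

    # --- movement ---
    walk_d: float = 1.0         # default forward step
    max_turn_angle: float = 180.0  # random-walk turn bound (robustness: 45/90/135)

    # --- contests ---
    max_dom: float = 1.0        # dominance of the top rank
    chase_d: float = 1.0        # winner chase displacement
    flee_d: float = 2.0         # loser flee displacement (robustness sweep 1-20)

    # --- avoidance ---
    avoid_d: float = 2.0        # avoidance displacement
    av_dom_diff: float = 0.2    # dominance gap above which others are avoided
    av_dist: float = 5.0        # distance within which aggressors are avoided
    avoidance_mode: str = "discrete"
    avoidance_slope: float = 30.0  # sigmoid slope (probabilistic mode)

    # --- velocity model ---
    max_velocity: float = 10.0  # fastest (lowest-rank) step length
    equal_velocities: bool = False  # null control: all step lengths equal

    # --- scheduling / sampling ---
    mean_interval: float = 10.0
    timing_regime: str = "exponential"
    total_steps: float = 72_000.0
    burn_in: float = 36_000.0
    sample_every: float = 900.0

    # --- variant & misc ---
    variant: str = "fleeing"
    encounter_full_circle: bool = False  # allow encounters from behind
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.timing_regime not in TIMING_REGIMES:
            raise ValueError(f"unknown timing regime {self.timing_regime!r}")
        if self.avoidance_mode not in AVOIDANCE_MODES:
            raise ValueError(f"unknown avoidance mode {self.avoidance_mode!r}")
        if self.n_agents < 2:
            raise ValueError("need at least two agents")
        if not (0.0 < self.pers_dist < self.near_dist < self.max_dist
                < self.far_dist <= self.L * math.sqrt(2.0) / 2.0):
            raise ValueError(
                "expected 0 < pers_dist < near_dist < max_dist < far_dist "
                "<= L*sqrt(2)/2")
        if not 0.0 < self.av_dom_diff < self.max_dom:
            raise ValueError("av_dom_diff must lie in (0, max_dom)")
        if self.max_dom <= 0.0:
            raise ValueError("max_dom must be positive")
        if self.mean_interval <= 0.0:
            raise ValueError("mean_interval must be positive")
        if not 0.0 <= self.burn_in < self.total_steps:
            raise ValueError("need 0 <= burn_in < total_steps")
        if self.sample_every <= 0.0:
            raise ValueError("sample_every must be positive")
        if not 0 <= int(self.seed) < 2**31:
            raise ValueError("seed must lie in [0, 2**31)")
        for name in ("walk_d", "flee_d", "chase_d", "avoid_d",
                     "max_velocity", "av_dist", "view_angle",
                     "max_turn_angle", "init_sigma"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")

    # --- derived quantities -------------------------------------------------

    @property
    def beta(self) -> float:
        """Steepness of the sigmoid win-chance function (6 / max_dom)."""
        return 6.0 / self.max_dom

    @property
    def uses_avoidance(self) -> bool:
        return self.variant in ("avoidance", "avoidance_fleeing_control")

    @property
    def equal_win_chance(self) -> bool:
        """True where every pairwise win chance is forced to 0.5."""
        return self.variant in ("avoidance_fleeing_control", "velocity")

    @property
    def n_snapshots(self) -> int:
        return int((self.total_steps - self.burn_in) // self.sample_every)

    # --- construction / serialization --------------------------------------

    def replace(self, **changes) -> "ModelConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ModelConfig":
        """Load a flat key-value YAML (or JSON) config file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of parameters")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
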