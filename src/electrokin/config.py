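"""Configuration objects for the synthetic session generator.

The generator emulates nocturnal exploration sessions of a pulse-type
weakly electric fish in a square arena whose central region is imaged by
an overhead camera. Frames are sampled at the animal's own electric organ
discharges (EODs), i.e. on an irregular time base with a mean rate near
25 Hz. The movement repertoire is a fixed table of prototypical movements
(PMs) expressed as mean thrust/slip/yaw velocities; all but two PMs come
in mirror pairs (equal thrust, sign-opposed slip and yaw).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class ConfigError(ValueError):
    """Raised when a generator or pipeline configuration is invalid."""


#: Macro-behaviors scripted by the generator. ``cruise`` is undirected
#: forward swimming; the other four are object-directed and only occur
#: when an object is present.
BEHAVIORS = ("cruise", "approach", "stationary", "backwards", "departure")

OBJECT_BEHAVIORS = ("approach", "stationary", "backwards", "departure")

#: Default prototype table, one row per PM (thrust cm/s, slip cm/s,
#: yaw deg/s). PM 01 is the single backward-thrust prototype, PM 02 the
#: single low-rotation forward prototype; PMs 03-10 form four mirror
#: pairs of graded rotation amplitude. These are generator defaults, not
#: values measured from any animal.
DEFAULT_PROTOTYPES = np.array(
    [
        [-3.0, 0.0, 0.0],    # PM 01  backward / stationary probing
        [8.0, 0.0, 0.0],     # PM 02  slow straight forward
        [16.0, 4.0, 40.0],   # PM 03  fast translation, left
        [16.0, -4.0, -40.0], # PM 04  fast translation, right
        [12.0, 6.0, 90.0],   # PM 05
        [12.0, -6.0, -90.0], # PM 06
        [8.0, 6.0, 160.0],   # PM 07
        [8.0, -6.0, -160.0], # PM 08
        [5.0, 4.0, 240.0],   # PM 09  strong rotation, left
        [5.0, -4.0, -240.0], # PM 10  strong rotation, right
    ]
)

#: Per-PM emission SDs (thrust, slip, yaw). PM 01 gets a wider thrust SD:
#: its frames are emitted with behavior-specific thrust means (stationary
#: vs backwards), and the wider SD keeps the pooled PM 01 thrust
#: distribution a single cluster with a bimodal interior.
DEFAULT_EMISSION_SD = np.array(
    [[1.5, 0.9, 11.0]] + [[0.9, 0.9, 11.0]] * 9
)

#: Mean EOD rate (Hz) while executing each PM. Slow translational PMs
#: carry low rates, high-amplitude PMs high rates; the data-weighted
#: average under the default behavior mix is close to 25 Hz.
DEFAULT_FEOD_BASE = np.array(
    [22.0, 22.0, 33.0, 33.0, 27.0, 27.0, 25.0, 25.0, 31.0, 31.0]
)

DEFAULT_SCRIPT_WEIGHTS = {
    "cruise": 0.50,
    "approach": 0.15,
    "stationary": 0.15,
    "backwards": 0.10,
    "departure": 0.10,
}

#: Median segment durations in seconds (log-normal draws). Stationary
#: probing is short (~0.6 s of near-zero thrust), backwards swimming a
#: little longer (~0.9 s of reversed thrust), matching the time scales
#: of the onset-triggered averages downstream.
DEFAULT_DURATION_MEDIANS = {
    "cruise": 2.0,
    "approach": 1.1,
    "stationary": 0.6,
    "backwards": 0.9,
    "departure": 1.1,
}


def mirror_pairs_from_table(table: np.ndarray, tol: float = 1e-6) -> list[tuple[int, int]]:
    """Return 0-based index pairs (i, j) with thrust_i == thrust_j,
    slip_i == -slip_j and yaw_i == -yaw_j (within ``tol``), requiring a
    nonzero slip or yaw so the two members are distinct."""
    pairs = []
    used: set[int] = set()
    k = len(table)
    for i in range(k):
        if i in used:
            continue
        for j in range(i + 1, k):
            if j in used:
                continue
            ti, si, yi = table[i]
            tj, sj, yj = table[j]
            if (
                abs(ti - tj) <= tol
                and abs(si + sj) <= tol
                and abs(yi + yj) <= tol
                and (abs(si) > tol or abs(yi) > tol)
            ):
                pairs.append((i, j))
                used.update((i, j))
                break
    return pairs


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    Geometry is in cm with the origin at the arena center (which is also
    the default object position), x rightward, y upward; headings are in
    degrees with 0 = +x and counterclockwise positive.
    """

    arena_extent: tuple[float, float] = (80.0, 80.0)
    view_extent: tuple[float, float] = (64.0, 48.0)
    object_present: bool = True
    object_edge_cm: float = 2.0
    object_position: tuple[float, float] = (0.0, 0.0)
    shelter_positions: tuple[tuple[float, float], ...] = ((0.0, 21.0), (0.0, -21.0))
    prototype_table: np.ndarray = field(default_factory=lambda: DEFAULT_PROTOTYPES.copy())
    emission_sd: np.ndarray = field(default_factory=lambda: DEFAULT_EMISSION_SD.copy())
    behavior_script_weights: dict = field(default_factory=lambda: dict(DEFAULT_SCRIPT_WEIGHTS))
    behavior_duration_medians: dict = field(default_factory=lambda: dict(DEFAULT_DURATION_MEDIANS))
    behavior_duration_sigma: float = 0.35
    feod_base_table: np.ndarray = field(default_factory=lambda: DEFAULT_FEOD_BASE.copy())
    feod_near_gain: float = 1.2
    feod_near_radius_cm: float = 5.0
    ipi_shape: float = 10.0
    n_frames_target: int = 10_000
    seed: int = 0
    #: Enforce the canonical 10-PM structure (one backward, one
    #: low-rotation forward, four mirror pairs). Disable for degenerate
    #: test tables; the generator then runs a single generic behavior
    #: over all PMs.
    check_prototype_structure: bool = True

    # -- derived ---------------------------------------------------------

    @property
    def n_prototypes(self) -> int:
        return len(self.prototype_table)

    @property
    def condition(self) -> str:
        return "object" if self.object_present else "no_object"

    def mirror_pairs(self) -> list[tuple[int, int]]:
        """0-based mirror-pair indices of the prototype table."""
        return mirror_pairs_from_table(np.asarray(self.prototype_table))

    def replace(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        table = np.asarray(self.prototype_table, dtype=float)
        sd = np.asarray(self.emission_sd, dtype=float)
        rates = np.asarray(self.feod_base_table, dtype=float)
        if table.ndim != 2 or table.shape[1] != 3:
            raise ConfigError("prototype_table must be (k, 3)")
        if sd.shape != table.shape:
            raise ConfigError("emission_sd must match prototype_table shape")
        if rates.shape != (len(table),):
            raise ConfigError("feod_base_table must have one rate per PM")
        if np.any(rates <= 0):
            raise ConfigError("all EOD rates must be > 0")
        if self.ipi_shape <= 0:
            raise ConfigError("ipi_shape must be > 0")
        if self.feod_near_gain <= 0 or self.feod_near_radius_cm <= 0:
            raise ConfigError("near-field gain and radius must be > 0")
        if not (
            self.view_extent[0] <= self.arena_extent[0]
            and self.view_extent[1] <= self.arena_extent[1]
        ):
            raise ConfigError("view_extent must be contained in arena_extent")
        if self.object_edge_cm <= 0:
            raise ConfigError("object_edge_cm must be > 0")
        w = self.behavior_script_weights
        if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise ConfigError("behavior weights must be nonnegative and normalizable")
        unknown = set(w) - set(BEHAVIORS)
        if unknown:
            raise ConfigError(f"unknown behaviors in weights: {sorted(unknown)}")
        if self.n_frames_target < 2:
            raise ConfigError("n_frames_target must be at least 2")
        if self.check_prototype_structure:
            self._validate_structure(table)

    def _validate_structure(self, table: np.ndarray) -> None:
        backward = np.flatnonzero(table[:, 0] < 0)
        if len(backward) != 1:
            raise ConfigError("exactly one backward-thrust prototype required")
        pairs = mirror_pairs_from_table(table)
        if len(pairs) != 4:
            raise ConfigError(f"expected 4 mirror pairs, found {len(pairs)}")
        paired = {i for p in pairs for i in p}
        singles = [i for i in range(len(table)) if i not in paired]
        forward_single = [
            i for i in singles if table[i, 0] > 0 and i not in backward
        ]
        if len(forward_single) != 1:
            raise ConfigError("exactly one unpaired low-velocity forward prototype required")
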