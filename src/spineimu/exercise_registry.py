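"""Registry of the ten spine rehabilitation exercises.

Each exercise targets a spine segment (cervical CS, thoracic TS, lumbar LS or
whole spine WS), is assessed through one kinematic angle, and requires two
IMUs at specific body sites.  The measured angle maps onto one ZXY Euler
channel: flexion -> gamma (z-roll), rotation -> alpha (y-yaw),
abduction -> beta (x-pitch).

The first listed IMU site is the distal (anatomically active) segment, the
second the proximal reference.  Placement checks are order-free: the
classifier reports sites, and the distal/proximal roles are resolved from
the registry order.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass

import yaml

from .errors import InvalidArgumentError

__all__ = [
    "ExerciseSpec",
    "PlacementCheck",
    "EXERCISES",
    "LOCATIONS",
    "LOCATION_CODES",
    "get_spec",
    "list_exercises",
    "check_placement",
    "registry_to_yaml",
]

#: The five IMU sites, in label-code order 1..5.
LOCATIONS = ("head", "thorax", "pelvis", "upper_arm", "thigh")
LOCATION_CODES = {name: i + 1 for i, name in enumerate(LOCATIONS)}


@dataclass(frozen=True)
class ExerciseSpec:
    """One exercise: target spine segment, measured angle, and IMU sites."""

    name: str
    spine_segment: str
    angle_name: str
    channel: str  # flexion | rotation | abduction
    imu_locations: tuple[str, str]  # (distal, proximal)

    @property
    def distal(self) -> str:
        return self.imu_locations[0]

    @property
    def proximal(self) -> str:
        return self.imu_locations[1]


@dataclass(frozen=True)
class PlacementCheck:
    """Outcome of comparing detected IMU sites against an exercise spec."""

    ok: bool
    expected: tuple[str, str]
    detected: tuple[str, str]
    wrong_sites: tuple[str, ...]

    def message(self) -> str:
        if self.ok:
            return "placement ok"
        return (
            f"IMU placement mismatch: detected {self.wrong_sites} not part of "
            f"expected sites {self.expected}"
        )


_SPECS = [
    ExerciseSpec("supine chin tuck head lift rotation", "CS", "Neck rotation",
                 "rotation", ("head", "thorax")),
    ExerciseSpec("dead bug unilateral isometric hold", "LS", "Hip flexion",
                 "flexion", ("thigh", "pelvis")),
    ExerciseSpec("pilates saw", "TS and LS", "Thorax rotation",
                 "rotation", ("thorax", "pelvis")),
    ExerciseSpec("catcow full spine", "WS", "Neck flexion",
                 "flexion", ("head", "pelvis")),
    ExerciseSpec("wall angel", "CS and TS", "Shoulder abduction",
                 "abduction", ("upper_arm", "thorax")),
    ExerciseSpec("quadruped neck flexion/extension", "CS", "Neck flexion",
                 "flexion", ("head", "thorax")),
    ExerciseSpec("adductor open book", "CS and TS", "Thorax rotation",
                 "rotation", ("thorax", "pelvis")),
    ExerciseSpec("side plank hip dip", "LS", "Low back abduction",
                 "abduction", ("thorax", "pelvis")),
    ExerciseSpec("bird dog hip spinal flexion", "LS", "Hip flexion",
                 "flexion", ("thigh", "pelvis")),
    ExerciseSpec("windmill single leg", "LS", "Lumbar flexion",
                 "flexion", ("thorax", "pelvis")),
]

EXERCISES: dict[str, ExerciseSpec] = {s.name: s for s in _SPECS}

_ALIASES = {
    "scthlr": "supine chin tuck head lift rotation",
    "dead bug": "dead bug unilateral isometric hold",
    "catcow": "catcow full spine",
    "cat cow full spine": "catcow full spine",
    "quadruped neck flexion extension": "quadruped neck flexion/extension",
    "bird dog": "bird dog hip spinal flexion",
    "windmill": "windmill single leg",
}


def _normalize(name: str) -> str:
    return re.sub(r"[\s_\-]+", " ", name.strip().lower())


def list_exercises() -> list[str]:
    """Registered exercise names, in registry order."""
    return [s.name for s in _SPECS]


def get_spec(name: str) -> ExerciseSpec:
    """Look up an exercise by (case-insensitive) name or alias.

    Raises
    ------
    InvalidArgumentError
        For unknown names, with a nearest-name suggestion when one exists.
    """
    key = _normalize(name)
    key = _ALIASES.get(key, key)
    if key in EXERCISES:
        return EXERCISES[key]
    close = difflib.get_close_matches(key, list(EXERCISES) + list(_ALIASES), n=1)
    hint = f"; did you mean {close[0]!r}?" if close else ""
    raise InvalidArgumentError(f"unknown exercise {name!r}{hint}")


def check_placement(spec: ExerciseSpec, detected: tuple[str, str]) -> PlacementCheck:
    """Check detected IMU sites against an exercise's required pair.

    Order-free set comparison; a mismatch report names the unexpected
    site(s) so the user can be alerted to move that sensor.
    """
    det = tuple(_normalize(d).replace(" ", "_") for d in detected)
    for d in det:
        if d not in LOCATIONS:
            raise InvalidArgumentError(f"unknown IMU site {d!r}")
    expected = set(spec.imu_locations)
    wrong = tuple(sorted(set(det) - expected))
    ok = set(det) == expected
    return PlacementCheck(ok=ok, expected=spec.imu_locations, detected=det,
                          wrong_sites=wrong)


def registry_to_yaml() -> str:
    """Serialize the registry (for user extension / inspection)."""
    return yaml.safe_dump(
        [
            {
                "name": s.name,
                "spine_segment": s.spine_segment,
                "angle_name": s.angle_name,
                "channel": s.channel,
                "imu_locations": list(s.imu_locations),
            }
            for s in _SPECS
        ],
        sort_keys=False,
    )
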