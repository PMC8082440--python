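"""Beam directions on the gantry-couch sphere and candidate-set construction.

Angle convention (IEC 61217): gantry rotates about the patient's
cranio-caudal axis, couch about the vertical axis. ``(gantry 0, couch 0)``
is an anterior beam; the source unit vector points from the isocenter
toward the source. Gantry angles are normalized to [-180, 180), couch
angles lie in [-90, 90].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "BeamDirection",
    "BeamSet",
    "CollisionMask",
    "angular_separation",
    "enumerate_coplanar_candidates",
    "enumerate_noncoplanar_candidates",
    "build_vmat_surrogate",
    "build_bvmat",
    "default_collision_mask",
    "save_beamset",
    "load_beamset",
]


def _normalize_gantry(gantry_deg: float) -> float:
    g = (gantry_deg + 180.0) % 360.0 - 180.0
    return 0.0 if g == 0 else g  # avoid -0.0


@dataclass(frozen=True)
class BeamDirection:
    """A (gantry, couch) angle pair with its derived source unit vector."""

    gantry_deg: float
    couch_deg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gantry_deg", _normalize_gantry(float(self.gantry_deg)))
        couch = float(self.couch_deg)
        if not -90.0 <= couch <= 90.0:
            raise ValueError(f"couch angle {couch} outside [-90, 90]")
        object.__setattr__(self, "couch_deg", 0.0 if couch == 0 else couch)

    @property
    def unit_vector(self) -> np.ndarray:
        """Isocenter-to-source direction in patient coordinates.

        Gantry rotation about z (sup-inf axis), then couch rotation about
        y (vertical / anterior axis): (0, 0) -> (0, 1, 0) anterior,
        (90, 0) -> patient's left, (g, 90) tilts anterior beams toward
        inferior for positive gantry.
        """
        g = math.radians(self.gantry_deg)
        c = math.radians(self.couch_deg)
        x0, y0 = math.sin(g), math.cos(g)
        return np.array([x0 * math.cos(c), y0, -x0 * math.sin(c)])

    @property
    def is_coplanar(self) -> bool:
        return self.couch_deg == 0.0

    def sort_key(self) -> tuple[float, float]:
        return (self.couch_deg, self.gantry_deg)


def angular_separation(a: BeamDirection, b: BeamDirection) -> float:
    """Great-circle angle between two beam axes, degrees in [0, 180].

    Uses atan2(||a x b||, a . b), which stays accurate near 0 and 180
    degrees where arccos of the dot product loses precision.
    """
    va, vb = a.unit_vector, b.unit_vector
    cross = float(np.linalg.norm(np.cross(va, vb)))
    dot = float(np.dot(va, vb))
    return math.degrees(math.atan2(cross, dot))


@dataclass(frozen=True)
class BeamSet:
    """Ordered collection of distinct beam directions.

    If ``min_separation_deg`` is positive, all pairwise great-circle
    separations are at least that angle (validated at construction).
    """

    beams: tuple[BeamDirection, ...]
    min_separation_deg: float = 0.0
    label: str = "selected"

    def __post_init__(self) -> None:
        object.__setattr__(self, "beams", tuple(self.beams))
        if len(set(self.beams)) != len(self.beams):
            raise ValueError("beam set contains duplicate directions")
        if self.min_separation_deg > 0:
            sep = self.pairwise_separations()
            if len(self.beams) > 1 and sep.min() < self.min_separation_deg - 1e-9:
                raise ValueError(
                    f"pairwise separation {sep.min():.3f} deg below "
                    f"{self.min_separation_deg} deg"
                )

    def __len__(self) -> int:
        return len(self.beams)

    def __iter__(self):
        return iter(self.beams)

    def __getitem__(self, i):
        return self.beams[i]

    def pairwise_separations(self) -> np.ndarray:
        """Condensed vector of all pairwise great-circle separations."""
        n = len(self.beams)
        out = []
        for i in range(n):
            for j in range(i + 1, n):
                out.append(angular_separation(self.beams[i], self.beams[j]))
        return np.asarray(out) if out else np.empty(0)

    def subset(self, indices: Iterable[int], label: str = "selected") -> "BeamSet":
        return BeamSet(
            beams=tuple(self.beams[i] for i in indices),
            min_separation_deg=0.0,
            label=label,
        )


@dataclass(frozen=True)
class CollisionMask:
    """Predicate marking deliverable (gantry, couch) directions.

    Couch-0 directions must always be deliverable.
    """

    predicate: Callable[[float, float], bool]

    def __call__(self, gantry_deg: float, couch_deg: float) -> bool:
        if couch_deg == 0:
            return True
        return bool(self.predicate(gantry_deg, couch_deg))


def default_collision_mask() -> CollisionMask:
    """Approximate deliverable region of a C-arm linac.

    Excludes posterior directions at large couch rotations (gantry beyond
    ±100 deg once |couch| > 20 deg), where the gantry would sweep through
    the couch. The exact region is machine-specific; this reproduces its
    shape, not any particular count.
    """

    def predicate(gantry_deg: float, couch_deg: float) -> bool:
        if abs(couch_deg) > 90.0:
            return False
        if abs(couch_deg) > 20.0 and abs(gantry_deg) > 100.0:
            return False
        return True

    return CollisionMask(predicate)


def enumerate_coplanar_candidates(spacing_deg: float = 10.0) -> BeamSet:
    """Equiangular couch-0 candidate ring starting at gantry 0."""
    if spacing_deg <= 0 or abs(360.0 / spacing_deg - round(360.0 / spacing_deg)) > 1e-9:
        raise ValueError(f"spacing {spacing_deg} deg does not divide 360")
    n = int(round(360.0 / spacing_deg))
    beams = [BeamDirection(i * spacing_deg, 0.0) for i in range(n)]
    beams.sort(key=BeamDirection.sort_key)
    return BeamSet(tuple(beams), min_separation_deg=spacing_deg, label="CP_candidates")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (spherical Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    zc = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - zc**2))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), zc])


def _vector_to_angles(v: np.ndarray) -> tuple[float, float] | None:
    """Invert BeamDirection.unit_vector; None for the gantry-0 axis ambiguity."""
    x, y, z = (float(c) for c in v)
    g = math.degrees(math.acos(max(-1.0, min(1.0, y))))
    s = math.hypot(x, z)
    if s < 1e-12:
        return (0.0, 0.0) if y > 0 else (180.0, 0.0)
    c = math.degrees(math.atan2(-z / s, x / s))
    # fold couch into [-90, 90] by flipping the gantry sign
    if c > 90.0:
        c, g = c - 180.0, -g
    elif c < -90.0:
        c, g = c + 180.0, -g
    return (_normalize_gantry(g), c)


def enumerate_noncoplanar_candidates(
    min_separation_deg: float = 10.0,
    mask: CollisionMask | None = None,
    oversample: int = 4,
) -> BeamSet:
    """Quasi-uniform candidate directions over the deliverable sphere.

    The coplanar equiangular ring (spacing equal to ``min_separation_deg``
    rounded to a divisor of 360) is force-included first; a deterministic
    spherical-Fibonacci lattice is then thinned so that every pairwise
    great-circle separation stays >= ``min_separation_deg``.
    """
    if min_separation_deg <= 0:
        raise ValueError("min_separation_deg must be positive")
    if mask is None:
        mask = default_collision_mask()

    ring_spacing = 360.0 / max(1, round(360.0 / min_separation_deg))
    coplanar = list(enumerate_coplanar_candidates(ring_spacing).beams)

    n_lattice = max(64, int(oversample * 41253.0 / min_separation_deg**2))
    lattice = []
    for v in _fibonacci_sphere(n_lattice):
        angles = _vector_to_angles(v)
        if angles is None:
            continue
        g, c = angles
        if mask(g, c):
            lattice.append(BeamDirection(g, c))
    lattice.sort(key=BeamDirection.sort_key)

    accepted: list[BeamDirection] = list(coplanar)
    vecs = [b.unit_vector for b in accepted]
    cos_min = math.cos(math.radians(min_separation_deg))
    for b in lattice:
        v = b.unit_vector
        if vecs and max(float(np.dot(v, w)) for w in vecs) > cos_min - 1e-12:
            continue
        accepted.append(b)
        vecs.append(v)
    if not accepted:
        raise ValueError("deliverable region is empty")
    accepted = sorted(accepted, key=BeamDirection.sort_key)
    return BeamSet(
        tuple(accepted), min_separation_deg=min_separation_deg, label="NCP_candidates"
    )


def build_vmat_surrogate() -> BeamSet:
    """21 coplanar equiangular beams emulating a full-arc delivery."""
    spacing = 360.0 / 21.0
    beams = sorted(
        (BeamDirection(i * spacing, 0.0) for i in range(21)),
        key=BeamDirection.sort_key,
    )
    return BeamSet(tuple(beams), min_separation_deg=0.0, label="VMAT")


def build_bvmat() -> BeamSet:
    """Butterfly class solution: 20 beams in three 60-degree arcs.

    Two couch-0 arcs of seven beams centered at gantry 0 and 180, plus one
    couch-90 arc of six beams centered at gantry 0 with the (0, 90)
    direction excluded (it duplicates the anterior couch-0 beam axis).
    """
    beams: list[BeamDirection] = []
    for g in range(-30, 31, 10):
        beams.append(BeamDirection(g, 0.0))
    for g in range(150, 211, 10):
        beams.append(BeamDirection(g, 0.0))
    for g in range(-30, 31, 10):
        if g != 0:
            beams.append(BeamDirection(g, 90.0))
    beams.sort(key=BeamDirection.sort_key)
    return BeamSet(tuple(beams), min_separation_deg=0.0, label="BVMAT")


def save_beamset(beamset: BeamSet, path) -> None:
    df = pd.DataFrame(
        {
            "label": beamset.label,
            "gantry_deg": [b.gantry_deg for b in beamset],
            "couch_deg": [b.couch_deg for b in beamset],
        }
    )
    df.to_csv(path, index=False)


def load_beamset(path) -> BeamSet:
    df = pd.read_csv(path)
    beams = tuple(
        BeamDirection(g, c) for g, c in zip(df["gantry_deg"], df["couch_deg"])
    )
    label = str(df["label"].iloc[0]) if len(df) else "selected"
    return BeamSet(beams, min_separation_deg=0.0, label=label)
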