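"""Gating observables: percent opening, chi1 rotamer, salt bridge, hydration.

Percent opening normalises a TM1b-TM10 or TM6a-TM10 probe distance
affinely between an inward-facing closed reference (0%) and the maximal
opening (100%); a helix is *open* above 60%, *intermediate* in [50, 60],
*occluded* below 50, and the vestibule counts as open only when both
helices are. The Phe253 chi1 rotamer is classified against the two
crystallographic means (-67° open, -164° occluded) by circular distance,
and the Arg30(Cζ)-Asp404(Cγ) distance against the 4.2 / 6.3 / 9.0 Å
references (direct / water-mediated / none) with midpoint boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, StructureError

OPEN_THRESHOLD = 60.0       # percent; open strictly above
OCCLUDED_THRESHOLD = 50.0   # percent; occluded strictly below
CHI1_OPEN = -67.0           # degrees, OF-open crystal mean
CHI1_OCCLUDED = -164.0      # degrees, OF-occluded crystal mean
#: midpoints between the 4.2 / 6.3 / 9.0 Å salt-bridge reference distances
SALTBRIDGE_THRESHOLDS = (5.25, 7.65)
WATER_SHELL = 3.0           # Å, pocket shell around coordinating residues


@dataclass(frozen=True)
class OpeningReference:
    """0% / 100% probe distances for one helix pair (Å)."""

    d_closed: float
    d_max: float

    def __post_init__(self) -> None:
        if self.d_max == self.d_closed:
            raise ConfigError("degenerate opening reference: d_max == d_closed")
        if self.d_max < self.d_closed:
            raise ConfigError("opening reference requires d_max > d_closed")


def opening_percent(d, ref: OpeningReference):
    """Affine percent opening; not clipped, may leave [0, 100]."""
    return 100.0 * (np.asarray(d, dtype=float) - ref.d_closed) / (ref.d_max - ref.d_closed)


def opening_class(pct: float) -> str:
    """open above 60%, intermediate in [50, 60] (boundaries inclusive), else occluded."""
    if pct > OPEN_THRESHOLD:
        return "open"
    if pct >= OCCLUDED_THRESHOLD:
        return "intermediate"
    return "occluded"


def classify_opening(pct_tm1b: float, pct_tm6a: float) -> tuple[str, str, bool]:
    """Per-helix classes plus the joint flag: the vestibule is completely
    open only when both TM1b and TM6a are open."""
    c1, c6 = opening_class(pct_tm1b), opening_class(pct_tm6a)
    return c1, c6, (c1 == "open" and c6 == "open")


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral about the p1-p2 axis, degrees in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise StructureError("undefined dihedral: collinear atom triple")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    # IUPAC sign convention (matches the standard protein chi/phi/psi usage)
    angle = np.degrees(np.arctan2(-np.dot(m1, n2), np.dot(n1, n2)))
    # map -180 -> +180 so the range is (-180, 180]
    return 180.0 if angle == -180.0 else float(angle)


def circular_distance(a: float, b: float) -> float:
    """Smallest absolute angular separation, degrees in [0, 180]."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def chi1_class(angle: float) -> str:
    """Rotamer class of a chi1 angle: nearer of -67° (open) / -164°
    (occluded) by circular distance; an exact tie is occluded."""
    d_open = circular_distance(angle, CHI1_OPEN)
    d_occ = circular_distance(angle, CHI1_OCCLUDED)
    return "open" if d_open < d_occ else "occluded"


def chi1_state(n, ca, cb, cg) -> tuple[float, str]:
    """Phe chi1 (N-CA-CB-CG) and its rotamer class.

    Class is the nearer of the two crystallographic means by circular
    distance; an exact tie falls to *occluded*, the crystallographic
    starting class.
    """
    angle = dihedral(n, ca, cb, cg)
    return angle, chi1_class(angle)


def saltbridge_state(d: float, thresholds: tuple[float, float] = SALTBRIDGE_THRESHOLDS) -> str:
    """Arg30-Asp404 interaction class from the Cζ-Cγ distance (Å)."""
    if d < 0:
        raise ConfigError("distance must be >= 0")
    lo, hi = thresholds
    if d < lo:
        return "direct"
    if d < hi:
        return "water_mediated"
    return "none"


def pocket_water_count(water_coords, pocket_coords, shell: float = WATER_SHELL) -> int:
    """Water oxygens within *shell* Å of ANY pocket atom; each counted once."""
    pocket = np.atleast_2d(np.asarray(pocket_coords, dtype=float))
    if pocket.size == 0:
        raise ConfigError("empty pocket selection")
    water = np.atleast_2d(np.asarray(water_coords, dtype=float))
    if water.size == 0:
        return 0
    dmin, _ = cKDTree(pocket).query(water, k=1)
    return int((dmin <= shell).sum())


def pocket_water_series(traj, water_selection, pocket_selection,
                        shell: float = WATER_SHELL) -> np.ndarray:
    """Per-frame pocket water counts for a trajectory (real mode)."""
    water_ids = water_selection.resolve(traj.topology)
    pocket_ids = pocket_selection.resolve(traj.topology)
    if len(pocket_ids) == 0:
        raise ConfigError("empty pocket selection")
    return np.array([
        pocket_water_count(traj.frames[k, water_ids, :], traj.frames[k, pocket_ids, :], shell)
        for k in range(traj.n_frames)
    ])


def _upward_crossings(values: np.ndarray, threshold: float) -> np.ndarray:
    """Frame indices where the series first meets the threshold from below."""
    above = np.asarray(values) >= threshold
    return np.flatnonzero(above[1:] & ~above[:-1]) + 1


def hydration_opening_curve(
    water: np.ndarray,
    opening_tm1b: np.ndarray,
    opening_tm6a: np.ndarray,
    frame_interval: float,
    water_threshold: float = 25.0,
    opening_threshold: float = OPEN_THRESHOLD,
):
    """Paired hydration/opening series and water-vs-opening crossing lags.

    For each vestibule-opening event (the joint opening, min of the two
    helices, crossing the 60% threshold upward), the signed lag is
    t(opening crossing) - t(associated water crossing); positive means
    water rose first. The associated water crossing is the one nearest in
    time, so a simultaneous crossing reports lag 0 rather than being
    dropped. Returns ``(table, lags_ns)``.
    """
    import pandas as pd

    water = np.asarray(water, dtype=float)
    o1 = np.asarray(opening_tm1b, dtype=float)
    o6 = np.asarray(opening_tm6a, dtype=float)
    if not (len(water) == len(o1) == len(o6)):
        raise StructureError("hydration and opening series lengths differ")
    times = np.arange(len(water)) * frame_interval
    table = pd.DataFrame({
        "time_ns": times,
        "water_count": water,
        "opening_pct_TM1b": o1,
        "opening_pct_TM6a": o6,
    })
    joint = np.minimum(o1, o6)
    open_times = times[_upward_crossings(joint, opening_threshold)]
    water_times = times[_upward_crossings(water, water_threshold)]
    lags = []
    for to in open_times:
        if len(water_times) == 0:
            continue
        tw = water_times[np.argmin(np.abs(water_times - to))]
        lags.append(to - tw)
    return table, np.asarray(lags)
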