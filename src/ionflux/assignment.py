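"""Per-frame site assignment and dwell-filtered episode extraction.

Each ion/substrate position is classified into one of the declared binding
sites (coordination criterion: at least ``min_coordination`` coordinating
atoms within ``cutoff`` Å), the extracellular vestibule (by z-interval), or
bulk. When several sites' criteria are met, the site with the smallest mean
coordinating distance wins; means equal within 1e-6 Å fall back to
configuration order. Episodes are maximal runs of one site label; following
the reporting convention for binding instances, only episodes lasting at
least 50 ns are kept by default (shorter blips are dropped, never bridged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import Selection, Trajectory
from .errors import ConfigError, EmptyInputError
from .mechanism import SITES, NON_SITES, SiteGeometry

#: minimum episode duration reported as a binding instance, ns
MIN_DWELL_NS = 50.0

#: mean-distance margin inside which candidate sites count as tied, Å
TIE_TOLERANCE = 1e-6


@dataclass
class SiteDefinition:
    """A named site given by its coordinating atoms and a distance criterion."""

    name: str
    coordinating_atoms: Selection
    min_coordination: int = 2
    cutoff: float = 3.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigError(f"site {self.name}: cutoff must be > 0")
        if self.min_coordination < 1:
            raise ConfigError(f"site {self.name}: min_coordination must be >= 1")


@dataclass
class ResolvedSite:
    """A site with concrete coordinating coordinates.

    ``coords`` has shape (m, 3) for static coordinates (synthetic-mode site
    centres) or (n_frames, m, 3) when the coordinating atoms move with the
    trajectory (real mode).
    """

    name: str
    coords: np.ndarray
    min_coordination: int
    cutoff: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape[-1] != 3 or self.coords.shape[-2] < self.min_coordination:
            raise ConfigError(
                f"site {self.name}: needs >= {self.min_coordination} coordinating atoms"
            )


def sites_from_geometry(geometry: SiteGeometry, cutoff: float = 3.0,
                        order: list[str] | None = None) -> list[ResolvedSite]:
    """Synthetic-mode sites: one pseudo-atom at each site centre."""
    names = order or [s for s in SITES if s in geometry.centers]
    return [
        ResolvedSite(name=n, coords=geometry.centers[n][None, :],
                     min_coordination=1, cutoff=cutoff)
        for n in names if n in geometry.centers
    ]


def resolve_sites(traj: Trajectory, definitions: list[SiteDefinition]) -> list[ResolvedSite]:
    """Real-mode sites: coordinating coordinates taken per frame."""
    out = []
    for d in definitions:
        ids = d.coordinating_atoms.resolve(traj.topology)
        if len(ids) == 0:
            raise ConfigError(
                f"site {d.name}: selection {d.coordinating_atoms.expression!r} "
                "resolves to no atoms"
            )
        out.append(ResolvedSite(name=d.name, coords=traj.frames[:, ids, :],
                                min_coordination=d.min_coordination, cutoff=d.cutoff))
    return out


@dataclass
class LabelSeries:
    """Per-frame site labels for one particle."""

    particle: str
    labels: np.ndarray  # object array over SITES + {vestibule, bulk}
    frame_interval: float  # ns

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) == 0:
            raise EmptyInputError("label series is empty")

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class Episode:
    """One contiguous residency of one particle at one site."""

    particle: str
    site: str
    t_start: float  # ns
    t_end: float    # ns, exclusive

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ConfigError("episode must have t_end > t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def assign_frame(position, sites: list[ResolvedSite],
                 vestibule_axis: tuple[float, float], bulk_z_min: float) -> str:
    """Classify a single position (Å); reference implementation of the rule.

    Sites whose coordination criterion is met compete by mean coordinating
    distance; otherwise the z-interval decides vestibule vs bulk.
    """
    position = np.asarray(position, dtype=np.float64)
    best_name = None
    best_mean = np.inf
    for site in sites:
        coords = site.coords
        if coords.ndim == 3:
            raise ConfigError("assign_frame needs static site coordinates; "
                              "use assign_trajectory for per-frame sites")
        d = np.linalg.norm(coords - position, axis=1)
        if (d <= site.cutoff).sum() >= site.min_coordination:
            mean = float(d.mean())
            if mean < best_mean - TIE_TOLERANCE:
                best_name, best_mean = site.name, mean
            # ties (within tolerance) keep the earlier site in config order
    if best_name is not None:
        return best_name
    z = position[2]
    if vestibule_axis[0] <= z < vestibule_axis[1]:
        return "vestibule"
    return "bulk"


def assign_trajectory(
    traj: Trajectory,
    particles: dict[str, Selection | int],
    sites: list[ResolvedSite],
    vestibule_axis: tuple[float, float],
    bulk_z_min: float,
) -> list[LabelSeries]:
    """Vectorised per-frame assignment for each particle.

    ``particles`` maps a particle label to either an atom index or a
    Selection resolving to the atoms whose centroid is tracked.
    """
    if traj.n_frames == 0:
        raise EmptyInputError("empty trajectory")
    out = []
    for label, sel in particles.items():
        if isinstance(sel, (int, np.integer)):
            pos = traj.frames[:, int(sel), :]
        else:
            pos = traj.positions(sel)
        out.append(LabelSeries(
            particle=label,
            labels=_assign_positions(pos, sites, vestibule_axis, bulk_z_min),
            frame_interval=traj.frame_interval,
        ))
    return out


def _assign_positions(pos: np.ndarray, sites: list[ResolvedSite],
                      vestibule_axis: tuple[float, float], bulk_z_min: float) -> np.ndarray:
    n = pos.shape[0]
    n_sites = len(sites)
    mean_d = np.full((n_sites, n), np.inf)
    for i, site in enumerate(sites):
        coords = site.coords if site.coords.ndim == 3 else site.coords[None, :, :]
        d = np.linalg.norm(coords - pos[:, None, :], axis=2)  # (n, m)
        met = (d <= site.cutoff).sum(axis=1) >= site.min_coordination
        md = d.mean(axis=1)
        mean_d[i, met] = md[met]
    labels = np.empty(n, dtype=object)
    any_met = np.isfinite(mean_d).any(axis=0)
    if n_sites and any_met.any():
        best = mean_d.min(axis=0)
        # first site (config order) within the tie tolerance of the best mean
        chosen = np.argmax(mean_d <= best[None, :] + TIE_TOLERANCE, axis=0)
        site_names = np.array([s.name for s in sites], dtype=object)
        labels[any_met] = site_names[chosen[any_met]]
    unmet = ~any_met
    z = pos[:, 2]
    in_vest = (z >= vestibule_axis[0]) & (z < vestibule_axis[1])
    labels[unmet & in_vest] = "vestibule"
    labels[unmet & ~in_vest] = "bulk"
    return labels


def occupancy_fractions(series: LabelSeries,
                        site_set: list[str] | None = None) -> dict[str, float]:
    """Fraction of frames carrying each label, over the full label alphabet."""
    alphabet = list(site_set) if site_set is not None else list(SITES)
    for extra in NON_SITES:
        if extra not in alphabet:
            alphabet.append(extra)
    n = series.n_frames
    return {label: float((series.labels == label).sum()) / n for label in alphabet}


def extract_episodes(series: LabelSeries, min_dwell: float = MIN_DWELL_NS,
                     site_set: tuple[str, ...] | None = None) -> list[Episode]:
    """Maximal same-site label runs lasting at least *min_dwell* ns.

    Vestibule/bulk residencies are not episodes. Sub-threshold runs are
    discarded outright (not merged into neighbours).
    """
    if 0.0 < min_dwell < series.frame_interval:
        warnings.warn(
            f"min_dwell {min_dwell} ns is below the frame interval "
            f"{series.frame_interval} ns; the filter is a no-op",
            stacklevel=2,
        )
    keep = set(site_set) if site_set is not None else set(SITES)
    dt = series.frame_interval
    labels = series.labels
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    episodes = []
    for i0, i1 in zip(starts, ends):
        site = labels[i0]
        if site not in keep:
            continue
        duration = (i1 - i0) * dt
        if duration >= min_dwell:
            episodes.append(Episode(particle=series.particle, site=site,
                                    t_start=i0 * dt, t_end=i1 * dt))
    return episodes


def site_sequence(episodes: list[Episode]) -> list[str]:
    """The ordered site-visit sequence implied by an episode list."""
    return [e.site for e in sorted(episodes, key=lambda e: e.t_start)]
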