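"""Continuous-time Markov simulation of the sodium/substrate binding mechanism.

The transporter's binding kinetics are modelled as a CTMC over *ligation
states*: joint assignments of particles (two sodium ions and one substrate)
to the binding sites Na1, Na1' (``Na1p``), Na1'' (``Na1pp``), Na2 and S1, or
to the extracellular vestibule or bulk. Timelines are generated by exact
stochastic simulation (Gillespie): dwell times are exponential with the
state's total exit rate, successors are chosen proportionally to rates.

A timeline can then be rendered into 3-D coordinates (site-centred Gaussian
jitter, a reflected random walk along z in the vestibule, diffuse bulk
placement) and into coupled gating observables (percent opening of
TM1b/TM6a, Phe253 chi1, Arg30-Asp404 salt-bridge distance, pocket water
count) whose threshold crossings are ordered by construction: water influx
precedes vestibule opening, and before a substrate release the TM helices
open, then the salt bridge breaks, then chi1 switches to the open rotamer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import DEFAULT_FRAME_INTERVAL, Topology, Trajectory
from .errors import ConfigError, EmptyInputError

#: canonical site labels; primes are spelled ``p`` (Na1p = Na1', Na1pp = Na1'')
SITES = ("Na1", "Na1p", "Na1pp", "Na2", "S1")
NON_SITES = ("vestibule", "bulk")
LOCATIONS = SITES + NON_SITES

#: pretty-print map for reports
DISPLAY = {"Na1p": "Na1′", "Na1pp": "Na1″"}


def display_name(site: str) -> str:
    return DISPLAY.get(site, site)


@dataclass(frozen=True)
class LigationState:
    """One joint placement of all particles; at most one particle per site."""

    placements: tuple[tuple[str, str], ...]  # ((particle, location), ...) sorted

    def __post_init__(self) -> None:
        seen_sites: set[str] = set()
        for particle, loc in self.placements:
            if loc not in LOCATIONS:
                raise ConfigError(f"unknown location {loc!r} for particle {particle!r}")
            if loc in SITES:
                if loc in seen_sites:
                    raise ConfigError(f"site {loc!r} claimed by two particles")
                seen_sites.add(loc)

    @classmethod
    def from_dict(cls, placements: dict[str, str]) -> "LigationState":
        return cls(tuple(sorted(placements.items())))

    def location(self, particle: str) -> str:
        for p, loc in self.placements:
            if p == particle:
                return loc
        raise KeyError(particle)

    @property
    def occupancy(self) -> dict[str, str]:
        """Map site -> particle for occupied sites only."""
        return {loc: p for p, loc in self.placements if loc in SITES}

    @property
    def particles(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.placements)


@dataclass
class MechanismConfig:
    """States, transition rates (μs⁻¹) and the initial state of the mechanism."""

    species: tuple[str, ...]
    states: dict[str, LigationState]
    rates: dict[tuple[str, str], float]  # (from, to) -> μs⁻¹
    initial: str

    def __post_init__(self) -> None:
        if self.initial not in self.states:
            raise ConfigError(f"initial state {self.initial!r} not declared")
        for (a, b), k in self.rates.items():
            if a not in self.states or b not in self.states:
                raise ConfigError(f"rate references undeclared state: {(a, b)}")
            if a == b:
                raise ConfigError(f"self-transition {a!r}")
            if k < 0:
                raise ConfigError(f"negative rate for {(a, b)}")
        for name, st in self.states.items():
            if set(st.particles) != set(self.species):
                raise ConfigError(f"state {name!r} does not place every species")
        self._check_connected()

    def _check_connected(self) -> None:
        # weak connectivity of the positive-rate graph
        adj: dict[str, set[str]] = {s: set() for s in self.states}
        for (a, b), k in self.rates.items():
            if k > 0:
                adj[a].add(b)
                adj[b].add(a)
        seen = {self.initial}
        stack = [self.initial]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        isolated = set(self.states) - seen
        if isolated and any(self.rates.values()):
            raise ConfigError(f"states unreachable from {self.initial!r}: {sorted(isolated)}")

    def exits(self, state: str) -> list[tuple[str, float]]:
        return [(b, k) for (a, b), k in self.rates.items() if a == state and k > 0]


@dataclass
class StateTimeline:
    """Piecewise-constant ligation-state path; times in ns."""

    events: list[tuple[float, str]]  # (time_ns, state name), first at t=0
    states: dict[str, LigationState]
    total_duration: float  # ns

    def __post_init__(self) -> None:
        if not self.events:
            raise EmptyInputError("timeline has no events")
        times = [t for t, _ in self.events]
        if times[0] != 0.0:
            raise ConfigError("first timeline event must be at t=0")
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ConfigError("timeline event times must be strictly increasing")

    @property
    def n_transitions(self) -> int:
        return len(self.events) - 1

    def dwells(self) -> list[tuple[str, float, bool]]:
        """(state, duration_ns, completed) per visit; the final dwell is censored."""
        out = []
        for (t0, s), (t1, _) in zip(self.events, self.events[1:]):
            out.append((s, t1 - t0, True))
        t_last, s_last = self.events[-1]
        out.append((s_last, self.total_duration - t_last, False))
        return out

    def n_frames(self, frame_interval: float) -> int:
        return int(np.floor(self.total_duration / frame_interval - 1e-9)) + 1

    def state_names_per_frame(self, frame_interval: float) -> np.ndarray:
        """Quantize to the frame grid t_k = k*interval (object array of names)."""
        times = np.array([t for t, _ in self.events])
        names = np.array([s for _, s in self.events], dtype=object)
        tk = np.arange(self.n_frames(frame_interval)) * frame_interval
        idx = np.searchsorted(times, tk, side="right") - 1
        return names[idx]

    def particle_locations(self, particle: str, frame_interval: float) -> np.ndarray:
        """Per-frame ground-truth location labels for one particle."""
        lut = {name: st.location(particle) for name, st in self.states.items()}
        per_frame = self.state_names_per_frame(frame_interval)
        return np.array([lut[n] for n in per_frame], dtype=object)


def simulate_mechanism(config: MechanismConfig, duration: float, seed: int) -> StateTimeline:
    """Exact stochastic simulation of the mechanism for *duration* ns.

    Rates are μs⁻¹; internal times are ns. Identical (config, seed) gives
    an identical timeline. An absorbing state truncates the path with a
    warning (the timeline still reports the full requested duration).
    """
    if duration <= 0:
        raise ConfigError("duration must be > 0")
    rng = np.random.default_rng(seed)
    exits = {s: config.exits(s) for s in config.states}
    t = 0.0
    state = config.initial
    events = [(0.0, state)]
    while True:
        out = exits[state]
        total = sum(k for _, k in out)
        if total == 0.0:
            if t < duration:
                warnings.warn(
                    f"absorbing state {state!r} entered at {t:.3f} ns with "
                    f"{duration - t:.3f} ns remaining; timeline truncated",
                    stacklevel=2,
                )
            break
        # rates are μs⁻¹ -> dwell in ns
        t += rng.exponential(1.0 / total) * 1e3
        if t >= duration:
            break
        r = rng.random() * total
        acc = 0.0
        for nxt, k in out:
            acc += k
            if r < acc:
                state = nxt
                break
        events.append((t, state))
    return StateTimeline(events=events, states=dict(config.states), total_duration=duration)


# ---------------------------------------------------------------------------
# coordinate rendering


@dataclass
class SiteGeometry:
    """Site centres and vestibule/bulk conventions for rendering (Å).

    S1 sits at the origin by the z-convention; Na1'' must lie 5-6 Å from
    both Na1 and Na2, matching its position in the transport core.
    """

    centers: dict[str, np.ndarray]
    vestibule_axis: tuple[float, float]  # z-interval, Å
    bulk_z_min: float
    jitter_sd: float = 0.3
    walk_step_sd: float = 0.8     # per-frame z step of the vestibule walk, Å
    lateral_sd: float = 1.5       # x/y spread in the vestibule, Å

    def __post_init__(self) -> None:
        self.centers = {k: np.asarray(v, dtype=np.float64) for k, v in self.centers.items()}
        names = list(self.centers)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                d = np.linalg.norm(self.centers[a] - self.centers[b])
                if d < 3.0:
                    raise ConfigError(f"site centres {a}/{b} closer than 3 Å ({d:.2f})")
        if "Na1pp" in self.centers:
            for other in ("Na1", "Na2"):
                if other in self.centers:
                    d = np.linalg.norm(self.centers["Na1pp"] - self.centers[other])
                    if not (5.0 <= d <= 6.0):
                        raise ConfigError(
                            f"Na1'' centre must be 5-6 Å from {other} (got {d:.2f})"
                        )
        lo, hi = self.vestibule_axis
        if not lo < hi:
            raise ConfigError("vestibule_axis must be an increasing z-interval")
        if self.bulk_z_min < hi:
            raise ConfigError("bulk_z_min must lie beyond the vestibule")
        if self.jitter_sd <= 0:
            raise ConfigError("jitter_sd must be > 0")


_PARTICLE_ATOMS = {  # particle -> (atom_name, residue_name)
    "Na_a": ("NA", "SOD"),
    "Na_b": ("NA", "SOD"),
    "substrate": ("CA", "LEU"),
}


def _particle_atom(particle: str) -> tuple[str, str]:
    return _PARTICLE_ATOMS.get(particle, ("X", "UNK"))


def _render_segments(loc: np.ndarray, geometry: SiteGeometry, rng: np.random.Generator) -> np.ndarray:
    """Positions (n_frames, 3) for one particle's per-frame location labels."""
    n = len(loc)
    pos = np.empty((n, 3))
    z_lo, z_hi = geometry.vestibule_axis
    width = z_hi - z_lo
    # site frames: centre + isotropic jitter
    for site, centre in geometry.centers.items():
        mask = loc == site
        m = int(mask.sum())
        if m:
            pos[mask] = centre + rng.normal(0.0, geometry.jitter_sd, size=(m, 3))
    # vestibule frames: reflected 1-D walk in z per contiguous segment + lateral jitter
    vest = loc == "vestibule"
    if vest.any():
        idx = np.flatnonzero(vest)
        pos[vest, 0] = rng.normal(0.0, geometry.lateral_sd, size=len(idx))
        pos[vest, 1] = rng.normal(0.0, geometry.lateral_sd, size=len(idx))
        breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        for seg in np.split(idx, breaks):
            steps = rng.normal(0.0, geometry.walk_step_sd, size=len(seg))
            steps[0] = 0.0
            w = 0.5 * (z_lo + z_hi) + np.cumsum(steps)
            # fold the unbounded walk into [z_lo, z_hi] (triangle-wave reflection)
            phase = np.mod(w - z_lo, 2.0 * width)
            pos[seg, 2] = z_lo + np.where(phase <= width, phase, 2.0 * width - phase)
    # bulk frames: diffuse placement beyond bulk_z_min
    bulk = loc == "bulk"
    if bulk.any():
        m = int(bulk.sum())
        pos[bulk, 0] = rng.normal(0.0, 5.0, size=m)
        pos[bulk, 1] = rng.normal(0.0, 5.0, size=m)
        pos[bulk, 2] = geometry.bulk_z_min + np.abs(rng.normal(0.0, 3.0, size=m)) + 0.5
    return pos


def embed_timeline(
    timeline: StateTimeline,
    geometry: SiteGeometry,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    seed: int = 0,
    chain_id: str = "A",
) -> Trajectory:
    """Render a timeline as a pseudo-atom trajectory (one atom per particle).

    While a particle occupies a site its position is the site centre plus
    isotropic Gaussian jitter; in the vestibule it random-walks along z
    within ``vestibule_axis``; in the bulk it is placed beyond
    ``bulk_z_min``. Frames are emitted at the fixed sampling interval.
    """
    if frame_interval <= 0:
        raise ConfigError("frame_interval must be > 0")
    short = [
        (s, d) for s, d, done in timeline.dwells() if done and d < frame_interval
    ]
    if short:
        warnings.warn(
            f"{len(short)} dwell(s) shorter than the frame interval "
            f"({frame_interval} ns) are invisible at this sampling: "
            f"{short[:5]}{'...' if len(short) > 5 else ''}",
            stacklevel=2,
        )
    particles = sorted({p for st in timeline.states.values() for p in st.particles})
    rng = np.random.default_rng(seed)
    topo = Topology.from_records(
        [(_particle_atom(p)[0], _particle_atom(p)[1], i + 1, chain_id)
         for i, p in enumerate(particles)]
    )
    n = timeline.n_frames(frame_interval)
    frames = np.empty((n, len(particles), 3))
    for j, particle in enumerate(particles):
        loc = timeline.particle_locations(particle, frame_interval)
        frames[:, j, :] = _render_segments(loc, geometry, rng)
    return Trajectory(topology=topo, frames=frames, frame_interval=frame_interval,
                      z_convention=True)


def particle_index(timeline: StateTimeline) -> dict[str, int]:
    """Atom index of each particle in the trajectory built by embed_timeline."""
    particles = sorted({p for st in timeline.states.values() for p in st.particles})
    return {p: i for i, p in enumerate(particles)}


# ---------------------------------------------------------------------------
# gating observables


@dataclass
class GatingCoupling:
    """Lags (ns) and levels wiring mechanism events to gating observables.

    All lags must be positive; they encode the constructed event ordering:
    water precedes TM opening by ``water_lead``; before a substrate release
    the TM helices cross 60% open ``tm_lead + sb_lead + chi1_lead`` ns
    early, the salt bridge passes the water-mediated threshold
    ``sb_lead + chi1_lead`` ns early, and chi1 switches ``chi1_lead`` ns
    early.
    """

    water_lead: float = 15.0
    tm_lead: float = 20.0
    sb_lead: float = 15.0
    chi1_lead: float = 10.0
    open_lag: float = 25.0        # binding -> opening-crossing delay
    close_lag: float = 50.0       # substrate binding -> closure delay
    ramp_width: float = 2.0       # ns, linear crossing width
    opening_occluded: float = 40.0
    opening_open: float = 80.0
    opening_threshold: float = 60.0
    water_low: float = 17.0
    water_high: float = 33.0
    water_threshold: float = 25.0
    sb_direct: float = 4.2        # Å, crystallographic direct salt bridge
    sb_none: float = 9.0          # Å, broken
    sb_threshold: float = 7.65
    chi1_occluded: float = -164.0
    chi1_open: float = -67.0
    chi1_boundary: float = -115.5
    noise_opening: float = 1.5
    noise_water: float = 1.0
    noise_sb: float = 0.1
    noise_chi1: float = 3.0

    def __post_init__(self) -> None:
        for name in ("water_lead", "tm_lead", "sb_lead", "chi1_lead",
                     "open_lag", "close_lag", "ramp_width"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"coupling lag {name} must be > 0")


@dataclass
class GatingSeries:
    """Per-frame gating observables aligned with a rendered trajectory."""

    opening_tm1b: np.ndarray   # percent
    opening_tm6a: np.ndarray   # percent
    chi1: np.ndarray           # degrees in (-180, 180]
    saltbridge: np.ndarray     # Å
    water: np.ndarray          # integer count
    frame_interval: float      # ns

    def __post_init__(self) -> None:
        n = len(self.opening_tm1b)
        for arr in (self.opening_tm6a, self.chi1, self.saltbridge, self.water):
            if len(arr) != n:
                raise ConfigError("gating series lengths differ")
        if (self.water < 0).any():
            raise ConfigError("water_count must be >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.opening_tm1b)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def _apply_ramps(values: np.ndarray, times: np.ndarray,
                 specs: list[tuple[float, float, float, float, float]]) -> None:
    """Apply linear threshold-crossing ramps in chronological order.

    Each spec is (t_cross, lo, hi, width, threshold): a linear lo->hi ramp
    whose *threshold* crossing sits exactly at *t_cross*, holding *hi*
    afterwards until the next ramp takes over. Writing is windowed to the
    next ramp's start so the cost is O(n + events).
    """
    if not specs:
        return
    starts = [t - w * (th - lo) / (hi - lo)
              for t, lo, hi, w, th in specs]
    order = np.argsort(starts, kind="stable")
    for pos, j in enumerate(order):
        t_cross, lo, hi, width, threshold = specs[j]
        t0 = starts[j]
        i0 = int(np.searchsorted(times, t0))
        i1 = len(times)
        if pos + 1 < len(order):
            i1 = int(np.searchsorted(times, starts[order[pos + 1]]))
        if i1 <= i0:
            continue
        frac = np.clip((times[i0:i1] - t0) / width, 0.0, 1.0)
        values[i0:i1] = lo + (hi - lo) * frac


def _transition_times(timeline: StateTimeline, particle: str,
                      src: str, dst: str) -> list[float]:
    """Times of transitions moving *particle* from location *src* to *dst*."""
    out = []
    for (t0, a), (t1, b) in zip(timeline.events, timeline.events[1:]):
        la = timeline.states[a].location(particle)
        lb = timeline.states[b].location(particle)
        if la == src and lb == dst:
            out.append(t1)
    return out


def generate_gating_series(
    timeline: StateTimeline,
    coupling: GatingCoupling | None = None,
    seed: int = 0,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> GatingSeries:
    """Construct gating observables consistent with the mechanism's ordering.

    With no events the series stay flat at the occluded baselines
    (opening < 50%, chi1 near -164°, salt-bridge near the 4.2 Å direct
    value). Around each sodium binding to Na1'' the water count crosses its
    threshold before the opening percentage crosses 60%; around each
    substrate release the TM opening crossing precedes the salt-bridge
    crossing, which precedes the chi1 switch, which precedes the release.
    """
    c = coupling or GatingCoupling()
    rng = np.random.default_rng(seed)
    n = timeline.n_frames(frame_interval)
    times = np.arange(n) * frame_interval

    opening = np.full(n, c.opening_occluded)
    water = np.full(n, c.water_low)
    sb = np.full(n, c.sb_direct)
    chi1 = np.full(n, c.chi1_occluded)

    na_particles = [p for p in timeline.states[timeline.events[0][1]].particles
                    if p != "substrate"]
    directives: list[tuple[float, str, bool]] = []  # (crossing time, observable set, opening?)
    for p in na_particles:
        for t in _transition_times(timeline, p, "vestibule", "Na1pp"):
            directives.append((t + c.open_lag, "open", True))
    has_sub = "substrate" in timeline.states[timeline.events[0][1]].particles
    if has_sub:
        for t in _transition_times(timeline, "substrate", "vestibule", "S1"):
            directives.append((t + c.close_lag, "close", False))
        for t in _transition_times(timeline, "substrate", "S1", "vestibule"):
            directives.append((t, "release", True))

    # A vestibule open/closed state machine converts mechanism events into
    # observable edges: only the first sodium binding of a closed period
    # opens, substrate binding closes (after close_lag), and a substrate
    # release fires the full cascade. Rapid rebinding attempts while the
    # vestibule is already open therefore emit nothing, which keeps ramps
    # from colliding at sub-resolution spacing.
    edges: dict[str, list[tuple[float, bool]]] = {
        "water": [], "opening": [], "sb": [], "chi1": [],
    }
    min_gap = max(2.0 * c.ramp_width, 4.0 * frame_interval)
    cascade_span = c.tm_lead + c.sb_lead + c.chi1_lead + c.water_lead
    ordered = sorted(directives)
    # an occluded period too short to resolve (its close directive would
    # collide with the next release's back-dated cascade) is rendered as a
    # continuously open vestibule: both the close and that release are
    # skipped in pairs
    skipped: set[int] = set()
    for i, (t_evt, kind, _) in enumerate(ordered):
        if kind != "close":
            continue
        for j in range(i + 1, len(ordered)):
            if ordered[j][1] == "release":
                if ordered[j][0] - cascade_span < t_evt + min_gap:
                    skipped.update((i, j))
                break
    is_open = False
    for i, (t_evt, kind, _) in enumerate(ordered):
        if i in skipped:
            continue
        if kind == "open" and not is_open:
            edges["water"].append((t_evt - c.water_lead, True))
            edges["opening"].append((t_evt, True))
            is_open = True
        elif kind == "close" and is_open:
            edges["opening"].append((t_evt, False))
            edges["water"].append((t_evt + c.water_lead, False))
            edges["sb"].append((t_evt + 1.0, False))
            edges["chi1"].append((t_evt + 2.0, False))
            is_open = False
        elif kind == "release":
            # cascade: TM opening, then salt-bridge break, then chi1
            # switch, each strictly before the release time
            t_open = t_evt - c.tm_lead - c.sb_lead - c.chi1_lead
            edges["water"].append((t_open - c.water_lead, True))
            edges["opening"].append((t_open, True))
            edges["sb"].append((t_evt - c.sb_lead - c.chi1_lead, True))
            edges["chi1"].append((t_evt - c.chi1_lead, True))
            is_open = True

    def _drop_blips(pairs: list[tuple[float, bool]], min_gap: float):
        # edges closer together than the resolvable gap cancel in pairs
        out: list[tuple[float, bool]] = []
        for e in pairs:
            if out and e[0] - out[-1][0] < min_gap and out[-1][1] != e[1]:
                out.pop()
            else:
                out.append(e)
        return out

    levels = {
        "water": (c.water_low, c.water_high, c.water_threshold),
        "opening": (c.opening_occluded, c.opening_open, c.opening_threshold),
        "sb": (c.sb_direct, c.sb_none, c.sb_threshold),
        "chi1": (c.chi1_occluded, c.chi1_open, c.chi1_boundary),
    }
    arrays = {"water": water, "opening": opening, "sb": sb, "chi1": chi1}
    for key, pairs in edges.items():
        lo, hi, threshold = levels[key]
        specs = [
            (t, lo, hi, c.ramp_width, threshold) if rising
            else (t, hi, lo, c.ramp_width, threshold)
            for t, rising in _drop_blips(sorted(pairs), min_gap)
        ]
        _apply_ramps(arrays[key], times, specs)

    opening_1b = opening + rng.normal(0.0, c.noise_opening, size=n)
    opening_6a = opening + rng.normal(0.0, c.noise_opening, size=n)
    chi1_noisy = chi1 + rng.normal(0.0, c.noise_chi1, size=n)
    chi1_noisy = np.mod(chi1_noisy + 180.0, 360.0) - 180.0
    sb_noisy = np.clip(sb + rng.normal(0.0, c.noise_sb, size=n), 0.0, None)
    water_noisy = np.clip(np.rint(water + rng.normal(0.0, c.noise_water, size=n)), 0, None)
    return GatingSeries(
        opening_tm1b=opening_1b,
        opening_tm6a=opening_6a,
        chi1=chi1_noisy,
        saltbridge=sb_noisy,
        water=water_noisy.astype(np.int64),
        frame_interval=frame_interval,
    )
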