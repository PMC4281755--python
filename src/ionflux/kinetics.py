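"""First-passage kinetics, ligation transitions and CTMC rate estimation.

Rate constants are reported as reciprocals of mean first-passage times
(k = 1/MFPT): binding is clocked from vestibule entry to the first Na1''
residency, unbinding from the start of a Na1'' residency to the first
departure back to vestibule/bulk. Incomplete (censored) passages at the
end of a series are excluded from the mean but always counted. The "±"
spread is reported both as the sample SD and as the standard error; display
values are rounded to 2 significant figures, full precision is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assignment import Episode, LabelSeries
from .errors import ConfigError, EmptyInputError, InconsistencyError, StructureError
from .mechanism import SITES, StateTimeline

NA_SITES = ("Na1", "Na1p", "Na1pp", "Na2")

NS_PER_US = 1e3


@dataclass(frozen=True)
class KineticEstimate:
    """A rate constant with the first-passage statistics behind it."""

    rate: float       # μs⁻¹
    mfpt_mean: float  # μs
    mfpt_sd: float    # μs (sample SD, ddof=1; 0 for n=1)
    mfpt_se: float    # μs
    n: int
    censored: int = 0

    def display(self) -> str:
        return f"{self.rate:.2g}"


def _change_points(series_or_timeline, particle: str | None):
    """Common event view: (times_ns, labels, end_time_ns).

    For a LabelSeries the change points are frame times; for a
    StateTimeline they are the exact event times of one particle's
    location.
    """
    if isinstance(series_or_timeline, LabelSeries):
        s = series_or_timeline
        labels = s.labels
        change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        idx = np.concatenate(([0], change))
        return idx * s.frame_interval, labels[idx], s.n_frames * s.frame_interval
    if isinstance(series_or_timeline, StateTimeline):
        tl = series_or_timeline
        if particle is None:
            if len({p for st in tl.states.values() for p in st.particles}) > 1:
                raise ConfigError("particle must be named for a multi-particle timeline")
            particle = next(iter(tl.states[tl.events[0][1]].particles))
        times, locs = [], []
        for t, name in tl.events:
            loc = tl.states[name].location(particle)
            if not locs or loc != locs[-1]:
                times.append(t)
                locs.append(loc)
        return np.asarray(times), np.asarray(locs, dtype=object), tl.total_duration
    raise ConfigError("expected a LabelSeries or StateTimeline")


def _as_predicate(cond):
    if callable(cond):
        return cond
    if isinstance(cond, str):
        return lambda lab: lab == cond
    members = set(cond)
    return lambda lab: lab in members


def first_passage_times(series, source, target,
                        particle: str | None = None) -> tuple[np.ndarray, int]:
    """Completed passage durations (μs) from each *source* entry to the
    first subsequent *target*, plus the censored count.

    The clock starts when the label first satisfies *source* (an entry:
    the previous label did not) and stops at the first label satisfying
    *target*; passages do not overlap. A passage still running at the end
    of the series is censored. Conditions may be a label, a set of labels,
    or a predicate.
    """
    src = _as_predicate(source)
    tgt = _as_predicate(target)
    times, labels, t_end = _change_points(series, particle)
    durations = []
    censored = 0
    clock: float | None = None
    prev_src = False
    for t, lab in zip(times, labels):
        is_src = bool(src(lab))
        if clock is not None and tgt(lab):
            durations.append(t - clock)
            clock = None
            prev_src = is_src
            continue
        if clock is None and is_src and not prev_src:
            clock = t
        prev_src = is_src
    if clock is not None and t_end > clock:
        censored = 1
    return np.asarray(durations) / NS_PER_US, censored


def rate_from_mfpt(times_us, censored: int = 0) -> KineticEstimate:
    """Reciprocal-MFPT rate with sample SD/SE of the passage times."""
    t = np.asarray(times_us, dtype=float)
    if t.size == 0:
        raise EmptyInputError("no completed passages")
    if (t <= 0).any():
        raise ConfigError("passage times must be > 0")
    mean = float(t.mean())
    sd = float(t.std(ddof=1)) if t.size > 1 else 0.0
    return KineticEstimate(
        rate=1.0 / mean, mfpt_mean=mean, mfpt_sd=sd,
        mfpt_se=sd / np.sqrt(t.size), n=int(t.size), censored=censored,
    )


def episode_dwells(episodes: list[Episode], site: str,
                   next_site: str | None = None) -> np.ndarray:
    """Durations (μs) of episodes at *site*; with *next_site*, only dwells
    terminated by a transition to that site (the same particle's successor
    episode). Episodes of different particles are chained independently."""
    by_particle: dict[str, list[Episode]] = {}
    for e in episodes:
        by_particle.setdefault(e.particle, []).append(e)
    out = []
    for eps in by_particle.values():
        eps = sorted(eps, key=lambda e: e.t_start)
        for e, nxt in zip(eps, eps[1:] + [None]):
            if e.site != site:
                continue
            if next_site is not None and (nxt is None or nxt.site != next_site):
                continue
            out.append(e.duration)
    return np.asarray(out) / NS_PER_US


@dataclass(frozen=True)
class TransitionRecord:
    """One change of the joint ligation state."""

    from_state: frozenset  # {(site, particle), ...} over the Na sites
    to_state: frozenset
    time: float  # ns

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise ConfigError("transition must change the ligation state")


def ligation_transitions(series_list: list[LabelSeries],
                         min_dwell: float = 50.0) -> list[TransitionRecord]:
    """Transitions of the joint (site -> particle) ligation state.

    The per-frame ligation state collects the four sodium sites only;
    episodes shorter than *min_dwell* ns are filtered out first, so
    sub-threshold blips do not generate transitions. Two particles
    claiming one site in the same frame is a conflict error.
    """
    from .assignment import extract_episodes

    if not series_list:
        raise EmptyInputError("no label series")
    n = series_list[0].n_frames
    dt = series_list[0].frame_interval
    for s in series_list[1:]:
        if s.n_frames != n or s.frame_interval != dt:
            raise StructureError("label series are not on the same frame grid")
    # rebuild filtered per-frame site labels from kept episodes
    filtered = {}
    for s in series_list:
        lab = np.full(n, None, dtype=object)
        for e in extract_episodes(s, min_dwell=min_dwell, site_set=NA_SITES):
            i0 = int(round(e.t_start / dt))
            i1 = int(round(e.t_end / dt))
            lab[i0:i1] = e.site
        filtered[s.particle] = lab
    states = []
    for k in range(n):
        claim: dict[str, str] = {}
        for p, lab in filtered.items():
            site = lab[k]
            if site is None:
                continue
            if site in claim:
                raise InconsistencyError(
                    f"frame {k}: site {site} claimed by {claim[site]} and {p}"
                )
            claim[site] = p
        states.append(frozenset(claim.items()))
    records = []
    for k in range(1, n):
        if states[k] != states[k - 1]:
            records.append(TransitionRecord(from_state=states[k - 1],
                                            to_state=states[k], time=k * dt))
    return records


def estimate_ctmc_rates(source, particle: str | None = None,
                        states: list[str] | None = None) -> pd.DataFrame:
    """Maximum-likelihood CTMC rate matrix k_ij = N_ij / T_i (μs⁻¹).

    *source* is a LabelSeries (frame-grid dwells) or StateTimeline (exact
    dwells; state names are per-particle locations). Rows of states never
    visited are NaN (flagged undefined), not zero; pass *states* to include
    declared-but-unvisited states. The final, censored dwell contributes to
    T_i but cannot contribute a transition.
    """
    times, labels, t_end = _change_points(source, particle)
    states = sorted(set(labels) | set(states or ()))
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    counts = np.zeros((n, n))
    dwell = np.zeros(n)
    bounds = np.concatenate((times, [t_end]))
    for i, lab in enumerate(labels):
        dwell[index[lab]] += bounds[i + 1] - bounds[i]
        if i + 1 < len(labels):
            counts[index[lab], index[labels[i + 1]]] += 1
    dwell_us = dwell / NS_PER_US
    with np.errstate(divide="ignore", invalid="ignore"):
        k = counts / dwell_us[:, None]
    np.fill_diagonal(k, 0.0)
    for s, i in index.items():
        if dwell_us[i] == 0:
            if counts[i].sum() > 0:
                raise InconsistencyError(f"state {s}: transitions without dwell time")
            k[i, :] = np.nan
    return pd.DataFrame(k, index=states, columns=states)


@dataclass
class ZTrace:
    """Substrate position along z with region labels."""

    z: np.ndarray        # Å, per frame
    regions: np.ndarray  # object array over {S1, vestibule, S2_band, EC}
    frame_interval: float


@dataclass(frozen=True)
class ZBands:
    """Region boundaries along +z (Å): S1 below *s1_halfwidth*, the S2 band
    within [s2_lo, s2_hi) (the putative secondary site ~10 Å above S1),
    vestibule between, EC beyond. Intervals are half-open [lo, hi)."""

    s1_halfwidth: float = 2.0
    s2_lo: float = 8.0
    s2_hi: float = 12.0

    def __post_init__(self) -> None:
        if not (0 < self.s1_halfwidth < self.s2_lo < self.s2_hi):
            raise ConfigError("z-bands must be positive and strictly increasing")


def substrate_z_trace(traj, substrate, bands: ZBands | None = None) -> ZTrace:
    """Per-frame substrate z (S1 at z = 0, +z extracellular) and region label."""
    bands = bands or ZBands()
    if hasattr(traj, "frames"):
        if isinstance(substrate, (int, np.integer)):
            z = traj.frames[:, int(substrate), 2]
        else:
            z = traj.positions(substrate)[:, 2]
        dt = traj.frame_interval
    else:
        z = np.asarray(traj, dtype=float)
        dt = float(substrate)
    regions = np.empty(len(z), dtype=object)
    regions[:] = "EC"
    regions[z < bands.s2_hi] = "S2_band"
    regions[z < bands.s2_lo] = "vestibule"
    regions[z < bands.s1_halfwidth] = "S1"
    return ZTrace(z=z, regions=regions, frame_interval=dt)


def _monotone_match(ta: list[float], tb: list[float]) -> list[tuple[float, float]]:
    """Order-preserving one-to-one matching of two sorted event-time lists,
    maximising the number of pairs and, among those, minimising the total
    |t_a - t_b|. Robust to occasional missed events on either side."""
    n, m = len(ta), len(tb)
    skip = 1e12  # >> any time difference: skips only when unavoidable
    cost = np.full((n + 1, m + 1), np.inf)
    cost[0, :] = np.arange(m + 1) * skip
    cost[:, 0] = np.arange(n + 1) * skip
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost[i, j] = min(cost[i - 1, j - 1] + abs(ta[i - 1] - tb[j - 1]),
                             cost[i - 1, j] + skip, cost[i, j - 1] + skip)
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        if np.isclose(cost[i, j],
                      cost[i - 1, j - 1] + abs(ta[i - 1] - tb[j - 1])):
            pairs.append((ta[i - 1], tb[j - 1]))
            i, j = i - 1, j - 1
        elif np.isclose(cost[i, j], cost[i - 1, j] + skip):
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def event_order_test(episodes_a: list[Episode], episodes_b: list[Episode],
                     relation: str = "a_release_before_b_release",
                     horizon: float | None = None):
    """Pairwise ordering verdicts between two particles' events.

    Releases are episode end times, bindings episode start times. Events
    are paired one-to-one in chronological order (maximum matching with
    minimum total time offset, so an occasional undetected event on one
    side drops a pair instead of shifting all later ones). Returns
    ``(verdicts, aggregate, n_unpaired)`` where each verdict is
    ``(lag_us, ok)`` with lag = t_b - t_a (positive when a precedes b) and
    aggregate is the satisfied fraction (NaN with no matchable events).
    """
    if relation == "a_release_before_b_release":
        ta = sorted(e.t_end for e in episodes_a)
        tb = sorted(e.t_end for e in episodes_b)
        if horizon is not None:
            # an episode truncated by the end of the series is censored,
            # not a release
            ta = [t for t in ta if t < horizon]
            tb = [t for t in tb if t < horizon]
    elif relation == "a_bind_before_b_bind":
        ta = sorted(e.t_start for e in episodes_a)
        tb = sorted(e.t_start for e in episodes_b)
    else:
        raise ConfigError(f"unknown relation {relation!r}")
    pairs = _monotone_match(ta, tb)
    verdicts = [((b - a) / NS_PER_US, a < b) for a, b in pairs]
    n = len(pairs)
    aggregate = (sum(ok for _, ok in verdicts) / n) if n else float("nan")
    return verdicts, aggregate, (len(ta) + len(tb) - 2 * n)
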