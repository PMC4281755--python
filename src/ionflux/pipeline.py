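"""Pipeline stages shared by the CLI and scripted analyses.

The canonical flow is simulate -> render -> assign -> kinetics/gating ->
report. Each stage is a plain function over the library types so it can be
driven from the command line, from tests, or from scripts; all stochastic
stages take explicit seeds and all tabular outputs are UTF-8 TSV with
``#``-prefixed metadata lines.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import (Episode, LabelSeries, extract_episodes, occupancy_fractions,
                         site_sequence, sites_from_geometry)
from .assignment import assign_trajectory as _assign_trajectory
from .core_io import Topology, Trajectory
from .errors import ConfigError, EmptyInputError
from .gating import chi1_class, opening_class, saltbridge_state
from .kinetics import (KineticEstimate, episode_dwells, first_passage_times,
                       ligation_transitions, rate_from_mfpt)
from .mechanism import (GatingCoupling, GatingSeries, MechanismConfig, SiteGeometry,
                        StateTimeline, display_name, embed_timeline,
                        generate_gating_series, particle_index, simulate_mechanism)

#: the first-passage transitions reported by the standard kinetics table:
#: name -> (source condition, target condition) over location labels
STANDARD_TRANSITIONS: dict[str, tuple[object, object]] = {
    "vestibule->Na1pp": ("vestibule", "Na1pp"),
    "Na1pp->vestibule": ("Na1pp", frozenset({"vestibule", "bulk"})),
    "Na1->Na1p": ("Na1", "Na1p"),
    "Na1p->Na1": ("Na1p", "Na1"),
}


@dataclass
class ChainResult:
    """Everything one simulated subunit produces."""

    chain_id: str
    timeline: StateTimeline
    trajectory: Trajectory
    gating: GatingSeries | None


def run_simulation(
    mechanism: MechanismConfig,
    geometry: SiteGeometry,
    duration: float,
    seed: int,
    frame_interval: float = 1.25,
    n_chains: int = 1,
    with_gating: bool = True,
    coupling: GatingCoupling | None = None,
    render: bool = True,
) -> list[ChainResult]:
    """Simulate and render *n_chains* independent subunits.

    The dimer is emulated as independent chains (A, B, ...) with seeds
    spawned deterministically from *seed*.
    """
    if duration <= 0:
        raise ConfigError("duration must be > 0")
    chains = []
    for i in range(n_chains):
        chain_id = chr(ord("A") + i)
        # keep derived seeds well below 2**31
        s = (int(seed) * 7919 + i * 104729) % (2**31 - 1)
        timeline = simulate_mechanism(mechanism, duration, seed=s)
        traj = (embed_timeline(timeline, geometry, frame_interval, seed=s + 1,
                               chain_id=chain_id) if render else None)
        gating = (generate_gating_series(timeline, coupling, seed=s + 2,
                                         frame_interval=frame_interval)
                  if with_gating else None)
        chains.append(ChainResult(chain_id, timeline, traj, gating))
    return chains


@dataclass
class ChainAnalysis:
    chain_id: str
    series: list[LabelSeries]
    episodes: list[Episode]
    occupancy: dict[str, dict[str, float]] = field(default_factory=dict)


def analyze_chain(
    traj: Trajectory,
    geometry: SiteGeometry,
    particles: dict[str, int] | None = None,
    cutoff: float = 3.0,
    min_dwell: float = 50.0,
    chain_id: str = "A",
    site_order: list[str] | None = None,
) -> ChainAnalysis:
    """Assign a rendered (or real, geometry-referenced) trajectory."""
    if particles is None:
        particles = particles_from_topology(traj.topology)
    sites = sites_from_geometry(geometry, cutoff=cutoff, order=site_order)
    series = _assign_trajectory(traj, particles, sites,
                                geometry.vestibule_axis, geometry.bulk_z_min)
    episodes = []
    occ = {}
    for s in series:
        episodes.extend(extract_episodes(s, min_dwell=min_dwell))
        occ[s.particle] = occupancy_fractions(s)
    return ChainAnalysis(chain_id=chain_id, series=series, episodes=episodes,
                         occupancy=occ)


def particles_from_topology(topo: Topology) -> dict[str, int]:
    """Track every sodium/substrate pseudo-atom found in a topology."""
    particles: dict[str, int] = {}
    for i in range(topo.n_atoms):
        resname = topo.residue_names[i]
        chain = topo.chain_ids[i]
        if resname in ("SOD", "NA"):
            particles[f"Na_{chain}{topo.residue_numbers[i]}"] = i
        elif resname == "LEU" and topo.atom_names[i] in ("CA", "C1"):
            particles[f"sub_{chain}{topo.residue_numbers[i]}"] = i
    if not particles:
        raise ConfigError("no sodium/substrate particles found in topology")
    return particles


def kinetics_table(
    series_list: list[LabelSeries],
    transitions: dict[str, tuple[object, object]] | None = None,
) -> pd.DataFrame:
    """Pooled first-passage kinetics for the standard transition set.

    Passages are pooled over all particles/chains; rows with no completed
    passage carry n=0 and NaN statistics.
    """
    transitions = transitions or STANDARD_TRANSITIONS
    rows = []
    for name, (src, tgt) in transitions.items():
        pooled = []
        censored = 0
        for s in series_list:
            t, c = first_passage_times(s, src, tgt)
            pooled.append(t)
            censored += c
        times = np.concatenate(pooled) if pooled else np.array([])
        if times.size:
            est = rate_from_mfpt(times, censored=censored)
            rows.append((name, est.n, est.mfpt_mean, est.mfpt_sd, est.rate, censored))
        else:
            rows.append((name, 0, np.nan, np.nan, np.nan, censored))
    return pd.DataFrame(
        rows, columns=["transition", "n", "mfpt_mean_us", "mfpt_sd_us",
                       "rate_per_us", "censored"],
    )


def gating_table(gating: GatingSeries) -> pd.DataFrame:
    """Per-frame gating observables with their classes."""
    n = gating.n_frames
    sb_class = [saltbridge_state(d) for d in gating.saltbridge]
    chi_class = [chi1_class(a) for a in gating.chi1]
    oc = [opening_class(min(a, b))
          for a, b in zip(gating.opening_tm1b, gating.opening_tm6a)]
    return pd.DataFrame({
        "frame": np.arange(n),
        "time_ns": gating.times,
        "open1b_pct": gating.opening_tm1b,
        "open6a_pct": gating.opening_tm6a,
        "open_class": oc,
        "chi1_deg": gating.chi1,
        "chi1_class": chi_class,
        "sb_dist": gating.saltbridge,
        "sb_class": sb_class,
        "water_count": gating.water,
    })


_CLASS_LETTER = {"open": "o", "intermediate": "i", "occluded": "x"}


def opening_transition_string(pct: np.ndarray, min_run: int = 4) -> str:
    """Compress a per-frame opening-percent series into the x/i/o alphabet
    (occluded/intermediate/open), e.g. ``x → o`` for a single opening.

    Class runs shorter than *min_run* frames are transient passes through a
    boundary (e.g. the single intermediate frame of a fast opening) and are
    omitted from the notation.
    """
    letters = [_CLASS_LETTER[opening_class(p)] for p in pct]
    runs = []
    for l in letters:
        if runs and runs[-1][0] == l:
            runs[-1][1] += 1
        else:
            runs.append([l, 1])
    compressed = []
    for l, count in runs:
        if count >= min_run and (not compressed or compressed[-1] != l):
            compressed.append(l)
    return " → ".join(compressed)


def event_table_report(analyses: list[ChainAnalysis],
                       gatings: dict[str, GatingSeries] | None = None) -> str:
    """Plain-text per-chain event table: ordered site visits per particle
    and TM1b/TM6a opening transitions in the x/i/o notation."""
    lines = []
    for a in analyses:
        lines.append(f"chain {a.chain_id}:")
        by_particle: dict[str, list[Episode]] = {}
        for e in a.episodes:
            by_particle.setdefault(e.particle, []).append(e)
        for s in a.series:
            eps = by_particle.get(s.particle, [])
            seq = [display_name(x) for x in site_sequence(eps)]
            if eps and s.labels[-1] == "bulk":
                seq.append("EC")
            lines.append(f"  {s.particle}: {' → '.join(seq) if seq else '(no binding)'}")
        if gatings and a.chain_id in gatings:
            g = gatings[a.chain_id]
            lines.append(f"  TM1b: {opening_transition_string(g.opening_tm1b)}")
            lines.append(f"  TM6a: {opening_transition_string(g.opening_tm6a)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# TSV writers / readers (all tables UTF-8, '#' metadata lines first)


def _write_tsv(df: pd.DataFrame, path, meta: dict | None = None,
               float_format: str = "%.6g") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def write_timeline_tsv(timeline: StateTimeline, path) -> None:
    df = pd.DataFrame(timeline.events, columns=["time_ns", "state"])
    _write_tsv(df, path, meta={"total_duration_ns": timeline.total_duration},
               float_format="%.6f")


def read_timeline_tsv(path, states) -> StateTimeline:
    total = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# total_duration_ns:"):
                total = float(line.split(":", 1)[1])
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    events = list(zip(df["time_ns"].astype(float), df["state"].astype(str)))
    if total is None:
        total = events[-1][0]
    return StateTimeline(events=events, states=states, total_duration=total)


def write_labels_tsv(series_list: list[LabelSeries], path) -> None:
    parts = []
    for s in series_list:
        parts.append(pd.DataFrame({
            "particle": s.particle,
            "frame": np.arange(s.n_frames),
            "time_ns": s.times,
            "label": s.labels,
        }))
    _write_tsv(pd.concat(parts, ignore_index=True), path)


def write_episodes_tsv(episodes: list[Episode], path) -> None:
    df = pd.DataFrame(
        [(e.particle, e.site, e.t_start, e.t_end) for e in episodes],
        columns=["particle", "site", "t_start_ns", "t_end_ns"],
    )
    _write_tsv(df, path)


def write_kinetics_tsv(table: pd.DataFrame, path) -> None:
    _write_tsv(table, path)


def write_occupancy_tsv(occupancy: dict[str, dict[str, float]], path) -> None:
    rows = [(p, label, frac) for p, d in occupancy.items() for label, frac in d.items()]
    _write_tsv(pd.DataFrame(rows, columns=["particle", "label", "fraction"]), path,
               float_format="%.8f")


def write_gating_tsv(table: pd.DataFrame, path) -> None:
    _write_tsv(table, path)


def read_gating_tsv(path) -> GatingSeries:
    df = pd.read_csv(path, sep="\t", comment="#")
    dt = float(df["time_ns"].iloc[1] - df["time_ns"].iloc[0]) if len(df) > 1 else 1.25
    return GatingSeries(
        opening_tm1b=df["open1b_pct"].to_numpy(float),
        opening_tm6a=df["open6a_pct"].to_numpy(float),
        chi1=df["chi1_deg"].to_numpy(float),
        saltbridge=df["sb_dist"].to_numpy(float),
        water=df["water_count"].to_numpy(np.int64),
        frame_interval=dt,
    )


def write_transitions_tsv(records, path) -> None:
    def fmt(state: frozenset) -> str:
        return "+".join(f"{site}:{p}" for site, p in sorted(state)) or "apo"

    df = pd.DataFrame(
        [(r.time, fmt(r.from_state), fmt(r.to_state)) for r in records],
        columns=["time_ns", "from_state", "to_state"],
    )
    _write_tsv(df, path)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()


def write_manifest(path, config: dict, seed: int, inputs: list[str],
                   outputs: list[str]) -> dict:
    manifest = {
        "tool": "ionflux",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": int(seed),
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
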