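"""Shipped default configurations.

Three named mechanism configurations are provided:

``binding_cycle``
    The vestibule ⇌ Na1'' bind/unbind cycle at the rates implied by the
    measured first-passage times: k_b = 55 μs⁻¹ (mean vestibule→Na1''
    passage 0.018 μs) and k_u = 2.3 μs⁻¹ (mean bound dwell 0.43 μs). This
    is the configuration against which the binding/unbinding kinetics
    estimators are benchmarked.

``na1_exchange``
    The Na1 ⇌ Na1' exchange at rates 1/0.173 ≈ 5.78 μs⁻¹ and
    1/0.060 ≈ 16.7 μs⁻¹ (the observed residence times of the frequent
    Na1/Na1' exchanges).

``full``
    A complete loading + release cycle for two sodium ions and one
    substrate obeying the mechanism's ordering constraints: extracellular
    sodium always enters via Na1'' (never directly to Na1, Na1' or Na2);
    Na1' is reachable only from Na1; Na2 release requires prior substrate
    release and exits via Na1''. Only the four rates above are anchored to
    measured values; the remaining rates are free parameters set to
    order-of-magnitude defaults and are flagged as such.

All rates are μs⁻¹ and live in one editable structure (YAML round-trip
supported); binding from solution is treated as pseudo-first-order (one
effective rate, no explicit concentration).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .mechanism import GatingCoupling, LigationState, MechanismConfig, SiteGeometry

# the four measured rates (μs⁻¹)
K_BIND_NA1PP = 55.0          # vestibule -> Na1'', 1/0.018 to 2 s.f.
K_UNBIND_NA1PP = 2.3         # Na1'' -> vestibule, 1/0.43
K_NA1_TO_NA1P = 1.0 / 0.173  # ≈ 5.78
K_NA1P_TO_NA1 = 1.0 / 0.060  # ≈ 16.7

# free parameters (not anchored to any measured value)
K_NA1PP_TO_NA1 = 5.0     # translocation "within hundreds of nanoseconds"
K_ARRIVE = 50.0          # bulk -> vestibule arrival (pseudo-first-order)
K_DEPART = 20.0          # vestibule -> bulk escape
K_NA1PP_TO_NA2 = 5.0
K_SUB_BIND_S1 = 10.0
K_SUB_RELEASE = 2.0
K_NA1_TO_NA1PP_BACK = 1.0
K_NA2_TO_NA1PP = 5.0


def binding_cycle_config() -> MechanismConfig:
    """Two-state vestibule ⇌ Na1'' cycle at the measured k_b, k_u."""
    return MechanismConfig(
        species=("Na_a",),
        states={
            "unbound": LigationState.from_dict({"Na_a": "vestibule"}),
            "bound": LigationState.from_dict({"Na_a": "Na1pp"}),
        },
        rates={
            ("unbound", "bound"): K_BIND_NA1PP,
            ("bound", "unbound"): K_UNBIND_NA1PP,
        },
        initial="unbound",
    )


def na1_exchange_config() -> MechanismConfig:
    """Two-site Na1 ⇌ Na1' exchange at the measured residence-time rates."""
    return MechanismConfig(
        species=("Na_a",),
        states={
            "at_Na1": LigationState.from_dict({"Na_a": "Na1"}),
            "at_Na1p": LigationState.from_dict({"Na_a": "Na1p"}),
        },
        rates={
            ("at_Na1", "at_Na1p"): K_NA1_TO_NA1P,
            ("at_Na1p", "at_Na1"): K_NA1P_TO_NA1,
        },
        initial="at_Na1",
    )


def full_mechanism_config() -> MechanismConfig:
    """Loading + release cycle for (Na_a, Na_b, substrate).

    State chain (single-particle moves only)::

        apo -> a@Na1'' -> a@Na1 (⇌ a@Na1') -> b arrives -> b@Na1''
            -> b@Na2 -> substrate arrives -> loaded (occluded)
            -> substrate release -> substrate leaves
            -> b@Na2 -> b@Na1'' -> b leaves
            -> a@Na1 -> a@Na1'' -> apo (cycle repeats)
    """
    def st(a, b, s):
        return LigationState.from_dict({"Na_a": a, "Na_b": b, "substrate": s})

    states = {
        "apo": st("vestibule", "bulk", "bulk"),
        "a_na1pp": st("Na1pp", "bulk", "bulk"),
        "a_na1": st("Na1", "bulk", "bulk"),
        "a_na1p": st("Na1p", "bulk", "bulk"),
        "b_vest": st("Na1", "vestibule", "bulk"),
        "b_na1pp": st("Na1", "Na1pp", "bulk"),
        "b_na2": st("Na1", "Na2", "bulk"),
        "s_vest": st("Na1", "Na2", "vestibule"),
        "loaded": st("Na1", "Na2", "S1"),
        "s_released": st("Na1", "Na2", "vestibule"),
        "s_gone": st("Na1", "Na2", "bulk"),
        "b_rel_na1pp": st("Na1", "Na1pp", "bulk"),
        "b_rel_vest": st("Na1", "vestibule", "bulk"),
        "b_gone": st("Na1", "bulk", "bulk"),
        "a_rel_na1pp": st("Na1pp", "bulk", "bulk"),
        "a_rel_vest": st("vestibule", "bulk", "bulk"),
    }
    rates = {
        ("apo", "a_na1pp"): K_BIND_NA1PP,
        ("a_na1pp", "apo"): K_UNBIND_NA1PP,
        ("a_na1pp", "a_na1"): K_NA1PP_TO_NA1,
        ("a_na1", "a_na1p"): K_NA1_TO_NA1P,
        ("a_na1p", "a_na1"): K_NA1P_TO_NA1,
        ("a_na1", "b_vest"): K_ARRIVE,
        ("b_vest", "b_na1pp"): K_BIND_NA1PP,
        ("b_na1pp", "b_vest"): K_UNBIND_NA1PP,
        ("b_na1pp", "b_na2"): K_NA1PP_TO_NA2,
        ("b_na2", "s_vest"): K_ARRIVE,
        ("s_vest", "loaded"): K_SUB_BIND_S1,
        ("loaded", "s_released"): K_SUB_RELEASE,
        ("s_released", "s_gone"): K_DEPART,
        ("s_gone", "b_rel_na1pp"): K_NA2_TO_NA1PP,
        ("b_rel_na1pp", "b_rel_vest"): K_UNBIND_NA1PP,
        ("b_rel_vest", "b_gone"): K_DEPART,
        ("b_gone", "a_rel_na1pp"): K_NA1_TO_NA1PP_BACK,
        ("a_rel_na1pp", "a_rel_vest"): K_UNBIND_NA1PP,
        ("a_rel_vest", "apo"): 1.0,  # re-approach; closes the cycle
    }
    return MechanismConfig(
        species=("Na_a", "Na_b", "substrate"),
        states=states,
        rates=rates,
        initial="apo",
    )


NAMED_MECHANISMS = {
    "binding_cycle": binding_cycle_config,
    "na1_exchange": na1_exchange_config,
    "full": full_mechanism_config,
}


def default_geometry() -> SiteGeometry:
    """Site centres in the S1-at-origin frame (+z extracellular), Å.

    Na1'' is placed 5.7 Å from both Na1 and Na2, above the S1 plane on the
    extracellular approach; the vestibule spans z in [8, 15] and bulk lies
    beyond z = 18.
    """
    return SiteGeometry(
        centers={
            "S1": np.array([0.0, 0.0, 0.0]),
            "Na1": np.array([3.5, 0.0, 0.0]),
            "Na1p": np.array([3.5, 3.5, 0.0]),
            "Na2": np.array([-3.5, 0.0, 0.0]),
            "Na1pp": np.array([0.0, 0.0, 4.5]),
        },
        vestibule_axis=(8.0, 15.0),
        bulk_z_min=18.0,
        jitter_sd=0.3,
    )


# Coordinating-atom selections for real-mode assignment: residue shells of
# each site. Na1 and Na1' share a residue list; Na1' additionally requires
# the Glu290 carboxylate within the cutoff, which is how the two are told
# apart.
SITE_RESIDUES = {
    "Na1pp": (21, 256, 355, 286),
    "Na1": (22, 27, 47, 254, 286, 290),
    "Na1p": (22, 27, 47, 254, 286, 290),
    "Na2": (20, 23, 351, 354, 355),
    "S1": (22, 25, 26, 104, 108, 253, 354, 258, 359, 260, 261, 262),
}


# ---------------------------------------------------------------------------
# YAML round-trip


def mechanism_to_dict(config: MechanismConfig) -> dict:
    return {
        "species": list(config.species),
        "states": {name: dict(st.placements) for name, st in config.states.items()},
        "rates": [[a, b, float(k)] for (a, b), k in config.rates.items()],
        "initial": config.initial,
    }


def mechanism_from_dict(data: dict) -> MechanismConfig:
    try:
        return MechanismConfig(
            species=tuple(data["species"]),
            states={name: LigationState.from_dict(p) for name, p in data["states"].items()},
            rates={(a, b): float(k) for a, b, k in data["rates"]},
            initial=data["initial"],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed mechanism config: {exc}") from exc


def geometry_to_dict(geometry: SiteGeometry) -> dict:
    return {
        "centers": {k: [float(x) for x in v] for k, v in geometry.centers.items()},
        "vestibule_axis": [float(geometry.vestibule_axis[0]), float(geometry.vestibule_axis[1])],
        "bulk_z_min": float(geometry.bulk_z_min),
        "jitter_sd": float(geometry.jitter_sd),
    }


def geometry_from_dict(data: dict) -> SiteGeometry:
    try:
        return SiteGeometry(
            centers={k: np.asarray(v, dtype=float) for k, v in data["centers"].items()},
            vestibule_axis=tuple(data["vestibule_axis"]),
            bulk_z_min=float(data["bulk_z_min"]),
            jitter_sd=float(data.get("jitter_sd", 0.3)),
            walk_step_sd=float(data.get("walk_step_sd", 0.8)),
            lateral_sd=float(data.get("lateral_sd", 1.5)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed geometry config: {exc}") from exc


def default_pipeline_config() -> dict:
    """One-file pipeline configuration (sections mirror the CLI stages)."""
    return {
        "mechanism": "full",
        "geometry": geometry_to_dict(default_geometry()),
        "sites": {
            "cutoff": 3.0,
            "order": ["Na1", "Na1p", "Na1pp", "Na2", "S1"],
        },
        "gating_refs": {
            "tm1b": {"d_closed": 10.0, "d_max": 20.0},
            "tm6a": {"d_closed": 10.0, "d_max": 20.0},
            "saltbridge_thresholds": [5.25, 7.65],
            "water_threshold": 25.0,
        },
        "bands": {"s1_halfwidth": 2.0, "s2_band": [8.0, 12.0]},
        "kinetics": {"min_dwell_ns": 50.0, "fpt_min_dwell_ns": 0.0},
    }


def load_pipeline_config(path) -> dict:
    base = default_pipeline_config()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for key, val in data.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            base[key].update(val)
        else:
            base[key] = val
    return base


def save_pipeline_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def resolve_mechanism(spec) -> MechanismConfig:
    """A mechanism given by name ('binding_cycle', 'na1_exchange', 'full')
    or as an inline mapping."""
    if isinstance(spec, str):
        try:
            return NAMED_MECHANISMS[spec]()
        except KeyError:
            raise ConfigError(
                f"unknown mechanism {spec!r}; choices: {sorted(NAMED_MECHANISMS)}"
            ) from None
    if isinstance(spec, dict):
        return mechanism_from_dict(spec)
    raise ConfigError("mechanism must be a name or a mapping")
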