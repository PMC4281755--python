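"""Shared fixtures: small PDB files and short synthetic runs.

All fixtures are generated programmatically; nothing binary ships with the
package.
"""

from __future__ import annotations

import numpy as np
import pytest

import ionflux as fx


def format_pdb_atom(serial, name, resname, chain, resid, x, y, z) -> str:
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain}{resid:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
    )


@pytest.fixture
def toy_pdb(tmp_path):
    """Three-atom single-chain PDB."""
    path = tmp_path / "toy.pdb"
    lines = [
        format_pdb_atom(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
        format_pdb_atom(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0),
        format_pdb_atom(3, "C", "ALA", "A", 1, 2.2, 1.2, 0.0),
        "END\n",
    ]
    path.write_text("".join(lines))
    return path


@pytest.fixture
def dimer_pdb(tmp_path):
    """Two chains (A, B) each with a Phe-253 fragment (N, CA, CB, CG) and a
    sodium ion, mimicking the two transporter subunits."""
    path = tmp_path / "dimer.pdb"
    lines = []
    serial = 1
    for i, chain in enumerate("AB"):
        off = 20.0 * i
        for name, xyz in [("N", (0, 1.4, 0)), ("CA", (0, 0, 0)),
                          ("CB", (1.5, 0, 0)), ("CG", (2.0, 1.3, 0.4))]:
            lines.append(format_pdb_atom(serial, name, "PHE", chain, 253,
                                         xyz[0] + off, xyz[1], xyz[2]))
            serial += 1
        lines.append(format_pdb_atom(serial, "NA", "SOD", chain, 1,
                                     5.0 + off, 5.0, 5.0))
        serial += 1
    lines.append("END\n")
    path.write_text("".join(lines))
    return path


@pytest.fixture
def geometry():
    return fx.default_geometry()


@pytest.fixture(scope="session")
def binding_run():
    """A moderate vestibule ⇌ Na1'' run rendered at 1.25 ns (session-scoped;
    ~450 binding cycles)."""
    import warnings

    geometry = fx.default_geometry()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        chains = fx.run_simulation(fx.binding_cycle_config(), geometry,
                                   duration=2.0e5, seed=11, n_chains=1,
                                   with_gating=False)
    return chains[0], geometry


@pytest.fixture(scope="session")
def full_run():
    """A full-mechanism loading/release run (3 particles, 2e5 ns)."""
    import warnings

    geometry = fx.default_geometry()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        chains = fx.run_simulation(fx.full_mechanism_config(), geometry,
                                   duration=2.0e5, seed=5, n_chains=1,
                                   with_gating=True)
    return chains[0], geometry


def label_series(labels, particle="Na_x", dt=1.25):
    return fx.LabelSeries(particle=particle,
                          labels=np.array(labels, dtype=object),
                          frame_interval=dt)
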