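"""Shared fixtures: hypothesis profile, toy PDB writer, QC fixture set."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def format_pdb_atom(serial, name, resname, chain, resseq, x, y, z,
                    element="C", altloc=" ", icode=" ") -> str:
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {pad_name}{altloc}{resname:>3s} {chain}"
        f"{resseq:>4d}{icode}   {x:>8.3f}{y:>8.3f}{z:>8.3f}"
        f"{1.0:>6.2f}{0.0:>6.2f}          {element:>2s}"
    )


@pytest.fixture
def write_pdb(tmp_path):
    """Write a minimal PDB file from (name, resname, chain, resseq, xyz) rows."""

    def _write(atoms, filename="toy.pdb"):
        lines = []
        for i, atom in enumerate(atoms, start=1):
            lines.append(format_pdb_atom(serial=i, **atom))
        lines.append("END")
        path = tmp_path / filename
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def make_slab_structure(linker_length=10.0, clash_cutoff=1.8):
    """Attachment atom above a thick slab of atoms filling the lower
    half-space, so the sterically allowed region is exactly z >= 0."""
    from clampfret import structure as sm

    extent = linker_length + 4.0
    wall_xy = np.arange(-extent, extent + 0.01, 0.5)
    gx, gy = np.meshgrid(wall_xy, wall_xy)
    layers = np.arange(-clash_cutoff, -(linker_length + 2.0), -1.0)
    wall = np.vstack(
        [
            np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
            for z in layers
        ]
    )
    n = len(wall) + 1
    return sm.StructureAtoms(
        chains=np.array(["A"] + ["B"] * len(wall)),
        residues=np.arange(1, n + 1)[:n],
        icodes=np.array([""] * n),
        names=np.array(["CA"] + ["O"] * len(wall)),
        elements=np.array(["C"] * n),
        coords=np.vstack([[0.0, 0.0, 0.0], wall]),
    )


def _const_trace(mol, n, idd, ida, iaa, rng, noise=15.0, exposure=0.02):
    from clampfret.sim import AlexTrace

    return AlexTrace(
        mol,
        np.clip(idd + rng.normal(0, noise, n), 0, None),
        np.clip(ida + rng.normal(0, noise, n), 0, None),
        np.clip(iaa + rng.normal(0, noise, n), 0, None),
        exposure,
    )


@pytest.fixture(scope="session")
def qc_fixture_set():
    """Ten engineered traces: four compliant, six violating exactly one
    selection criterion each (intensity windows x3, early bleach,
    blinking, aggregate multi-step bleaching)."""
    from clampfret.sim import AlexTrace

    rng = np.random.default_rng(42)
    n = 500
    traces = []
    expected = {}

    # 0-2: fully compliant, no photophysics events
    for mol in range(3):
        traces.append(_const_trace(mol, n, 700, 300, 500, rng))
        expected[mol] = ("pass", "")
    # 3: compliant with a single acceptor bleach at frame 200
    idd = np.concatenate([np.full(200, 700.0), np.full(n - 200, 1000.0)])
    ida = np.concatenate([np.full(200, 300.0), np.zeros(n - 200)])
    iaa = np.concatenate([np.full(200, 500.0), np.zeros(n - 200)])
    traces.append(
        AlexTrace(
            3,
            np.clip(idd + rng.normal(0, 15, n), 0, None),
            np.clip(ida + rng.normal(0, 15, n), 0, None),
            np.clip(iaa + rng.normal(0, 15, n), 0, None),
            0.02,
        )
    )
    expected[3] = ("pass", "")
    # 4: I_DD too bright (2500 > 2000)
    traces.append(_const_trace(4, n, 2500, 300, 500, rng))
    expected[4] = ("fail", "idd_window")
    # 5: I_DD too dim (100 < 300)
    traces.append(_const_trace(5, n, 100, 300, 500, rng))
    expected[5] = ("fail", "idd_window")
    # 6: I_AA too bright (2500 > 2000)
    traces.append(_const_trace(6, n, 700, 300, 2500, rng))
    expected[6] = ("fail", "iaa_window")
    # 7: acceptor bleach in frame 30 (early-bleach rule, frames 1-50)
    idd = np.concatenate([np.full(30, 700.0), np.full(n - 30, 1000.0)])
    ida = np.concatenate([np.full(30, 300.0), np.zeros(n - 30)])
    iaa = np.concatenate([np.full(30, 500.0), np.zeros(n - 30)])
    traces.append(
        AlexTrace(
            7,
            np.clip(idd + rng.normal(0, 15, n), 0, None),
            np.clip(ida + rng.normal(0, 15, n), 0, None),
            np.clip(iaa + rng.normal(0, 15, n), 0, None),
            0.02,
        )
    )
    expected[7] = ("fail", "early_bleach")
    # 8: donor blink, frames 250-270, full recovery
    idd = np.full(n, 700.0)
    ida = np.full(n, 300.0)
    idd[250:270] = 0.0
    ida[250:270] = 0.0
    traces.append(
        AlexTrace(
            8,
            np.clip(idd + rng.normal(0, 15, n), 0, None),
            np.clip(ida + rng.normal(0, 15, n), 0, None),
            np.clip(500 + rng.normal(0, 15, n), 0, None),
            0.02,
        )
    )
    expected[8] = ("fail", "blinking")
    # 9: aggregate of two molecules, donor bleaches at 150 and 350
    idd = np.where(np.arange(n) < 150, 700.0, 0.0) + np.where(
        np.arange(n) < 350, 700.0, 0.0
    )
    ida = np.where(np.arange(n) < 150, 300.0, 0.0) + np.where(
        np.arange(n) < 350, 300.0, 0.0
    )
    iaa = np.full(n, 1000.0)
    traces.append(
        AlexTrace(
            9,
            np.clip(idd + rng.normal(0, 15, n), 0, None),
            np.clip(ida + rng.normal(0, 15, n), 0, None),
            np.clip(iaa + rng.normal(0, 15, n), 0, None),
            0.02,
        )
    )
    expected[9] = ("fail", "multistep_bleach")
    return traces, expected
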