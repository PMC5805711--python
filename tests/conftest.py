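import numpy as np
import pytest

from titrakit import GroundTruth, gen_binding_series, gen_ph_series, gen_temperature_series


@pytest.fixture()
def truth() -> GroundTruth:
    return GroundTruth(seed=1)


@pytest.fixture()
def ph_series_clean(truth):
    return gen_ph_series(truth, noise=False)


@pytest.fixture()
def temp_series_clean(truth):
    return gen_temperature_series(truth, noise=False)


@pytest.fixture()
def binding_series_clean(truth):
    return gen_binding_series(truth, noise=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def write_synthetic_pdb(path, coords_by_chain, bfac=20.0):
    """Write a minimal synthetic PDB file.

    ``coords_by_chain``: {chain: [(resnum, resname, [(atom, x, y, z, occ, altloc), ...])]}
    """
    lines = []
    serial = 1
    for chain, residues in coords_by_chain.items():
        for resnum, resname, atoms in residues:
            for atom, x, y, z, occ, altloc in atoms:
                elem = atom[0]
                lines.append(
                    f"ATOM  {serial:5d} {atom:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
                    f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}"
                    f"          {elem:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {residues[-1][1]:<3s} {chain:1s}{residues[-1][0]:4d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def synthetic_protein_coords(n_residues, rng, atoms=("N", "CA", "C", "O"), names=None):
    """Random-walk backbone coordinates for a synthetic test protein."""
    residues = []
    origin = np.zeros(3)
    for i in range(1, n_residues + 1):
        origin = origin + rng.normal(0, 1.2, 3) + np.array([3.0, 0.3, -0.2])
        atom_rows = []
        for j, name in enumerate(atoms):
            pos = origin + rng.normal(0, 0.6, 3) + j * np.array([0.4, 0.5, 0.1])
            atom_rows.append((name, *pos, 1.0, " "))
        resname = (names or ["ALA"] * n_residues)[i - 1]
        residues.append((i, resname, atom_rows))
    return residues
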