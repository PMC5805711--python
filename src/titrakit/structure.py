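"""Crystal-structure comparison: superposition, backbone RMSD, contacts.

Coordinates are read with gemmi (PDB or mmCIF); superposition is the
closed-form Kabsch algorithm (SVD with a reflection guard), applied to
backbone selections matched pairwise by (residue number, atom name).
RMSDs are reported with and without flexible C-terminal tail residues,
and :func:`contact_distances` measures donor–acceptor distances such as
the Q62 backbone amide nitrogen to the nearest residue-65 side-chain
oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "SuperpositionResult",
    "read_structure",
    "select_backbone",
    "superpose",
    "pair_rmsd",
    "contact_distances",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = {
    "N-CA-C": ("N", "CA", "C"),
    "N-CA-C-O": ("N", "CA", "C", "O"),
}

#: donor-acceptor distance below which a polar/hydrogen-bond contact is likely
HBOND_CUTOFF = 3.5  # Angstrom


@dataclass
class StructureModel:
    """A parsed coordinate model (first model of the file)."""

    entry_id: str
    structure: gemmi.Structure

    @property
    def model(self) -> gemmi.Model:
        return self.structure[0]

    def chain(self, name: str) -> gemmi.Chain:
        ch = self.model.find_chain(name)
        if ch is None:
            raise KeyError(f"{self.entry_id}: no chain {name!r}")
        return ch

    @property
    def chain_names(self) -> list[str]:
        return [ch.name for ch in self.model]

    def polymer_residues(self, chain: str) -> list[gemmi.Residue]:
        """Amino-acid residues of a chain (waters/heteroatoms excluded)."""
        return [
            res for res in self.chain(chain)
            if gemmi.find_tabulated_residue(res.name)
            and gemmi.find_tabulated_residue(res.name).is_amino_acid()
        ]

    def atom_pos(self, chain: str, residue_index: int, atom_name: str) -> np.ndarray:
        for res in self.chain(chain):
            if res.seqid.num == residue_index:
                atom = res.find_atom(atom_name, "*")
                if atom is not None:
                    return np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        raise KeyError(
            f"{self.entry_id}: atom {atom_name!r} of {chain}/{residue_index} not found"
        )


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB (or mmCIF) file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken toward altloc 'A'); waters and heteroatoms are kept in
    the model but excluded from protein selections.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    st.setup_entities()
    _resolve_altlocs(st)
    entry_id = st.name or path.stem
    return StructureModel(entry_id=entry_id.upper(), structure=st)


def _resolve_altlocs(st: gemmi.Structure) -> None:
    for model in st:
        for chain in model:
            for res in chain:
                groups: dict[str, list[gemmi.Atom]] = {}
                for atom in res:
                    groups.setdefault(atom.name, []).append(atom)
                keep: set[int] = set()
                for atoms in groups.values():
                    # highest occupancy wins; ties resolved alphabetically ('A' first)
                    best = min(atoms, key=lambda a: (-a.occ, a.altloc or "A"))
                    keep.add(id(best))
                for i in reversed(range(len(res))):
                    if id(res[i]) not in keep:
                        del res[i]
                for atom in res:
                    atom.altloc = "\0"


def select_backbone(
    model: StructureModel,
    chain: str,
    residue_range: tuple[int, int],
    atom_set: str = "N-CA-C-O",
) -> pd.DataFrame:
    """Backbone coordinates of a residue range, in residue-then-atom order.

    Returns a frame with columns residue_index, atom, x, y, z; missing
    atoms are simply absent (downstream matching is pairwise-complete).
    """
    if atom_set not in BACKBONE_ATOMS:
        raise ValueError(f"atom_set must be one of {sorted(BACKBONE_ATOMS)}")
    names = BACKBONE_ATOMS[atom_set]
    lo, hi = residue_range
    rows = []
    for res in model.polymer_residues(chain):
        num = res.seqid.num
        if not (lo <= num <= hi):
            continue
        for name in names:
            atom = res.find_atom(name, "*")
            if atom is not None:
                rows.append((num, name, atom.pos.x, atom.pos.y, atom.pos.z))
    if not rows:
        raise ValueError(
            f"{model.entry_id}: empty backbone selection {chain}/{lo}-{hi}"
        )
    return pd.DataFrame(rows, columns=["residue_index", "atom", "x", "y", "z"])


@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # 3x3, proper (det = +1)
    translation: np.ndarray  # applied as x' = R @ x + t
    rmsd: float              # Angstrom
    n_atoms: int
    selection: str = ""

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, target: np.ndarray, selection: str = "") -> SuperpositionResult:
    """Least-squares optimal rigid superposition of paired coordinate sets.

    Kabsch algorithm: SVD of the cross-covariance of the centered sets,
    with the determinant sign corrected so the result is a proper
    rotation (no reflection).  Requires n >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 paired atoms, got {n}")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    A = mobile - mc
    B = target - tc
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("degenerate (collinear) geometry")
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = A @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n,
                               selection=selection)


def pair_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_a: str,
    chain_b: str,
    residue_range: tuple[int, int],
    atom_set: str = "N-CA-C-O",
) -> SuperpositionResult:
    """Backbone RMSD between two structures over a residue range.

    Selections are matched pairwise-complete by (residue number, atom
    name); superposition and RMSD use the same matched atom set.  Fails
    when fewer than half of the expected pairs match (a sign of
    mis-specified chains or numbering).
    """
    sel_a = select_backbone(model_a, chain_a, residue_range, atom_set)
    sel_b = select_backbone(model_b, chain_b, residue_range, atom_set)
    merged = sel_a.merge(sel_b, on=["residue_index", "atom"], suffixes=("_a", "_b"))
    expected = max(len(sel_a), len(sel_b))
    if len(merged) < 0.5 * expected:
        raise ValueError(
            f"only {len(merged)}/{expected} backbone atoms matched between "
            f"{model_a.entry_id}:{chain_a} and {model_b.entry_id}:{chain_b}"
        )
    mobile = merged[["x_a", "y_a", "z_a"]].to_numpy()
    target = merged[["x_b", "y_b", "z_b"]].to_numpy()
    sel = (
        f"{model_a.entry_id}:{chain_a} vs {model_b.entry_id}:{chain_b} "
        f"{residue_range[0]}-{residue_range[1]} {atom_set}"
    )
    return superpose(mobile, target, selection=sel)


def contact_distances(
    model: StructureModel,
    donor: tuple[str, int, str],
    acceptors: tuple[str, int, tuple[str, ...]],
    hbond_cutoff: float = HBOND_CUTOFF,
) -> pd.DataFrame:
    """Distances from one donor atom to a set of candidate acceptor atoms.

    ``donor`` is (chain, residue, atom name); ``acceptors`` is (chain,
    residue, tuple of atom names).  Returns a table of per-candidate
    Euclidean distances with a hydrogen-bond heuristic flag
    (< ``hbond_cutoff`` Å); the minimum-distance candidate is first.
    Missing atoms raise KeyError naming the atom.
    """
    d_pos = model.atom_pos(*donor)
    rows = []
    for name in acceptors[2]:
        a_pos = model.atom_pos(acceptors[0], acceptors[1], name)
        dist = float(np.linalg.norm(a_pos - d_pos))
        rows.append({"acceptor_atom": name, "distance_A": dist,
                     "hbond_plausible": dist < hbond_cutoff})
    df = pd.DataFrame(rows).sort_values("distance_A").reset_index(drop=True)
    df.attrs["min_distance_A"] = float(df["distance_A"].iloc[0])
    df.attrs["donor"] = donor
    return df
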