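"""Read/write PDB structures, residue selection, superposition and RMSD.

The geometric substrate for the binding-mode analysis: structures are held
as :class:`Structure`, a thin container around a biotite ``AtomArray`` that
preserves original residue numbering (including negative numbers such as the
dockerin tail residues -5..0), exposes hetero Ca2+ ions, and provides the
residue-range truncation used to put the two crystal forms on a common
sequence footing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation


class PDBFormatError(ValueError):
    """Raised when a PDB stream cannot be parsed or yields no atoms."""


class SelectionError(ValueError):
    """Raised when a residue selection is empty or refers to a missing chain."""


#: hetero residue names treated as dockerin-bound calcium ions
ION_RES_NAMES = ("CA", "CA2", "CAL")


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive residue-number range on one chain."""

    chain_id: str
    first: int
    last: int

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError(f"first ({self.first}) > last ({self.last})")


@dataclass
class Structure:
    """Hierarchical atom container backed by a biotite ``AtomArray``.

    Atoms keep their original residue numbers and insertion codes; hydrogen
    atoms are dropped on ingestion (all downstream geometry is heavy-atom
    only).
    """

    atoms: struc.AtomArray
    source: str = field(default="", compare=False)

    # -- derived views -------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.atoms.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    def is_ion_mask(self) -> np.ndarray:
        return self.atoms.hetero & np.isin(self.atoms.res_name, ION_RES_NAMES)

    @property
    def ions(self) -> struc.AtomArray:
        """Hetero Ca2+ ion atoms."""
        return self.atoms[self.is_ion_mask()]

    @property
    def protein_atoms(self) -> struc.AtomArray:
        return self.atoms[~self.is_ion_mask()]

    def residue_ids(self, chain_id: str | None = None) -> list[tuple[int, str]]:
        """Ordered unique (residue_number, insertion_code) pairs."""
        a = self.protein_atoms
        if chain_id is not None:
            a = a[a.chain_id == chain_id]
        out: dict[tuple[int, str], None] = {}
        for rid, ic in zip(a.res_id, a.ins_code):
            out.setdefault((int(rid), str(ic)))
        return list(out)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids())

    def calpha(self, chain_id: str | None = None) -> struc.AtomArray:
        a = self.protein_atoms
        if chain_id is not None:
            a = a[a.chain_id == chain_id]
        return a[a.atom_name == "CA"]

    def calpha_coords(self, chain_id: str | None = None) -> np.ndarray:
        return np.asarray(self.calpha(chain_id).coord, dtype=float)

    def heavy_coords(self) -> np.ndarray:
        return np.asarray(self.atoms.coord, dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with coordinates mapped to ``R @ x + t``."""
        new = self.atoms.copy()
        new.coord = self.atoms.coord @ np.asarray(rotation, float).T + np.asarray(
            translation, float
        )
        return Structure(new, source=self.source)


def _ensure_heavy(atoms: struc.AtomArray) -> struc.AtomArray:
    mask = atoms.element != "H"
    # deuterium, unlabeled hydrogens named like "1H.."
    mask &= atoms.element != "D"
    return atoms[mask]


def read_pdb(source) -> Structure:
    """Parse ATOM/HETATM records from a path, text or stream into a Structure.

    Keeps the highest-occupancy alternate conformer, drops hydrogens, and
    exposes Ca2+ HETATM records through :attr:`Structure.ions`.
    """
    name = ""
    if isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
    elif isinstance(source, (str, bytes)):
        handle = source
        name = str(source)
    else:
        handle = source
        name = getattr(source, "name", "")
    try:
        pdb = PDBFile.read(handle)
        atoms = pdb.get_structure(model=1, altloc="occupancy", extra_fields=["b_factor"])
    except Exception as exc:  # biotite raises various subclasses
        raise PDBFormatError(f"cannot parse PDB input {name!r}: {exc}") from exc
    atoms = _ensure_heavy(atoms)
    if atoms.array_length() == 0:
        raise PDBFormatError(f"PDB input {name!r} contains no heavy atoms")
    return Structure(atoms, source=name)


def write_pdb(structure: Structure, target) -> None:
    """Write the structure as standard ATOM/HETATM records."""
    pdb = PDBFile()
    pdb.set_structure(structure.atoms)
    pdb.write(target)


def pdb_string(structure: Structure) -> str:
    buf = io.StringIO()
    write_pdb(structure, buf)
    return buf.getvalue()


def select_residues(s: Structure, r: ResidueRange, keep_ions: bool = True) -> Structure:
    """Restrict one chain to an inclusive residue-number range.

    Other chains are dropped.  Ions are retained when ``keep_ions`` (they sit
    in the selected chain's coordination sphere in the crystal forms used
    here); set False to strip them.
    """
    if r.chain_id not in s.chain_ids:
        raise SelectionError(
            f"chain {r.chain_id!r} not present (have {s.chain_ids})"
        )
    a = s.atoms
    in_chain = a.chain_id == r.chain_id
    in_range = (a.res_id >= r.first) & (a.res_id <= r.last)
    mask = in_chain & in_range & ~s.is_ion_mask()
    if keep_ions:
        mask |= s.is_ion_mask()
    if not np.any(mask & in_chain & in_range):
        raise SelectionError(
            f"selection {r.chain_id}:{r.first}..{r.last} is empty"
        )
    return Structure(a[mask], source=s.source)


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of paired point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ mobile_i + translation`` best matches ``reference_i``.
    The rotation is proper (det = +1).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError(f"shape mismatch: {mob.shape} vs {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 points, got {n}")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # degenerate (collinear) inputs leave the rotation under-determined
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    rmsd = float(rssd / np.sqrt(n))
    return R, t, rmsd


def _paired_calpha(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Cα coordinates paired by (chain, residue number, insertion code)."""

    def index(s: Structure) -> dict[tuple[str, int, str], np.ndarray]:
        ca = s.calpha()
        return {
            (str(c), int(r), str(i)): np.asarray(xyz, float)
            for c, r, i, xyz in zip(ca.chain_id, ca.res_id, ca.ins_code, ca.coord)
        }

    ia, ib = index(a), index(b)
    common = [k for k in ia if k in ib]
    if len(common) < len(ia) or len(common) < len(ib):
        # fall back to residue-number pairing when chain ids differ between
        # entries (the two crystal forms label their chains differently)
        def index_nochain(s: Structure):
            ca = s.calpha()
            out = {}
            for r, i, xyz in zip(ca.res_id, ca.ins_code, ca.coord):
                out.setdefault((int(r), str(i)), np.asarray(xyz, float))
            return out

        if len({k[0] for k in ia}) == 1 and len({k[0] for k in ib}) == 1:
            ia2, ib2 = index_nochain(a), index_nochain(b)
            common2 = [k for k in ia2 if k in ib2]
            if len(common2) > len(common):
                return (
                    np.array([ia2[k] for k in common2]),
                    np.array([ib2[k] for k in common2]),
                )
    return np.array([ia[k] for k in common]), np.array([ib[k] for k in common])


def paired_calpha_rmsd(a: Structure, b: Structure) -> float:
    """RMSD of residue-number-paired Cα atoms after optimal superposition.

    Pairing is by residue number and insertion code (not residue name), so
    point mutants pair with their wild-type counterparts.
    """
    ca, cb = _paired_calpha(a, b)
    if len(ca) < 3:
        raise ValueError(f"only {len(ca)} common Cα pairs; need >= 3")
    _, _, rmsd = kabsch_superpose(ca, cb)
    return rmsd
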