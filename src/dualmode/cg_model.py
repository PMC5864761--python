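"""Structure-based Cα coarse-grained Hamiltonian with analytic forces.

One bead per residue, centred on the Cα atom (plus one bead per bound Ca2+
ion).  The energy has four terms, in internal units (energy ε, length Å):

* harmonic bonds between sequence neighbours, V = (k_bond/2)(r - r_nat)²
  with k_bond = 100 ε/Å²;
* native contacts, V = 4ε[(σ_ij/r)¹² - (σ_ij/r)⁶] with σ_ij chosen so the
  minimum sits at the native distance;
* non-native pairs, the truncated-and-shifted repulsive LJ with
  σ = r0/2^(1/6), r0 = 4 Å (zero beyond r0);
* a local-chirality harmonic per bead quadruplet,
  V = (κ/2)(C_i - C_i^nat)², C_i = [(v_i × v_{i+1}) · v_{i+2}] / d0³,
  favouring the native handedness of each chain.

The reference energy scale is ε ≈ 110 pN·Å; the time unit τ (~1 ns) and a
uniform bead mass m complete the unit system used by the dynamics driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contact_map import ContactMap
from .structure_io import Structure

#: conversion of the contact-depth energy unit to pN·Å
EPSILON_PN_ANGSTROM = 110.0
#: 1 kcal/mol in pN·Å (for reporting energies in kcal/mol)
KCAL_PER_MOL_PN_ANGSTROM = 69.5


@dataclass(frozen=True)
class CGParameters:
    """Model constants, all in internal units (ε, Å, τ, m)."""

    epsilon: float = 1.0
    k_bond: float = 100.0  # ε/Å²
    r0_repulsive: float = 4.0  # Å
    chirality_strength: float = 1.0  # ε
    mass: float = 1.0
    gamma: float = 2.0  # m/τ
    dt: float = 0.005  # τ

    def __post_init__(self) -> None:
        for name in ("epsilon", "k_bond", "r0_repulsive", "mass", "gamma", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sigma_repulsive(self) -> float:
        return self.r0_repulsive / 2 ** (1 / 6)


@dataclass
class CGTopology:
    """Full specification of the Hamiltonian for one system.

    ``bonds`` are (i, i+1) bead pairs with native lengths; ``contacts`` the
    native pairs with per-pair sigma; every remaining pair is non-native
    (purely repulsive).  Ion beads join only through their native contacts.
    """

    positions: np.ndarray  # native coordinates, (N, 3)
    chain_of: np.ndarray  # chain index per bead; -1 for ion beads
    bonds: np.ndarray  # (n_bonds, 2) int
    bond_lengths: np.ndarray
    contacts: np.ndarray  # (n_contacts, 2) int
    contact_sigma: np.ndarray
    contact_class: list[str]
    chirality_quads: np.ndarray  # (n_quads, 4) int
    chirality_native: np.ndarray
    params: CGParameters = field(default_factory=CGParameters)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def _pair_key(self, i: int, j: int) -> tuple[int, int]:
        return (min(i, j), max(i, j))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self._excluded = {self._pair_key(*b) for b in np.atleast_2d(self.bonds)} if len(
            self.bonds
        ) else set()
        self._excluded |= {self._pair_key(*c) for c in np.atleast_2d(self.contacts)} if len(
            self.contacts
        ) else set()
        # static non-native pair list (all pairs minus bonded minus native)
        n = self.n_beads
        ii, jj = np.triu_indices(n, k=1)
        keep = np.array(
            [(int(a), int(b)) not in self._excluded for a, b in zip(ii, jj)]
        )
        self.nonnative_pairs = np.stack([ii[keep], jj[keep]], axis=1) if keep.any() else np.zeros((0, 2), int)

    def interface_contact_indices(self) -> np.ndarray:
        return np.array(
            [k for k, c in enumerate(self.contact_class) if c == "interface"], int
        )

    def nonlocal_contact_indices(self, min_sep: int = 5) -> np.ndarray:
        """Contacts with |i - j| > 4 in sequence (or cross-chain/ion)."""
        out = []
        for k, (i, j) in enumerate(np.atleast_2d(self.contacts)):
            same = self.chain_of[i] == self.chain_of[j] and self.chain_of[i] >= 0
            if not same or abs(int(i) - int(j)) >= min_sep:
                out.append(k)
        return np.array(out, int)


class ChainBreakError(ValueError):
    """Sequence neighbours too far apart to be bonded."""


def build_topology(
    s: Structure,
    cmap: ContactMap,
    params: CGParameters | None = None,
    max_bond_length: float = 4.5,
    allow_breaks: bool = False,
) -> CGTopology:
    """Assemble the coarse-grained topology from a structure and its map.

    Beads follow the contact map's bead list (residue Cαs then ions); bonds
    tether sequence neighbours within each chain at their native lengths.
    """
    params = params or CGParameters()
    beads = cmap.beads
    positions = np.array([b.position for b in beads])
    chain_labels = sorted({b.chain_id for b in beads if not b.is_ion})
    chain_index = {c: k for k, c in enumerate(chain_labels)}
    chain_of = np.array(
        [-1 if b.is_ion else chain_index[b.chain_id] for b in beads], int
    )

    bonds, lengths = [], []
    for i in range(len(beads) - 1):
        a, b = beads[i], beads[i + 1]
        if a.is_ion or b.is_ion or a.chain_id != b.chain_id:
            continue
        d = float(np.linalg.norm(positions[i + 1] - positions[i]))
        if d > max_bond_length and not allow_breaks:
            raise ChainBreakError(
                f"Cα-Cα distance {d:.2f} Å between {a.chain_id}:{a.res_id} and "
                f"{b.chain_id}:{b.res_id} exceeds {max_bond_length} Å"
            )
        bonds.append((i, i + 1))
        lengths.append(d)

    quads, crefs = [], []
    for i in range(len(beads) - 3):
        group = beads[i : i + 4]
        if any(b.is_ion for b in group):
            continue
        if len({b.chain_id for b in group}) != 1:
            continue
        quads.append((i, i + 1, i + 2, i + 3))
        crefs.append(_chirality_value(positions[i : i + 4]))

    contacts = np.array([(c.i, c.j) for c in cmap.contacts], int).reshape(-1, 2)
    sigma = np.array([c.sigma for c in cmap.contacts])
    classes = [c.contact_class for c in cmap.contacts]
    return CGTopology(
        positions=positions,
        chain_of=chain_of,
        bonds=np.array(bonds, int).reshape(-1, 2),
        bond_lengths=np.array(lengths),
        contacts=contacts,
        contact_sigma=sigma,
        contact_class=classes,
        chirality_quads=np.array(quads, int).reshape(-1, 4),
        chirality_native=np.array(crefs),
        params=params,
    )


# ---------------------------------------------------------------------------
# potential terms


def native_lj_energy(r, sigma, epsilon: float = 1.0):
    """12-6 Lennard-Jones value and radial force magnitude (-dV/dr)."""
    r = np.asarray(r, float)
    s6 = (sigma / r) ** 6
    V = 4 * epsilon * (s6 * s6 - s6)
    dVdr = 4 * epsilon * (-12 * s6 * s6 + 6 * s6) / r
    return V, -dVdr


def repulsive_energy(r, params: CGParameters | None = None):
    """Truncated-and-shifted repulsive LJ: zero at and beyond r0."""
    params = params or CGParameters()
    r = np.asarray(r, float)
    sigma = params.sigma_repulsive
    s6 = (sigma / r) ** 6
    V = np.where(r < params.r0_repulsive, 4 * params.epsilon * (s6 * s6 - s6) + params.epsilon, 0.0)
    dVdr = np.where(
        r < params.r0_repulsive,
        4 * params.epsilon * (-12 * s6 * s6 + 6 * s6) / r,
        0.0,
    )
    return V, -dVdr


def _chirality_value(x4: np.ndarray) -> float:
    """C = [(v1 × v2) · v3] / d0³ with d0 the native bond length (3.8 Å)."""
    v1, v2, v3 = x4[1] - x4[0], x4[2] - x4[1], x4[3] - x4[2]
    d0 = 3.8
    return float(np.dot(np.cross(v1, v2), v3) / d0**3)


def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # np.cross carries axis-normalisation overhead that dominates small systems
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _row_norms(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", a, a))


def _chirality_values(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    q = np.atleast_2d(quads)
    v1 = coords[q[:, 1]] - coords[q[:, 0]]
    v2 = coords[q[:, 2]] - coords[q[:, 1]]
    v3 = coords[q[:, 3]] - coords[q[:, 2]]
    return np.einsum("ij,ij->i", _cross_rows(v1, v2), v3) / 3.8**3


def chirality_energy(
    coords: np.ndarray,
    quads: np.ndarray,
    references: np.ndarray,
    strength: float = 1.0,
) -> float:
    if len(np.atleast_2d(quads)) == 0 or np.asarray(quads).size == 0:
        return 0.0
    c = _chirality_values(coords, quads)
    return float(np.sum(0.5 * strength * (c - np.asarray(references)) ** 2))


@dataclass(frozen=True)
class EnergyReport:
    bond: float
    native: float
    repulsive: float
    chirality: float

    @property
    def total(self) -> float:
        return self.bond + self.native + self.repulsive + self.chirality


def total_energy(top: CGTopology, coords: np.ndarray) -> EnergyReport:
    """Energy decomposition at the given coordinates (ε units)."""
    p = top.params
    coords = np.asarray(coords, float)

    e_bond = 0.0
    if len(top.bonds):
        d = np.linalg.norm(coords[top.bonds[:, 1]] - coords[top.bonds[:, 0]], axis=1)
        e_bond = float(np.sum(0.5 * p.k_bond * (d - top.bond_lengths) ** 2))

    e_nat = 0.0
    if len(top.contacts):
        d = np.linalg.norm(coords[top.contacts[:, 1]] - coords[top.contacts[:, 0]], axis=1)
        V, _ = native_lj_energy(d, top.contact_sigma, p.epsilon)
        e_nat = float(np.sum(V))

    e_rep = 0.0
    if len(top.nonnative_pairs):
        d = np.linalg.norm(
            coords[top.nonnative_pairs[:, 1]] - coords[top.nonnative_pairs[:, 0]], axis=1
        )
        V, _ = repulsive_energy(d, p)
        e_rep = float(np.sum(V))

    e_chi = chirality_energy(
        coords, top.chirality_quads, top.chirality_native, p.chirality_strength
    )
    return EnergyReport(bond=e_bond, native=e_nat, repulsive=e_rep, chirality=e_chi)


def total_force(top: CGTopology, coords: np.ndarray) -> np.ndarray:
    """Analytic force (negative gradient of the total energy) per bead."""
    p = top.params
    coords = np.asarray(coords, float)
    F = np.zeros_like(coords)

    def pair_accumulate(pairs, f_mag, rij, d):
        # f_mag is the radial force magnitude (-dV/dr); force on j is along +rij
        fvec = (f_mag / d)[:, None] * rij
        np.add.at(F, pairs[:, 1], fvec)
        np.add.at(F, pairs[:, 0], -fvec)

    if len(top.bonds):
        rij = coords[top.bonds[:, 1]] - coords[top.bonds[:, 0]]
        d = _row_norms(rij)
        if d.min() < 0.1:
            raise ValueError("overlapping bonded beads (r < 0.1 Å)")
        f = -p.k_bond * (d - top.bond_lengths)
        pair_accumulate(top.bonds, f, rij, d)

    if len(top.contacts):
        rij = coords[top.contacts[:, 1]] - coords[top.contacts[:, 0]]
        d = _row_norms(rij)
        if d.min() < 0.1:
            raise ValueError("overlapping contact beads (r < 0.1 Å)")
        _, f = native_lj_energy(d, top.contact_sigma, p.epsilon)
        pair_accumulate(top.contacts, f, rij, d)

    if len(top.nonnative_pairs):
        rij = coords[top.nonnative_pairs[:, 1]] - coords[top.nonnative_pairs[:, 0]]
        d = _row_norms(rij)
        if d.min() < 0.1:
            raise ValueError("overlapping beads (r < 0.1 Å)")
        _, f = repulsive_energy(d, p)
        pair_accumulate(top.nonnative_pairs, f, rij, d)

    if len(top.chirality_quads):
        F += _chirality_force(
            coords, top.chirality_quads, top.chirality_native, p.chirality_strength
        )
    return F


def _chirality_force(coords, quads, references, strength) -> np.ndarray:
    """Analytic gradient of the chirality term.

    With T = (v1 × v2) · v3:  dT/dv1 = v2 × v3, dT/dv2 = v3 × v1,
    dT/dv3 = v1 × v2; bead gradients follow from v_k = r_{k+1} - r_k.
    """
    F = np.zeros_like(coords)
    q = np.atleast_2d(quads)
    if len(q) == 0:
        return F
    d03 = 3.8**3
    v1 = coords[q[:, 1]] - coords[q[:, 0]]
    v2 = coords[q[:, 2]] - coords[q[:, 1]]
    v3 = coords[q[:, 3]] - coords[q[:, 2]]
    g3 = _cross_rows(v1, v2)
    c = np.einsum("ij,ij->i", g3, v3) / d03
    pref = (strength * (c - np.asarray(references)) / d03)[:, None]
    g1 = _cross_rows(v2, v3)
    g2 = _cross_rows(v3, v1)
    # dE/dr_bead = pref * dT/dr_bead; force is the negative
    np.add.at(F, q[:, 0], pref * g1)
    np.add.at(F, q[:, 1], -pref * (g1 - g2))
    np.add.at(F, q[:, 2], -pref * (g2 - g3))
    np.add.at(F, q[:, 3], -pref * g3)
    return F


def native_contact_distances(top: CGTopology, coords: np.ndarray) -> np.ndarray:
    return np.linalg.norm(
        coords[top.contacts[:, 1]] - coords[top.contacts[:, 0]], axis=1
    )


def contacts_present(
    top: CGTopology, coords: np.ndarray, cutoff_factor: float = 1.5
) -> np.ndarray:
    """Boolean per-contact presence: r_ij < cutoff_factor * sigma_ij."""
    if not len(top.contacts):
        return np.zeros(0, bool)
    return native_contact_distances(top, coords) < cutoff_factor * top.contact_sigma
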