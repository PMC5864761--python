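"""Seed-deterministic generators for every input class the pipeline consumes.

Real inputs to this analysis are crystal structures and free-energy grids
produced by an external side-chain-repacking energy backend.  The generators
here emulate both at toy scale with fully known ground truth:

* two-basin ΔG(Z, phi) landscapes with configurable minima, widths and
  per-replica jitter, plus a manifest carrying the analytic minima and the
  dense-quadrature mode-probability ratio;
* ideal α-helical chains decorated with a fixed alanine-like heavy-atom
  template (N, Cα, C, O, Cβ), sufficient to exercise the overlap criterion
  and the coarse-grained protocols;
* two-helix "complexes" with a planned interface for pose scans and pulling;
* structure pairs related by a known axial rotation for the symmetry-axis
  recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import biotite.structure as struc
from scipy.spatial.transform import Rotation

from .landscape_stats import KB_KCAL, MODE_I, MODE_II, EnergyLandscape
from .structure_io import Structure


# ---------------------------------------------------------------------------
# landscapes


@dataclass(frozen=True)
class BasinSpec:
    """One Gaussian basin of the (Z, phi) landscape."""

    z0: float  # Å
    phi0: float  # degrees
    depth: float  # kcal/mol, negative
    width_z: float = 1.5  # Å
    width_phi: float = 15.0  # degrees
    baseline: float = 0.0  # kcal/mol

    def __post_init__(self) -> None:
        if self.depth >= self.baseline:
            raise ValueError("basin depth must lie below the baseline")
        if self.width_z <= 0 or self.width_phi <= 0:
            raise ValueError("widths must be positive")


@dataclass(frozen=True)
class LandscapeSpec:
    basins: tuple[BasinSpec, ...]
    replicas: int = 1
    jitter: float = 1.0  # kcal/mol of per-replica additive Gaussian noise
    seed: int = 0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.basins or self.replicas < 1:
            raise ValueError("need >= 1 basin and >= 1 replica")


#: emulates the wild-type tailless system: minima at phi = 3 and 173 deg with
#: depths -38.2 and -28.7 kcal/mol (the deepest replica of each mode)
DEFAULT_BASINS = (
    BasinSpec(z0=0.0, phi0=3.0, depth=-38.2, width_z=1.5, width_phi=20.0),
    BasinSpec(z0=0.0, phi0=173.0, depth=-28.7, width_z=1.2, width_phi=12.0),
)


def _circular_delta(phi: np.ndarray, phi0: float) -> np.ndarray:
    return (phi - phi0 + 180.0) % 360.0 - 180.0


def landscape_function(spec: LandscapeSpec):
    """The analytic ΔG(z, phi) (no jitter), vectorised; kcal/mol."""

    def fn(z, phi):
        z = np.asarray(z, float)
        phi = np.asarray(phi, float)
        dG = np.full(np.broadcast(z, phi).shape, spec.baseline, float)
        for b in spec.basins:
            dphi = _circular_delta(phi, b.phi0)
            dG = dG + (b.depth - b.baseline) * np.exp(
                -((z - b.z0) ** 2) / (2 * b.width_z**2)
                - dphi**2 / (2 * b.width_phi**2)
            )
        return dG

    return fn


def _quadrature_ratio(spec: LandscapeSpec, T: float, n_z=801, n_phi=3600) -> float:
    """Dense-grid Boltzmann ratio p_I/p_II of the analytic landscape."""
    fn = landscape_function(spec)
    z = np.linspace(-8, 8, n_z)
    phi = np.linspace(-180, 180, n_phi, endpoint=False)
    dG = fn(z[:, None], phi[None, :])
    beta = 1.0 / (KB_KCAL * T)
    w = np.exp(-beta * (dG - dG.min()))
    in_I = MODE_I.contains(phi)[None, :]
    in_II = MODE_II.contains(phi)[None, :]
    return float(w[np.broadcast_to(in_I, w.shape)].sum() / w[np.broadcast_to(in_II, w.shape)].sum())


def make_landscape(
    spec: LandscapeSpec,
    z_values: np.ndarray | None = None,
    phi_values: np.ndarray | None = None,
    T: float = 298.0,
) -> tuple[list[EnergyLandscape], dict]:
    """Generate per-replica landscapes plus a ground-truth manifest.

    The manifest records each basin, the analytic minima per mode, and the
    dense-quadrature mode-probability ratio of the jitter-free landscape at
    temperature ``T``.
    """
    if z_values is None:
        z_values = np.arange(-5.0, 5.0 + 1e-9, 0.5)
    if phi_values is None:
        phi_values = np.arange(-180.0, 180.0, 2.0)
    z_values = np.asarray(z_values, float)
    phi_values = np.asarray(phi_values, float)
    fn = landscape_function(spec)
    base = fn(z_values[:, None], phi_values[None, :])
    rng = np.random.default_rng(spec.seed)
    landscapes = []
    for k in range(spec.replicas):
        noise = rng.normal(0.0, spec.jitter, base.shape) if spec.jitter > 0 else 0.0
        landscapes.append(
            EnergyLandscape(
                k=k + 1,
                z_values=z_values,
                phi_values=phi_values,
                values=base + noise,
            )
        )
    manifest = {
        "basins": [asdict(b) for b in spec.basins],
        "replicas": spec.replicas,
        "jitter": spec.jitter,
        "seed": spec.seed,
        "true_minima": {
            ("I" if bool(MODE_I.contains(b.phi0)) else "II"): {
                "z": b.z0, "phi": b.phi0, "dG": b.depth,
            }
            for b in sorted(spec.basins, key=lambda b: b.depth, reverse=True)
        },
        "quadrature_ratio_I_over_II": _quadrature_ratio(spec, T),
        "T": T,
    }
    return landscapes, manifest


# ---------------------------------------------------------------------------
# toy structures

# alanine-like heavy-atom template in a local residue frame (Å):
# offsets applied relative to the Cα position, oriented along the chain
_RESIDUE_TEMPLATE = {
    "N": np.array([-1.20, 0.60, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.25, 0.60, 0.00]),
    "O": np.array([1.30, 1.80, 0.20]),
    "CB": np.array([-0.10, -1.00, 1.10]),
}
_TEMPLATE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å


def _helix_calpha_trace(n: int) -> np.ndarray:
    idx = np.arange(n)
    theta = np.radians(HELIX_TWIST * idx)
    return np.stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * idx],
        axis=1,
    )


def _decorate(
    ca: np.ndarray,
    chain_id: str = "A",
    res_start: int = 1,
    res_name: str = "ALA",
) -> struc.AtomArray:
    """Attach the heavy-atom template to each Cα using a local chain frame."""
    n = len(ca)
    atoms = []
    for i in range(n):
        # local frame: x along chain direction, z away from the helix axis
        nxt = ca[min(i + 1, n - 1)] - ca[max(i - 1, 0)]
        ex = nxt / np.linalg.norm(nxt)
        radial = ca[i] - np.array([0.0, 0.0, ca[i][2]])
        if np.linalg.norm(radial) < 1e-6:
            radial = np.array([1.0, 0.0, 0.0])
        ez = radial - (radial @ ex) * ex
        ez /= np.linalg.norm(ez)
        ey = np.cross(ez, ex)
        R = np.stack([ex, ey, ez], axis=1)
        for name, offset in _RESIDUE_TEMPLATE.items():
            atoms.append((chain_id, res_start + i, res_name, name,
                          _TEMPLATE_ELEMENTS[name], ca[i] + R @ offset))
    arr = struc.AtomArray(len(atoms))
    arr.chain_id = np.array([a[0] for a in atoms])
    arr.res_id = np.array([a[1] for a in atoms])
    arr.ins_code = np.array([""] * len(atoms))
    arr.res_name = np.array([a[2] for a in atoms])
    arr.atom_name = np.array([a[3] for a in atoms])
    arr.element = np.array([a[4] for a in atoms])
    arr.hetero = np.zeros(len(atoms), bool)
    arr.coord = np.array([a[5] for a in atoms], dtype=np.float32)
    return arr


def make_helix(n: int, chain_id: str = "A", res_start: int = 1) -> Structure:
    """Ideal right-handed α-helix with backbone heavy atoms.

    Rise 1.5 Å, twist 100 deg, radius 2.3 Å, giving consecutive Cα-Cα
    distances of ~3.8 Å.
    """
    if n < 4:
        raise ValueError("need n >= 4 residues")
    return Structure(_decorate(_helix_calpha_trace(n), chain_id, res_start))


def make_hairpin(n_per_arm: int = 8, gap: float = 5.0, chain_id: str = "A") -> Structure:
    """Two antiparallel extended strands joined by a turn (toy hairpin).

    Small enough for fast unfolding runs yet holding several nonlocal
    contacts across the strand-strand interface.
    """
    if n_per_arm < 3:
        raise ValueError("need >= 3 residues per arm")
    spacing = 3.8
    up = np.stack(
        [np.zeros(n_per_arm), np.zeros(n_per_arm), spacing * np.arange(n_per_arm)],
        axis=1,
    )
    turn = np.array([[gap / 2, 1.5, spacing * (n_per_arm - 1) + 2.2]])
    down = np.stack(
        [
            np.full(n_per_arm, gap),
            np.zeros(n_per_arm),
            spacing * np.arange(n_per_arm - 1, -1, -1),
        ],
        axis=1,
    )
    ca = np.concatenate([up, turn, down])
    return Structure(_decorate(ca, chain_id))


@dataclass(frozen=True)
class ComplexSpec:
    n_residues_a: int = 12
    n_residues_b: int = 10
    separation: float = 9.0  # Å between helix axes
    seed: int = 0


def make_two_body_complex(spec: ComplexSpec | None = None) -> tuple[Structure, dict]:
    """Two parallel helices docked side by side; stands in for a two-chain
    complex in pose scans and pulling.

    The manifest lists the helix extents and the axis separation; interface
    contacts follow from the overlap criterion at build time.
    """
    spec = spec or ComplexSpec()
    a = _decorate(_helix_calpha_trace(spec.n_residues_a), "A", 1)
    cb = _helix_calpha_trace(spec.n_residues_b) + np.array([spec.separation, 0.0, 1.0])
    b = _decorate(cb, "B", 1)
    both = a + b
    manifest = {
        "chains": {"A": spec.n_residues_a, "B": spec.n_residues_b},
        "separation": spec.separation,
        "seed": spec.seed,
    }
    return Structure(both), manifest


def make_rotated_pair(
    base: Structure,
    axis: np.ndarray,
    angle_deg: float,
    noise: float = 0.0,
    origin: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[Structure, Structure, dict]:
    """Copy of ``base`` rotated about ``axis`` (through ``origin``) by
    ``angle_deg``, with optional coordinate noise; ground truth returned."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    if origin is None:
        origin = base.heavy_coords().mean(axis=0)
    origin = np.asarray(origin, float)
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    rotated = base.transformed(R, origin - R @ origin)
    if noise > 0:
        rng = np.random.default_rng(seed)
        arr = rotated.atoms.copy()
        arr.coord = arr.coord + rng.normal(0, noise, arr.coord.shape).astype(np.float32)
        rotated = Structure(arr)
    truth = {"axis": axis.tolist(), "angle_deg": float(angle_deg),
             "origin": origin.tolist(), "noise": noise, "seed": seed}
    return base, rotated, truth
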