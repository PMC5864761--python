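"""Symmetry axis between the two binding modes and rigid (Z, phi) posing.

The two cohesin-dockerin binding modes are related by a ~180 deg rotation of
the dockerin about an axis fixed in the cohesin frame.  With the cohesins of
the two crystal forms superposed, vectors joining equivalent helix Cα atoms
of the two dockerin poses all lie (ideally) in planes perpendicular to that
axis.  The axis is found by iteratively rotating the coordinate system so
that the axial components of those difference vectors vanish; a rotation
angle phi about the axis and a shift Z along it then parametrise rigid poses
of the dockerin, with sterically clashing poses masked out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure_io import Structure, kabsch_superpose

#: dockerin helix residue ranges (inclusive)
HELIX_RANGES: dict[str, tuple[int, int]] = {
    "alpha1'": (11, 23),
    "alpha2'": (28, 36),
    "alpha3'": (45, 56),
}

#: helices used for the symmetry-axis derivation (the two that couple to the
#: cohesin in both modes)
AXIS_HELICES = ("alpha1'", "alpha3'")

DEFAULT_MIN_DIST = 2.0  # Å, heavy-atom steric clash threshold


class ConvergenceError(RuntimeError):
    """Axis iteration failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SymmetryFrame:
    """Orthonormal frame whose third row is the symmetry (Z) axis."""

    origin: np.ndarray
    axes: np.ndarray  # rows are x, y, z unit vectors

    def __post_init__(self) -> None:
        A = np.asarray(self.axes, float)
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-8):
            raise ValueError("frame rows are not orthonormal")
        if np.linalg.det(A) < 0:
            raise ValueError("frame is left-handed")

    @property
    def z_axis(self) -> np.ndarray:
        return np.asarray(self.axes, float)[2]


@dataclass(frozen=True)
class RigidPose:
    """A rigid pose: rotation ``phi`` (degrees) about Z then shift along +Z (Å).

    Positive ``z_shift`` moves the dockerin toward the cohesin (frame
    orientation is chosen accordingly at derivation time).
    """

    z_shift: float
    phi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.z_shift) and np.isfinite(self.phi)):
            raise ValueError("non-finite pose")
        object.__setattr__(self, "phi", wrap_angle(self.phi))


def wrap_angle(phi: float) -> float:
    """Wrap an angle in degrees into [-180, 180)."""
    return float((phi + 180.0) % 360.0 - 180.0)


@dataclass
class PoseGrid:
    z_values: np.ndarray
    phi_values: np.ndarray
    allowed: np.ndarray  # shape (len(z), len(phi))

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, float)
        self.phi_values = np.asarray(self.phi_values, float)
        if np.any(np.diff(self.z_values) <= 0) or np.any(np.diff(self.phi_values) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if self.allowed.shape != (len(self.z_values), len(self.phi_values)):
            raise ValueError("mask shape does not match grid")

    @property
    def allowed_fraction(self) -> float:
        return float(np.mean(self.allowed))


def _helix_calpha(doc: Structure, helices=AXIS_HELICES) -> tuple[list[int], np.ndarray]:
    """Residue numbers and Cα coordinates of the requested dockerin helices."""
    ca = doc.calpha()
    ids = np.array([int(r) for r in ca.res_id])
    keep = np.zeros(len(ids), bool)
    for name in helices:
        lo, hi = HELIX_RANGES[name]
        keep |= (ids >= lo) & (ids <= hi)
    return [int(i) for i in ids[keep]], np.asarray(ca.coord, float)[keep]


def difference_vectors(
    doc_a: Structure, doc_b: Structure, helices=AXIS_HELICES
) -> np.ndarray:
    """Vectors from mode-I to mode-II positions of equivalent helix Cα atoms.

    Both dockerins must already be expressed in the frame in which the
    cohesins are superposed.
    """
    ids_a, xa = _helix_calpha(doc_a, helices)
    ids_b, xb = _helix_calpha(doc_b, helices)
    map_a = dict(zip(ids_a, xa))
    map_b = dict(zip(ids_b, xb))
    expected: list[int] = []
    for name in helices:
        lo, hi = HELIX_RANGES[name]
        expected.extend(range(lo, hi + 1))
    missing = [i for i in expected if i not in map_a or i not in map_b]
    common = [i for i in expected if i in map_a and i in map_b]
    if missing and not common:
        raise ValueError(f"helix residues missing from both inputs: {missing}")
    if missing:
        raise ValueError(f"helix residues missing: {missing}")
    return np.array([map_b[i] - map_a[i] for i in common])


def _pair_centroid(doc_a: Structure, doc_b: Structure, helices=AXIS_HELICES) -> np.ndarray:
    _, xa = _helix_calpha(doc_a, helices)
    _, xb = _helix_calpha(doc_b, helices)
    return (xa.mean(axis=0) + xb.mean(axis=0)) / 2.0


def find_symmetry_axis(
    vectors: np.ndarray,
    origin: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> SymmetryFrame:
    """Frame whose Z-axis minimises the squared axial components of ``vectors``.

    Each iteration solves the linearised least-squares problem for the small
    rotation of the current frame that reduces the summed squared
    Z-components, applies it exactly, and repeats until the residual change
    drops below ``tol`` (Å²).
    """
    v = np.asarray(vectors, float)
    v = v[np.linalg.norm(v, axis=1) > 1e-12]
    if len(v) < 3:
        raise ValueError(f"need >= 3 non-zero vectors, got {len(v)}")
    axes = np.eye(3)
    prev = np.inf
    for _ in range(max_iter):
        w = v @ axes.T  # vectors in current frame
        residual = float(np.sum(w[:, 2] ** 2))
        if prev - residual < tol:
            return SymmetryFrame(
                origin=np.zeros(3) if origin is None else np.asarray(origin, float),
                axes=axes,
            )
        prev = residual
        # small rotation (wx, wy) about the in-plane axes changes
        # z-components linearly: z' ≈ z + wx*y - wy*x
        A = np.stack([w[:, 1], -w[:, 0]], axis=1)
        b = -w[:, 2]
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        wx, wy = sol
        R = Rotation.from_rotvec([wx, wy, 0.0]).as_matrix()
        axes = R @ axes
    raise ConvergenceError(
        f"axis iteration did not converge in {max_iter} steps", residual=prev
    )


def derive_frame(
    coh_ref: Structure,
    doc_a: Structure,
    doc_b: Structure,
    helices=AXIS_HELICES,
) -> SymmetryFrame:
    """Symmetry frame from two dockerin poses in the cohesin-superposed frame.

    The origin is the centroid of the paired helix Cα atoms (midpoint of the
    two modes); +Z is oriented toward the cohesin centroid so that positive
    Z-shifts move the dockerin toward the cohesin.
    """
    vecs = difference_vectors(doc_a, doc_b, helices)
    origin = _pair_centroid(doc_a, doc_b, helices)
    frame = find_symmetry_axis(vecs, origin=origin)
    toward = coh_ref.heavy_coords().mean(axis=0) - origin
    if float(frame.z_axis @ toward) < 0:
        # flip z (and x, to stay right-handed)
        axes = np.array([-frame.axes[0], frame.axes[1], -frame.axes[2]])
        frame = SymmetryFrame(origin=origin, axes=axes)
    return frame


def mode_rotation_angle(
    doc_a: Structure, doc_b: Structure, frame: SymmetryFrame, helices=AXIS_HELICES
) -> float:
    """Angle about the frame Z-axis best mapping doc_a helix Cαs onto doc_b.

    Least-squares over the in-plane components; returned in [0, 360).
    """
    ids_a, xa = _helix_calpha(doc_a, helices)
    ids_b, xb = _helix_calpha(doc_b, helices)
    common = [i for i in ids_a if i in set(ids_b)]
    pa = np.array([xa[ids_a.index(i)] for i in common]) - frame.origin
    pb = np.array([xb[ids_b.index(i)] for i in common]) - frame.origin
    ax, ay = pa @ frame.axes[0], pa @ frame.axes[1]
    bx, by = pb @ frame.axes[0], pb @ frame.axes[1]
    norm = np.hypot(ax, ay) * np.hypot(bx, by)
    if np.all(norm < 1e-9):
        raise ValueError("all points lie on the axis; angle undefined")
    # optimal in-plane rotation: atan2(sum cross, sum dot)
    cross = float(np.sum(ax * by - ay * bx))
    dot = float(np.sum(ax * bx + ay * by))
    ang = np.degrees(np.arctan2(cross, dot))
    return float(ang % 360.0)


def pose_matrix(frame: SymmetryFrame, pose: RigidPose) -> tuple[np.ndarray, np.ndarray]:
    """Rotation and translation implementing a pose: rotate about Z through
    the frame origin by phi, then translate along +Z by z_shift."""
    z = frame.z_axis
    R = Rotation.from_rotvec(np.radians(pose.phi) * z).as_matrix()
    t = frame.origin - R @ frame.origin + pose.z_shift * z
    return R, t


def apply_pose(doc: Structure, frame: SymmetryFrame, pose: RigidPose) -> Structure:
    """Rigidly transform the dockerin into the requested (Z, phi) pose."""
    R, t = pose_matrix(frame, pose)
    return doc.transformed(R, t)


def steric_allowed(
    coh: Structure, doc_posed: Structure, min_dist: float = DEFAULT_MIN_DIST
) -> bool:
    """True iff no inter-molecular heavy-atom pair is closer than ``min_dist``."""
    xa = coh.heavy_coords()
    xb = doc_posed.heavy_coords()
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("empty structure")
    tree = cKDTree(xa)
    d, _ = tree.query(xb, k=1, distance_upper_bound=min_dist)
    return bool(np.all(np.isinf(d)))


def generate_pose_grid(
    coh: Structure,
    doc: Structure,
    frame: SymmetryFrame,
    z_values=None,
    phi_values=None,
    min_dist: float = DEFAULT_MIN_DIST,
) -> PoseGrid:
    """Scan the (Z, phi) grid and record which poses are sterically allowed.

    Defaults: Z in [-10, 4] Å step 0.5; phi in [-180, 180) step 2 deg.
    """
    if z_values is None:
        z_values = np.arange(-10.0, 4.0 + 1e-9, 0.5)
    if phi_values is None:
        phi_values = np.arange(-180.0, 180.0, 2.0)
    z_values = np.asarray(z_values, float)
    phi_values = np.asarray(phi_values, float)
    if len(z_values) == 0 or len(phi_values) == 0:
        raise ValueError("empty pose grid")
    allowed = np.zeros((len(z_values), len(phi_values)), bool)
    for j, phi in enumerate(phi_values):
        rotated = apply_pose(doc, frame, RigidPose(0.0, float(phi)))
        for i, z in enumerate(z_values):
            posed = rotated.transformed(np.eye(3), z * frame.z_axis)
            allowed[i, j] = steric_allowed(coh, posed, min_dist)
    return PoseGrid(z_values=z_values, phi_values=phi_values, allowed=allowed)
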