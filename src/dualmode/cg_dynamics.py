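"""Langevin dynamics driver and the three simulation protocols.

The beads obey  m r'' = F - γ r' + Γ  with uniform mass m, damping
γ = 2 m/τ (practically overdamped), and Gaussian thermal noise of standard
deviation sqrt(2 γ k_B T / dt) per force component and step.  The equations
are integrated with a fifth-order Gear predictor-corrector at dt = 0.005 τ
(a Langevin velocity-Verlet variant is available for cross-validation).

Protocols built on the driver:

* equilibrium thermal stability — P0, the probability that every native
  contact is simultaneously present, and Q, the mean fraction of native
  contacts, as functions of temperature;
* thermal unfolding — the median time t_u for all nonlocal (|i-j| > 4)
  contacts to be simultaneously broken at elevated temperature;
* AFM-like constant-speed pulling — harmonic springs on the two N-termini,
  one anchor fixed and one moving at v_p, with window-averaged
  force-extension curves, per-contact last-break displacements and a
  long/short trajectory classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .cg_model import (
    CGTopology,
    contacts_present,
    native_contact_distances,
    total_energy,
    total_force,
)

BREAK_FACTOR = 1.5  # contact broken when r_ij > 1.5 sigma_ij

# Gear 5th-order corrector coefficients for second-order ODEs with
# velocity-dependent forces
_GEAR_ALPHA = np.array([3 / 16, 251 / 360, 1.0, 11 / 18, 1 / 6, 1 / 60])
_PASCAL = np.array(
    [
        [1, 1, 1, 1, 1, 1],
        [0, 1, 2, 3, 4, 5],
        [0, 0, 1, 3, 6, 10],
        [0, 0, 0, 1, 4, 10],
        [0, 0, 0, 0, 1, 5],
        [0, 0, 0, 0, 0, 1],
    ],
    float,
)


class NumericalBlowupError(RuntimeError):
    def __init__(self, step: int):
        super().__init__(f"coordinate exceeded 1e6 Å at step {step}")
        self.step = step


@dataclass(frozen=True)
class LangevinSettings:
    """Integration settings in internal units (ε, Å, τ, m)."""

    temperature: float  # ε/k_B
    gamma: float = 2.0
    dt: float = 0.005
    seed: int = 0
    steps: int = 10_000
    equilibration_steps: int = 0
    sample_stride: int = 100
    integrator: str = "gear5"  # or "verlet"

    def __post_init__(self) -> None:
        if self.temperature < 0 or self.dt <= 0:
            raise ValueError("require T >= 0 and dt > 0")


@dataclass
class Trajectory:
    times: np.ndarray  # τ units
    positions: np.ndarray  # (n_frames, n_beads, 3)
    velocities: np.ndarray | None = None


class _GearState:
    """Scaled Taylor derivatives y_k = (dt^k / k!) d^k r / dt^k."""

    def __init__(self, x0: np.ndarray, v0: np.ndarray, a0: np.ndarray, dt: float):
        n = x0.shape
        self.dt = dt
        self.y = np.zeros((6,) + n)
        self.y[0] = x0
        self.y[1] = v0 * dt
        self.y[2] = a0 * dt**2 / 2

    @property
    def x(self) -> np.ndarray:
        return self.y[0]

    @property
    def v(self) -> np.ndarray:
        return self.y[1] / self.dt

    def predict(self) -> None:
        self.y = np.einsum("ij,j...->i...", _PASCAL, self.y)

    def correct(self, a: np.ndarray) -> None:
        delta = a * self.dt**2 / 2 - self.y[2]
        for k in range(6):
            self.y[k] += _GEAR_ALPHA[k] * delta


def _make_force_fn(top: CGTopology, extra=None) -> Callable:
    if extra is None:
        return lambda x, t: total_force(top, x)
    return lambda x, t: total_force(top, x) + extra(x, t)


def integrate(
    top: CGTopology,
    settings: LangevinSettings,
    coords0: np.ndarray | None = None,
    extra_force: Callable | None = None,
    observer: Callable | None = None,
    mass: float = 1.0,
) -> Trajectory:
    """Run Langevin dynamics and return sampled frames.

    ``extra_force(x, t)`` adds a time-dependent external force (used by the
    pulling protocol); ``observer(step, t, x, v)`` is called at each sampled
    frame and may return True to stop early.  Bit-reproducible for a fixed
    seed.
    """
    rng = np.random.default_rng(settings.seed)
    x = np.array(top.positions if coords0 is None else coords0, float)
    v = np.zeros_like(x)
    dt = settings.dt
    gamma = settings.gamma
    noise_std = np.sqrt(2 * gamma * settings.temperature / dt)
    force_fn = _make_force_fn(top, extra_force)

    times, frames, vels = [], [], []
    total_steps = settings.equilibration_steps + settings.steps

    def sample(step, t, x, v):
        if step >= settings.equilibration_steps:
            times.append(t)
            frames.append(x.copy())
            vels.append(v.copy())
            if observer is not None:
                return bool(observer(step, t, x, v))
        return False

    if settings.integrator == "gear5":
        def accel(x, v, t):
            gam = rng.standard_normal(x.shape) * noise_std if noise_std > 0 else 0.0
            return (force_fn(x, t) - gamma * v + gam) / mass

        state = _GearState(x, v, accel(x, v, 0.0), dt)
        for step in range(1, total_steps + 1):
            state.predict()
            t = step * dt
            a = accel(state.x, state.v, t)
            state.correct(a)
            if np.any(np.abs(state.x) > 1e6):
                raise NumericalBlowupError(step)
            if step % settings.sample_stride == 0:
                if sample(step, t, state.x, state.v):
                    break
    elif settings.integrator == "verlet":
        # Langevin velocity Verlet (BAOAB splitting)
        if gamma > 0:
            c1 = np.exp(-gamma * dt / mass)
            c2 = np.sqrt(max(settings.temperature, 0.0) * (1 - c1**2) / mass)
        else:
            c1, c2 = 1.0, 0.0
        F = force_fn(x, 0.0)
        for step in range(1, total_steps + 1):
            t = step * dt
            v = v + 0.5 * dt * F / mass
            x = x + 0.5 * dt * v
            v = c1 * v + c2 * rng.standard_normal(x.shape)
            x = x + 0.5 * dt * v
            F = force_fn(x, t)
            v = v + 0.5 * dt * F / mass
            if np.any(np.abs(x) > 1e6):
                raise NumericalBlowupError(step)
            if step % settings.sample_stride == 0:
                if sample(step, t, x, v):
                    break
    else:
        raise ValueError(f"unknown integrator {settings.integrator!r}")

    return Trajectory(
        times=np.array(times),
        positions=np.array(frames) if frames else np.zeros((0,) + x.shape),
        velocities=np.array(vels) if vels else None,
    )


# ---------------------------------------------------------------------------
# thermal stability


@dataclass
class ThermalStabilityResult:
    temperatures: np.ndarray
    P0: np.ndarray
    Q: np.ndarray
    n_trajectories: int

    @property
    def T0(self) -> float:
        """Temperature at which P0 crosses 1/2 (linear interpolation)."""
        P = np.asarray(self.P0)
        T = np.asarray(self.temperatures)
        above = P >= 0.5
        if above.all() or not above.any():
            return float("nan")
        i = int(np.max(np.flatnonzero(above)))
        if i + 1 >= len(T):
            return float(T[i])
        p1, p2 = P[i], P[i + 1]
        return float(T[i] + (p1 - 0.5) / (p1 - p2) * (T[i + 1] - T[i]))


def native_state_stats(
    top: CGTopology,
    temperatures: Sequence[float],
    n_traj: int = 21,
    settings: LangevinSettings | None = None,
) -> ThermalStabilityResult:
    """Equilibrium P0 and Q over a temperature scan.

    A contact counts as present when r_ij < 1.5 sigma_ij (the same cutoff
    used for breaking during pulling).  Frames are pooled across time and
    trajectories.
    """
    if n_traj < 1:
        raise ValueError("n_traj >= 1")
    base = settings or LangevinSettings(temperature=0.0)
    P0, Q = [], []
    for T in temperatures:
        all_present, frac = [], []
        for it in range(n_traj):
            st = replace(base, temperature=float(T), seed=base.seed + 1000 * it + int(1e4 * T))
            traj = integrate(top, st)
            for x in traj.positions:
                pres = contacts_present(top, x, BREAK_FACTOR)
                all_present.append(bool(pres.all()))
                frac.append(float(pres.mean()))
        P0.append(float(np.mean(all_present)))
        Q.append(float(np.mean(frac)))
    return ThermalStabilityResult(
        temperatures=np.asarray(temperatures, float),
        P0=np.array(P0),
        Q=np.array(Q),
        n_trajectories=n_traj,
    )


# ---------------------------------------------------------------------------
# thermal unfolding


@dataclass
class UnfoldingResult:
    temperatures: np.ndarray
    times: list[np.ndarray]  # per T, per-trajectory t_unf (inf if censored)

    @property
    def t_u(self) -> np.ndarray:
        """Median unfolding time per temperature (inf when <50% unfolded)."""
        return np.array([float(np.median(t)) for t in self.times])

    @property
    def unfolded_fraction(self) -> np.ndarray:
        return np.array([float(np.mean(np.isfinite(t))) for t in self.times])


def unfolding_times(
    top: CGTopology,
    temperatures: Sequence[float],
    n_traj: int = 21,
    settings: LangevinSettings | None = None,
) -> UnfoldingResult:
    """Time for all nonlocal (|i-j| > 4) native contacts to be broken at once.

    Trajectories that never unfold within the step budget contribute +inf
    (censoring); the median is well-defined when more than half unfold.
    """
    base = settings or LangevinSettings(temperature=1.0, sample_stride=50)
    nonlocal_idx = top.nonlocal_contact_indices()
    times_per_T: list[np.ndarray] = []
    for T in temperatures:
        t_unf = []
        for it in range(n_traj):
            if len(nonlocal_idx) == 0:
                t_unf.append(0.0)
                continue
            st = replace(base, temperature=float(T), seed=base.seed + 7000 * it + int(1e4 * T))
            hit = {"t": np.inf}

            def observer(step, t, x, v):
                d = native_contact_distances(top, x)[nonlocal_idx]
                if np.all(d > BREAK_FACTOR * top.contact_sigma[nonlocal_idx]):
                    hit["t"] = t
                    return True
                return False

            integrate(top, st, observer=observer)
            t_unf.append(hit["t"])
        times_per_T.append(np.array(t_unf))
    return UnfoldingResult(temperatures=np.asarray(temperatures, float), times=times_per_T)


# ---------------------------------------------------------------------------
# pulling


@dataclass(frozen=True)
class PullingSettings:
    """AFM-like stretching parameters (internal units)."""

    spring_constant: float = 0.12  # ε/Å²
    speed: float = 5e-5  # Å/τ
    fixed_bead: int = 0
    pulled_bead: int = 1
    window: float = 0.5  # Å of spring displacement per force-average window
    max_displacement: float = 200.0  # Å
    dissociation_margin: float = 1.0  # Å of sustained full interface breakage

    def __post_init__(self) -> None:
        if self.fixed_bead == self.pulled_bead:
            raise ValueError("springs attached to the same bead")


class BreakTracker:
    """Tracks per-contact last-break displacements.

    A contact may break, re-form under thermal fluctuations, and break again;
    only the displacement of its *last* break is retained.
    """

    def __init__(self, initial_present: np.ndarray):
        self.was_present = np.array(initial_present, bool)
        self.last_break: dict[int, float] = {}

    def update(self, present: np.ndarray, displacement: float) -> None:
        newly_broken = self.was_present & ~np.asarray(present, bool)
        for idx in np.flatnonzero(newly_broken):
            self.last_break[int(idx)] = float(displacement)
        self.was_present[:] = present


@dataclass
class ForceExtensionCurve:
    displacement: np.ndarray  # window centres, Å
    force: np.ndarray  # window-averaged spring force, ε/Å
    last_break: dict[int, float]  # contact index -> last-break displacement
    dissociation_d: float  # Å (nan if never dissociated)
    complete: bool

    @property
    def f_max(self) -> float:
        return float(np.max(self.force)) if len(self.force) else float("nan")


def pull(
    top: CGTopology,
    pulling: PullingSettings | None = None,
    langevin: LangevinSettings | None = None,
) -> ForceExtensionCurve:
    """Constant-speed pulling from the native state.

    One spring anchors the fixed bead at its native position; the other
    anchor moves at ``speed`` along the initial fixed->pulled direction.
    The tension on the moving spring is averaged per 0.5 Å of anchor travel;
    contact breaking (r > 1.5 sigma, re-formation allowed) is logged by the
    displacement of its last break.  Dissociation is declared once every
    interface contact stays broken for a sustained margin of displacement.
    """
    pulling = pulling or PullingSettings()
    langevin = langevin or LangevinSettings(temperature=0.3, sample_stride=200)
    x0 = top.positions
    anchor_fixed = x0[pulling.fixed_bead].copy()
    anchor0 = x0[pulling.pulled_bead].copy()
    direction = anchor0 - anchor_fixed
    nrm = np.linalg.norm(direction)
    if nrm < 1e-9:
        raise ValueError("attachment beads coincide")
    direction = direction / nrm
    K, vp = pulling.spring_constant, pulling.speed

    def extra_force(x, t):
        F = np.zeros_like(x)
        F[pulling.fixed_bead] += K * (anchor_fixed - x[pulling.fixed_bead])
        moving = anchor0 + vp * t * direction
        F[pulling.pulled_bead] += K * (moving - x[pulling.pulled_bead])
        return F

    interface = top.interface_contact_indices()
    sigma = top.contact_sigma
    state = {
        "win_lo": 0.0,
        "f_sum": 0.0,
        "f_n": 0,
        "diss_d": np.nan,
        "diss_candidate": np.nan,
    }
    d_centres: list[float] = []
    f_means: list[float] = []
    tracker = BreakTracker(contacts_present(top, x0, BREAK_FACTOR))

    total_time = pulling.max_displacement / vp
    steps = int(total_time / langevin.dt)

    def observer(step, t, x, v):
        d = vp * t
        moving = anchor0 + vp * t * direction
        tension = K * float((moving - x[pulling.pulled_bead]) @ direction)
        state["f_sum"] += tension
        state["f_n"] += 1
        if d - state["win_lo"] >= pulling.window:
            d_centres.append(state["win_lo"] + pulling.window / 2)
            f_means.append(state["f_sum"] / max(state["f_n"], 1))
            state["win_lo"] = d
            state["f_sum"], state["f_n"] = 0.0, 0
        pres = contacts_present(top, x, BREAK_FACTOR)
        tracker.update(pres, d)
        if len(interface):
            if not pres[interface].any():
                if np.isnan(state["diss_candidate"]):
                    state["diss_candidate"] = d
                elif d - state["diss_candidate"] >= pulling.dissociation_margin:
                    state["diss_d"] = state["diss_candidate"]
                    return True
            else:
                state["diss_candidate"] = np.nan
        return False

    st = replace(langevin, steps=steps, equilibration_steps=0)
    integrate(top, st, extra_force=extra_force, observer=observer)
    return ForceExtensionCurve(
        displacement=np.array(d_centres),
        force=np.array(f_means),
        last_break=tracker.last_break,
        dissociation_d=float(state["diss_d"]),
        # the run either dissociated or exhausted the displacement limit
        complete=True,
    )


def classify_trajectory(curve: ForceExtensionCurve, threshold_d: float) -> str:
    """'long' iff the final dissociation displacement reaches ``threshold_d``."""
    if not curve.complete:
        raise ValueError("cannot classify an incomplete curve")
    d = curve.dissociation_d
    if np.isnan(d):
        d = float(curve.displacement[-1]) if len(curve.displacement) else 0.0
    return "long" if d >= threshold_d else "short"


def default_threshold(dissociation_ds: np.ndarray) -> float:
    """Midpoint between the two modes of a 1-D two-cluster split.

    Chooses the split minimising within-cluster variance (exact 1-D
    2-means over sorted values), then returns the midpoint between the
    cluster means.
    """
    x = np.sort(np.asarray(dissociation_ds, float))
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return float(x[0]) if len(x) else 0.0
    best, best_cost = 1, np.inf
    for split in range(1, len(x)):
        a, b = x[:split], x[split:]
        cost = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
        if cost < best_cost:
            best, best_cost = split, cost
    return float((x[:best].mean() + x[best:].mean()) / 2)


@dataclass
class ScenarioReport:
    n_total: int
    n_long: int
    fraction_long: float
    ci_low: float
    ci_high: float
    threshold_d: float
    median_last_break: dict[str, float]  # contact-class label -> displacement


def scenario_report(
    curves: Sequence[ForceExtensionCurve],
    top: CGTopology,
    threshold_d: float | None = None,
    class_labels: dict[int, str] | None = None,
    confidence: float = 0.95,
) -> ScenarioReport:
    """Long/short fractions with a binomial CI and break-order medians.

    ``class_labels`` maps contact indices to named groups (defaults to the
    topology's contact classes).
    """
    if not curves:
        raise ValueError("need at least one curve")
    diss = np.array(
        [
            c.dissociation_d
            if np.isfinite(c.dissociation_d)
            else (c.displacement[-1] if len(c.displacement) else 0.0)
            for c in curves
        ]
    )
    if threshold_d is None:
        threshold_d = default_threshold(diss)
    labels = [classify_trajectory(c, threshold_d) for c in curves]
    n = len(curves)
    n_long = sum(1 for l in labels if l == "long")
    from scipy.stats import binomtest

    ci = binomtest(n_long, n).proportion_ci(confidence_level=confidence)

    if class_labels is None:
        class_labels = {i: cls for i, cls in enumerate(top.contact_class)}
    per_class: dict[str, list[float]] = {}
    for c in curves:
        for idx, d in c.last_break.items():
            per_class.setdefault(class_labels.get(idx, "other"), []).append(d)
    medians = {k: float(np.median(v)) for k, v in sorted(per_class.items())}
    return ScenarioReport(
        n_total=n,
        n_long=n_long,
        fraction_long=n_long / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        threshold_d=float(threshold_d),
        median_last_break=medians,
    )
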