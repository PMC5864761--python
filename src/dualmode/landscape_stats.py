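"""Boltzmann aggregation of per-pose free energies into binding-mode statistics.

A scan of the rigid-body coordinates (Z, phi) with an external energy backend
yields, for each input structure replica ``k``, a grid of free energies
ΔG_k(Z, phi) in kcal/mol.  The free energy of binding in a mode is the
Boltzmann aggregate over every structure, shift and in-mode angle whose ΔG
lies below a cutoff E_c,

    F_mode = -k_B T log( sum_k sum_Z sum_{phi in mode}
                         exp(-ΔG_k(Z, phi) / k_B T) [ΔG_k < E_c] ),

with mode I the angular interval (-90, 90) deg and mode II its complement
(90, 270) deg, boundaries excluded.  F saturates once E_c clears the basin
shoulders, and the ratio of mode probabilities follows from the saturated
values: p_I / p_II = exp[-(F_I - F_II) / k_B T].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: Boltzmann constant in kcal / (mol K)
KB_KCAL = 1.9872e-3

LANDSCAPE_COLUMNS = ["k", "z", "phi", "dG"]


class EmptyModeError(ValueError):
    """No grid cell of the mode passes the energy cutoff."""


@dataclass(frozen=True)
class ModeDefinition:
    """Angular interval (degrees, exclusive bounds) defining a binding mode."""

    name: str
    phi_min: float
    phi_max: float

    def contains(self, phi) -> np.ndarray:
        """Membership of angles (degrees, any wrap) with exclusive bounds."""
        p = np.asarray(phi, float)
        # wrap into [phi_min, phi_min + 360)
        w = (p - self.phi_min) % 360.0 + self.phi_min
        return (w > self.phi_min) & (w < self.phi_max)


MODE_I = ModeDefinition("I", -90.0, 90.0)
MODE_II = ModeDefinition("II", 90.0, 270.0)
MODES = {"I": MODE_I, "II": MODE_II}


@dataclass
class EnergyLandscape:
    """Grid of ΔG(Z, phi) (kcal/mol) for one structure replica ``k``.

    ``values`` has shape (len(z), len(phi)); forbidden/missing cells are NaN
    or masked out by ``allowed``.
    """

    k: int
    z_values: np.ndarray
    phi_values: np.ndarray
    values: np.ndarray
    allowed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, float)
        self.phi_values = np.asarray(self.phi_values, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.z_values) <= 0) or np.any(np.diff(self.phi_values) <= 0):
            raise ValueError("landscape axes must be strictly increasing")
        if self.values.shape != (len(self.z_values), len(self.phi_values)):
            raise ValueError("values shape does not match axes")
        if self.allowed is None:
            self.allowed = ~np.isnan(self.values)
        else:
            self.allowed = np.asarray(self.allowed, bool) & ~np.isnan(self.values)
        if not np.all(np.isfinite(self.values[self.allowed])):
            raise ValueError("non-finite ΔG on allowed cells")

    def mode_mask(self, mode: ModeDefinition) -> np.ndarray:
        return self.allowed & mode.contains(self.phi_values)[None, :]


@dataclass(frozen=True)
class BindingFreeEnergies:
    F_I: float
    F_II: float
    E_c: float
    T: float
    k_set: tuple[int, ...]


@dataclass(frozen=True)
class ModeProbabilities:
    p_I: float
    p_II: float
    ratio: float


@dataclass(frozen=True)
class MinimumReport:
    mode: str
    dG_min: float
    z: float
    phi: float


# ---------------------------------------------------------------------------
# I/O


def read_landscape(source) -> list[EnergyLandscape]:
    """Read landscapes from TSV with columns k, z, phi, dG [, allowed]."""
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in LANDSCAPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landscape table missing columns {missing}")
    if df[LANDSCAPE_COLUMNS[:3]].duplicated().any():
        dup = df[df[LANDSCAPE_COLUMNS[:3]].duplicated()].iloc[0]
        raise ValueError(
            f"duplicate (k, z, phi) row: ({dup.k}, {dup.z}, {dup.phi})"
        )
    if not np.all(np.isfinite(df["dG"].to_numpy(float))):
        raise ValueError("non-numeric or non-finite dG values")
    out = []
    for k, grp in df.groupby("k", sort=True):
        z_values = np.unique(grp["z"].to_numpy(float))
        phi_values = np.unique(grp["phi"].to_numpy(float))
        values = np.full((len(z_values), len(phi_values)), np.nan)
        allowed = np.zeros_like(values, dtype=bool)
        iz = np.searchsorted(z_values, grp["z"].to_numpy(float))
        ip = np.searchsorted(phi_values, grp["phi"].to_numpy(float))
        values[iz, ip] = grp["dG"].to_numpy(float)
        if "allowed" in grp.columns:
            allowed[iz, ip] = grp["allowed"].to_numpy(bool)
        else:
            allowed[iz, ip] = True
        out.append(
            EnergyLandscape(
                k=int(k), z_values=z_values, phi_values=phi_values,
                values=values, allowed=allowed,
            )
        )
    return out


def write_landscape(landscapes: Iterable[EnergyLandscape], target) -> None:
    rows = []
    for ls in landscapes:
        for i, z in enumerate(ls.z_values):
            for j, phi in enumerate(ls.phi_values):
                if np.isnan(ls.values[i, j]):
                    continue
                rows.append(
                    {"k": ls.k, "z": z, "phi": phi, "dG": ls.values[i, j],
                     "allowed": bool(ls.allowed[i, j])}
                )
    pd.DataFrame(rows, columns=LANDSCAPE_COLUMNS + ["allowed"]).to_csv(
        target, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Aggregation


def _collect_energies(
    landscapes: Sequence[EnergyLandscape], mode: ModeDefinition, E_c: float
) -> np.ndarray:
    vals = []
    for ls in landscapes:
        m = ls.mode_mask(mode) & (ls.values < E_c)
        vals.append(ls.values[m])
    return np.concatenate(vals) if vals else np.array([])


def mode_free_energy(
    landscapes: Sequence[EnergyLandscape],
    mode: ModeDefinition,
    E_c: float,
    T: float,
) -> float:
    """Boltzmann free energy of one binding mode (kcal/mol).

    Overflow-safe via log-sum-exp even for deeply negative ΔG/k_B T.
    """
    dG = _collect_energies(landscapes, mode, E_c)
    if dG.size == 0:
        raise EmptyModeError(
            f"no allowed cell of mode {mode.name} below E_c = {E_c} kcal/mol"
        )
    beta = 1.0 / (KB_KCAL * T)
    return float(-logsumexp(-beta * dG) / beta)


def binding_free_energies(
    landscapes: Sequence[EnergyLandscape], E_c: float, T: float
) -> BindingFreeEnergies:
    return BindingFreeEnergies(
        F_I=mode_free_energy(landscapes, MODE_I, E_c, T),
        F_II=mode_free_energy(landscapes, MODE_II, E_c, T),
        E_c=E_c,
        T=T,
        k_set=tuple(sorted(ls.k for ls in landscapes)),
    )


def saturation_scan(
    landscapes: Sequence[EnergyLandscape],
    mode: ModeDefinition,
    E_c_values: Sequence[float],
    T: float,
    plateau_tol: float = 0.05,
    plateau_window: float = 5.0,
) -> pd.DataFrame:
    """F(E_c) curve plus plateau detection.

    Returns a DataFrame (E_c, F) where F is NaN below the first populated
    cutoff.  ``attrs['plateau_onset']`` holds the smallest E_c beyond which
    |ΔF| stays below ``plateau_tol`` kcal/mol over a ``plateau_window``
    kcal/mol window; ``attrs['saturation']`` is F at the largest E_c.
    """
    E_c_values = np.sort(np.asarray(E_c_values, float))
    if E_c_values.size == 0:
        raise ValueError("empty E_c grid")
    F = np.full(len(E_c_values), np.nan)
    for i, ec in enumerate(E_c_values):
        try:
            F[i] = mode_free_energy(landscapes, mode, ec, T)
        except EmptyModeError:
            pass
    df = pd.DataFrame({"E_c": E_c_values, "F": F})
    # plateau onset: smallest cutoff from which F stays within plateau_tol of
    # its end-of-scan value (F is monotone in E_c, so this is the earliest
    # point after which the curve is flat to tolerance)
    onset = np.nan
    finite = np.isfinite(F)
    if finite.any():
        F_sat = F[finite][-1]
        flat = finite & (np.abs(F - F_sat) < plateau_tol)
        # require flatness for every scanned cutoff from onset onward
        ok = np.flatnonzero(flat & (np.cumsum((~flat & finite)[::-1])[::-1] == 0))
        if len(ok):
            onset = float(E_c_values[ok[0]])
    df.attrs["plateau_onset"] = onset
    df.attrs["saturation"] = float(F[finite][-1]) if finite.any() else np.nan
    return df


def probability_ratio(F_I: float, F_II: float, T: float) -> ModeProbabilities:
    """Mode probabilities from the two binding free energies.

    ratio = p_I/p_II = exp[-(F_I - F_II)/k_B T], with p_I + p_II = 1.
    """
    if not (np.isfinite(F_I) and np.isfinite(F_II) and T > 0):
        raise ValueError("F_I, F_II must be finite and T > 0")
    x = -(F_I - F_II) / (KB_KCAL * T)
    ratio = float(np.exp(x))
    # p_I = ratio / (1 + ratio), computed stably on either tail
    if x > 0:
        p_I = 1.0 / (1.0 + np.exp(-x))
    else:
        p_I = ratio / (1.0 + ratio)
    return ModeProbabilities(p_I=float(p_I), p_II=float(1.0 - p_I), ratio=ratio)


def minimum_report(landscape: EnergyLandscape, mode: ModeDefinition) -> MinimumReport:
    """Minimum ΔG and its (z, phi) location over the mode's allowed cells."""
    m = landscape.mode_mask(mode)
    if not m.any():
        raise EmptyModeError(f"mode {mode.name} region is empty")
    vals = np.where(m, landscape.values, np.inf)
    i, j = np.unravel_index(int(np.argmin(vals)), vals.shape)
    return MinimumReport(
        mode=mode.name,
        dG_min=float(landscape.values[i, j]),
        z=float(landscape.z_values[i]),
        phi=float(landscape.phi_values[j]),
    )


def round_to_one_significant_figure(x: float) -> float:
    """Round as the field reports order-of-magnitude probability ratios."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    exp = int(np.floor(np.log10(abs(x))))
    return float(round(x, -exp))
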