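"""End-to-end runs composing the analysis stages, with provenance manifests.

Two entry points: the dual-binding landscape analysis (axis -> pose scan ->
landscape aggregation -> mode probabilities) and the coarse-grained
mechanics suite (thermal stability, unfolding, pulling ensemble).  All
randomness flows from a single root seed through per-stage derived seeds
recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import __version__
from . import landscape_stats as ls
from . import synthetic_data as synth
from .cg_dynamics import (
    LangevinSettings,
    PullingSettings,
    native_state_stats,
    pull,
    scenario_report,
    unfolding_times,
)
from .cg_model import CGParameters, build_topology
from .contact_map import native_contacts


def derive_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stage_outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config, "outputs": self.stage_outputs},
            indent=2, sort_keys=True, default=_jsonify,
        )


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def run_dual_binding_analysis(
    landscapes: Sequence[ls.EnergyLandscape],
    temperatures: Sequence[float] = (298.0, 308.0),
    E_c_values: Sequence[float] | None = None,
    config: dict | None = None,
) -> RunManifest:
    """Aggregate landscapes into per-temperature mode statistics.

    For each temperature: the F(E_c) saturation scans for both modes, the
    saturated F_I/F_II, and the mode probabilities from their difference.
    """
    if E_c_values is None:
        E_c_values = np.arange(-45.0, -5.0 + 1e-9, 0.5)
    manifest = RunManifest(config=dict(config or {}))
    out: dict[str, Any] = {"k_set": sorted({l.k for l in landscapes})}
    for T in temperatures:
        scan_I = ls.saturation_scan(landscapes, ls.MODE_I, E_c_values, T)
        scan_II = ls.saturation_scan(landscapes, ls.MODE_II, E_c_values, T)
        F_I = scan_I.attrs["saturation"]
        F_II = scan_II.attrs["saturation"]
        for name, F in (("I", F_I), ("II", F_II)):
            if not np.isfinite(F):
                raise ls.EmptyModeError(
                    f"mode {name} has no state below any scanned cutoff at T={T:g}"
                )
        probs = ls.probability_ratio(F_I, F_II, T)
        out[f"T={T:g}"] = {
            "F_I": F_I,
            "F_II": F_II,
            "plateau_onset_I": scan_I.attrs["plateau_onset"],
            "plateau_onset_II": scan_II.attrs["plateau_onset"],
            "ratio": probs.ratio,
            "p_I": probs.p_I,
            "p_II": probs.p_II,
        }
    manifest.stage_outputs["dual_binding"] = out
    return manifest


def run_mechanics_suite(
    structure,
    thermal_temperatures: Sequence[float] = (0.1, 0.3, 0.6),
    unfolding_temperatures: Sequence[float] = (1.4, 1.8),
    n_thermal: int = 5,
    n_unfold: int = 5,
    n_pull: int = 4,
    seed: int = 0,
    steps: int = 20_000,
    max_pull_displacement: float = 60.0,
    pull_speed: float = 5e-5,
    config: dict | None = None,
) -> RunManifest:
    """Thermal stability, unfolding and pulling on one structure.

    Sizes default to quick-look scale; production scans raise the trajectory
    counts and step budgets through the keyword arguments.
    """
    cmap = native_contacts(structure)
    top = build_topology(structure, cmap, CGParameters())
    manifest = RunManifest(config=dict(config or {}))

    therm = native_state_stats(
        top, thermal_temperatures, n_traj=n_thermal,
        settings=LangevinSettings(
            temperature=0.0, seed=derive_seed(seed, "thermal"),
            steps=steps, equilibration_steps=steps // 10, sample_stride=200,
        ),
    )
    manifest.stage_outputs["thermal"] = {
        "T": list(therm.temperatures), "P0": list(therm.P0), "Q": list(therm.Q),
        "n_trajectories": therm.n_trajectories,
    }

    unf = unfolding_times(
        top, unfolding_temperatures, n_traj=n_unfold,
        settings=LangevinSettings(
            temperature=1.0, seed=derive_seed(seed, "unfold"),
            steps=steps * 2, sample_stride=50,
        ),
    )
    manifest.stage_outputs["unfolding"] = {
        "T": list(unf.temperatures),
        "t_u": list(unf.t_u),
        "unfolded_fraction": list(unf.unfolded_fraction),
    }

    chain_ids = [b.chain_id for b in cmap.beads if not b.is_ion]
    first_beads = {}
    for i, c in enumerate(chain_ids):
        first_beads.setdefault(c, i)
    beads = sorted(first_beads.values())
    if len(beads) >= 2:
        pulling = PullingSettings(
            fixed_bead=beads[0], pulled_bead=beads[1],
            speed=pull_speed,
            max_displacement=max_pull_displacement,
        )
        curves = [
            pull(top, pulling, LangevinSettings(
                temperature=0.3, seed=derive_seed(seed, f"pull{i}"), sample_stride=100,
            ))
            for i in range(n_pull)
        ]
        rep = scenario_report(curves, top)
        manifest.stage_outputs["pulling"] = {
            "n": rep.n_total, "fraction_long": rep.fraction_long,
            "ci": [rep.ci_low, rep.ci_high], "threshold_d": rep.threshold_d,
            "f_max": [c.f_max for c in curves],
            "median_last_break": rep.median_last_break,
        }
    return manifest
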