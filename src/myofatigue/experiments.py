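"""The in-silico experiments that attribute fatigue to recruitment decline
versus Pi/H+ accumulation.

Four computational experiments on top of the protocol simulator:

* recruitment scenarios — rerun the protocol with hypothetical constant
  recruitment profiles and ask how much of the force drop the decline in
  motor-unit recruitment explains;
* metabolite ramps — extend the finished protocol by six clamped cycles
  with Pi or H+ raised to 1-2x their end-of-exercise level;
* the Pi x H+ grid — a single fully activated cycle per concentration
  combination spanning start- to end-of-exercise levels, from which the
  individual and synergistic force attributions are read off the corners;
* state-fraction scans and the friction/ratchet force decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import STATE_NAMES, ph_to_h
from .parameters import ModelParameters
from .protocol import (
    ProtocolResult, ProtocolSpec, extend_protocol, init_cycle,
    resting_state_vector, simulate_cycle, simulate_protocol,
)
from .synthetic import make_iemg_profile

__all__ = [
    "ScenarioResult", "GridResult", "recruitment_scenarios",
    "metabolite_ramp", "pi_h_grid", "state_fraction_scan",
    "force_decomposition",
]


@dataclass
class ScenarioResult:
    forces: Dict[str, np.ndarray]          # per-cycle peak force per profile
    force_gap_N: float                     # constant-max vs observed, cycle 60
    recovery_fraction: float               # gap / total drop under observed
    results: Dict[str, ProtocolResult] = field(repr=False, default_factory=dict)


@dataclass
class GridResult:
    pi_values: np.ndarray
    h_values: np.ndarray
    force: np.ndarray                      # (n_pi, n_h) peak single-cycle force
    attributions: Dict[str, float]         # % reduction at the three corners

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.force, index=self.pi_values, columns=self.h_values)
        df.index.name = "Pi_mM"
        df.columns.name = "H_uM"
        return df


# --------------------------------------------------------------------- #

def recruitment_scenarios(
    p: ModelParameters,
    observed_iemg: Optional[Sequence[float]] = None,
    spec_kwargs: Optional[dict] = None,
) -> ScenarioResult:
    """Observed vs constant-maximal vs constant-submaximal recruitment.

    The recovery fraction is the cycle-60 force gap between the
    constant-maximal and observed runs, normalized by the total force drop
    under the observed profile.  Falls back to the linear 1.0 -> 0.7 decline
    when no measured profile is supplied.
    """
    if observed_iemg is None:
        observed_iemg = make_iemg_profile("linear-decline", 60)
    observed_iemg = np.asarray(observed_iemg, dtype=float)
    n = len(observed_iemg)
    kw = dict(store_trajectory=False)
    kw.update(spec_kwargs or {})

    profiles = {
        "observed": observed_iemg,
        "constant_max": np.full(n, float(observed_iemg[0])),
        "constant_submax": np.full(n, float(observed_iemg[-1])),
    }
    results = {
        label: simulate_protocol(ProtocolSpec(iemg=prof, **kw), p)
        for label, prof in profiles.items()
    }
    forces = {label: r.peak_forces for label, r in results.items()}
    gap = float(forces["constant_max"][-1] - forces["observed"][-1])
    drop = float(forces["observed"][0] - forces["observed"][-1])
    recovery = gap / drop if drop > 0 else float("nan")
    return ScenarioResult(forces=forces, force_gap_N=gap,
                          recovery_fraction=recovery, results=results)


def metabolite_ramp(
    p: ModelParameters,
    which: str,
    scales: Sequence[float] = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0),
    baseline: Optional[ProtocolResult] = None,
    extra_cycles: int = 6,
) -> pd.DataFrame:
    """Normalized force after six extra cycles with Pi or H+ elevated.

    For each scale in [1, 2], the finished 60-cycle protocol is continued
    for `extra_cycles` with the chosen metabolite clamped at scale x its
    end-of-exercise concentration (all other metabolite derivatives zeroed);
    the force at the final extended cycle is reported normalized by the
    cycle-60 force.
    """
    if which not in ("Pi", "H"):
        raise KeyError(f"metabolite must be 'Pi' or 'H', got {which!r}")
    scales = np.asarray(scales, dtype=float)
    if np.any((scales < 1.0) | (scales > 2.0)):
        raise ValueError("scales must lie within [1, 2]")
    if baseline is None:
        spec = ProtocolSpec(iemg=make_iemg_profile("linear-decline", 60),
                            store_trajectory=False)
        baseline = simulate_protocol(spec, p)
    f60 = float(baseline.peak_forces[-1])
    rows = []
    for s in scales:
        ext = extend_protocol(baseline, extra_cycles, clamp={which: float(s)})
        f_end = float(ext.peak_forces[-1])
        rows.append({"scale": s, "normalized_force": f_end / f60,
                     "force_N": f_end})
    return pd.DataFrame(rows)


def _single_cycle_force(
    p: ModelParameters,
    overrides: Dict[str, float],
    activation: float = 1.0,
    spec: Optional[ProtocolSpec] = None,
) -> Tuple[float, np.ndarray]:
    """One fully activated clamped cycle at given metabolite overrides."""
    spec = spec or ProtocolSpec(iemg=[activation], store_trajectory=False)
    y0 = init_cycle(1, resting_state_vector(p), activation, p)
    for name, value in overrides.items():
        y0[STATE_NAMES.index(name)] = value
    cyc = simulate_cycle(y0, p, spec, metabolites_frozen=True)
    return cyc.peak_force, cyc.end_state


def pi_h_grid(
    p: ModelParameters,
    n_grid: int = 100,
    pi_range: Optional[Tuple[float, float]] = None,
    h_range: Optional[Tuple[float, float]] = None,
    baseline: Optional[ProtocolResult] = None,
    activation: float = 1.0,
) -> GridResult:
    """Single-cycle force over a Pi x H+ grid spanning the exercise range.

    Unless given explicitly, the ranges run from the resting levels to the
    end-of-protocol maxima of a baseline simulation.  The corner
    attributions report the percent force reduction relative to the
    (resting Pi, resting H) corner when Pi alone, H alone, or both sit at
    their end-of-exercise maxima.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    if pi_range is None or h_range is None:
        if baseline is None:
            spec = ProtocolSpec(iemg=make_iemg_profile("linear-decline", 60),
                                store_trajectory=False)
            baseline = simulate_protocol(spec, p)
        met = baseline.end_metabolites()
        r = p.resting
        pi_range = pi_range or (r.Pi, float(met["Pi"].max()))
        h_range = h_range or (ph_to_h(r.pH), float(met["H"].max()))

    pi_values = np.linspace(*pi_range, n_grid)
    h_values = np.linspace(*h_range, n_grid)
    force = np.empty((n_grid, n_grid))
    spec = ProtocolSpec(iemg=[activation], store_trajectory=False)
    for i, pi in enumerate(pi_values):
        for j, h in enumerate(h_values):
            force[i, j], _ = _single_cycle_force(
                p, {"Pi": pi, "H": h}, activation, spec)

    f_base = force[0, 0]
    attributions = {
        "Pi_alone_pct": 100.0 * (1.0 - force[-1, 0] / f_base),
        "H_alone_pct": 100.0 * (1.0 - force[0, -1] / f_base),
        "combined_pct": 100.0 * (1.0 - force[-1, -1] / f_base),
    }
    return GridResult(pi_values, h_values, force, attributions)


def state_fraction_scan(
    p: ModelParameters,
    which: str,
    levels: Sequence[float],
    activation: float = 1.0,
) -> pd.DataFrame:
    """End-of-cycle cross-bridge state fractions vs clamped Pi or H+ level.

    One fully activated cycle per level, all other metabolites held at rest.
    """
    if which not in ("Pi", "H"):
        raise KeyError(f"metabolite must be 'Pi' or 'H', got {which!r}")
    spec = ProtocolSpec(iemg=[activation], store_trajectory=False)
    rows = []
    for level in np.asarray(levels, dtype=float):
        if level < 0:
            raise ValueError("metabolite levels must be non-negative")
        _, end = _single_cycle_force(p, {which: level}, activation, spec)
        rows.append({
            which: level,
            "P": end[0], "A1": end[1], "A2": end[2], "A3": end[3],
        })
    return pd.DataFrame(rows)


def force_decomposition(result: ProtocolResult) -> pd.DataFrame:
    """Time-resolved friction vs ratcheting force components.

    Returns the dense trajectory with both components [mN/mm^2], total
    contractile force and the ratchet share; the share is NaN wherever the
    total contractile force is zero (relaxation, empty pool).
    """
    p = result.params
    df = result.trajectory()
    friction = p.kstiff1 * (df["A2_1"] + df["A3_1"])
    ratchet = p.kstiff2 * p.delta_r * df["A3_0"]
    total = friction + ratchet
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, ratchet / total, np.nan)
    return pd.DataFrame({
        "time": df["time"],
        "friction_mN_mm2": friction,
        "ratchet_mN_mm2": ratchet,
        "contractile_mN_mm2": total,
        "ratchet_share": share,
    })
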