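"""Cycle-reset protocol: 60 maximal isometric contractions (3 s on, 2 s off)
with metabolite carryover between cycles.

Each cycle starts with the permissible-state fraction set to that cycle's
motor-unit recruitment (iEMG) value and the attached states emptied; the
metabolites continue from wherever the previous cycle left them, which is
what lets Pi and H+ accumulate over the five minutes.  During the 2-s
relaxation the cross-bridge states are held (no cycling) while the metabolic
recovery fluxes continue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from . import model as _m
from .model import STATE_NAMES, force_from_vector, h_to_ph
from .parameters import ModelParameters

__all__ = [
    "ProtocolSpec", "CycleResult", "ProtocolResult",
    "init_cycle", "simulate_cycle", "simulate_protocol", "extend_protocol",
    "resting_state_vector",
]

#: metabolite names accepted by the clamping interface
_CLAMPABLE = ("ATP", "ADP", "AMP", "PCr", "Cr", "Pi", "H")


@dataclass
class ProtocolSpec:
    """Timing and recruitment input for one exercise protocol."""

    iemg: Sequence[float]
    T_cyc: float = 5.0
    T_on: float = 3.0
    output_dt: float = 0.01
    rtol: float = 1e-8
    atol: float = 1e-10
    store_trajectory: bool = True

    def __post_init__(self) -> None:
        self.iemg = np.asarray(self.iemg, dtype=float)
        if self.iemg.ndim != 1 or len(self.iemg) == 0:
            raise ValueError("iemg must be a non-empty 1-D sequence")
        if np.any((self.iemg < 0) | (self.iemg > 1)):
            raise ValueError("all iEMG recruitment fractions must lie in [0, 1]")
        if not (0 < self.T_on <= self.T_cyc):
            raise ValueError("need 0 < T_on <= T_cyc")
        if self.output_dt <= 0:
            raise ValueError("output_dt must be positive")

    @property
    def n_cycles(self) -> int:
        return len(self.iemg)


@dataclass
class CycleResult:
    index: int                      # 1-based cycle index
    t_start: float
    peak_force: float               # N, maximum during the contraction phase
    mean_force: float               # N, contraction-phase mean
    end_state: np.ndarray           # full state at t_start + T_cyc
    mean_xb: Dict[str, float]       # contraction-phase mean occupancies
    times: Optional[np.ndarray] = None
    states: Optional[np.ndarray] = None   # (n_t, N_STATES)
    forces: Optional[np.ndarray] = None


@dataclass
class ProtocolResult:
    """Per-cycle summaries plus (optionally) dense trajectories."""

    spec: ProtocolSpec
    params: ModelParameters
    cycles: List[CycleResult] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def peak_forces(self) -> np.ndarray:
        return np.array([c.peak_force for c in self.cycles])

    @property
    def end_state(self) -> np.ndarray:
        return self.cycles[-1].end_state

    def end_metabolites(self) -> pd.DataFrame:
        """End-of-cycle metabolite pools, one row per cycle."""
        rows = []
        for c in self.cycles:
            met = dict(zip(STATE_NAMES[7:], c.end_state[7:]))
            met["pH"] = h_to_ph(met["H"])
            met["cycle"] = c.index
            met["t"] = c.t_start + self.spec.T_cyc
            rows.append(met)
        return pd.DataFrame(rows).set_index("cycle")

    def trajectory(self) -> pd.DataFrame:
        """Dense tidy trajectory (time, states, force, pH)."""
        if self.cycles and self.cycles[0].times is None:
            raise ValueError("protocol was run with store_trajectory=False")
        t = np.concatenate([c.times for c in self.cycles])
        y = np.vstack([c.states for c in self.cycles])
        f = np.concatenate([c.forces for c in self.cycles])
        df = pd.DataFrame(y, columns=list(STATE_NAMES))
        df.insert(0, "time", t)
        df["force_N"] = f
        with np.errstate(divide="ignore"):
            df["pH"] = 6.0 - np.log10(df["H"].to_numpy())
        return df

    def sample(self, column: str, t: float) -> float:
        """Linear interpolation of one trajectory column at time t [s]."""
        df = self.trajectory()
        return float(np.interp(t, df["time"].to_numpy(), df[column].to_numpy()))

    def to_tidy_csv(self, path) -> None:
        self.trajectory()[
            ["time", "force_N", "PCr", "Pi", "pH", "P", "A1_0", "A2_0", "A3_0"]
        ].rename(columns={"A1_0": "A1", "A2_0": "A2", "A3_0": "A3"}).to_csv(
            path, index=False
        )


# --------------------------------------------------------------------- #

def resting_state_vector(p: ModelParameters) -> np.ndarray:
    """Packed state at rest: empty cross-bridge pool, resting metabolites."""
    r = p.resting
    return np.array([
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
        r.ATP, r.ADP, r.AMP, r.PCr, r.Cr, r.Pi, _m.ph_to_h(r.pH),
    ])


def init_cycle(
    j: int,
    prev: Optional[np.ndarray],
    iemg_j: float,
    p: ModelParameters,
) -> np.ndarray:
    """State at the start of cycle j: P set to the recruitment fraction,
    attached states emptied, metabolites carried over (resting for j=1)."""
    if not (0.0 <= iemg_j <= 1.0):
        raise ValueError(f"iEMG fraction must lie in [0, 1], got {iemg_j!r}")
    base = resting_state_vector(p) if prev is None else np.array(prev, dtype=float)
    y0 = base.copy()
    y0[0] = iemg_j
    y0[1:7] = 0.0
    return y0


def _integrate_phase(y0, t0, t1, p, spec, xb_active, metabolites_frozen):
    # odeint (LSODA) carries far less per-call overhead than solve_ivp for
    # this small stiff system, which matters inside multistart fits
    n_pts = max(int(round((t1 - t0) / spec.output_dt)), 2) + 1
    t_eval = np.linspace(t0, t1, n_pts)
    y, info = odeint(
        _m._rhs, y0, t_eval,
        args=(p, xb_active, metabolites_frozen),
        rtol=spec.rtol, atol=spec.atol, tfirst=True, full_output=True,
        printmessg=False,
    )
    if info["message"] != "Integration successful.":
        raise RuntimeError(f"integrator failed on [{t0}, {t1}]: {info['message']}")
    if not np.all(np.isfinite(y[-1])):
        raise RuntimeError(f"non-finite state reached on [{t0}, {t1}]")
    return t_eval, y


def simulate_cycle(
    state0: np.ndarray,
    p: ModelParameters,
    spec: ProtocolSpec,
    index: int = 1,
    t_start: float = 0.0,
    metabolites_frozen: bool = False,
) -> CycleResult:
    """One contraction/relaxation cycle.

    Cross-bridge cycling runs over [0, T_on]; over (T_on, T_cyc] the
    cross-bridge states are held while metabolic fluxes continue (skipped
    entirely when the metabolites are clamped, since nothing then moves).
    """
    try:
        t_on, y_on = _integrate_phase(
            state0, t_start, t_start + spec.T_on, p, spec,
            xb_active=True, metabolites_frozen=metabolites_frozen,
        )
        if spec.T_cyc > spec.T_on and not metabolites_frozen:
            t_off, y_off = _integrate_phase(
                y_on[-1], t_start + spec.T_on, t_start + spec.T_cyc, p, spec,
                xb_active=False, metabolites_frozen=False,
            )
            t_all = np.concatenate([t_on, t_off[1:]])
            y_all = np.vstack([y_on, y_off[1:]])
        else:
            t_all, y_all = t_on, y_on
            if spec.T_cyc > spec.T_on:
                t_all = np.append(t_all, t_start + spec.T_cyc)
                y_all = np.vstack([y_all, y_all[-1]])
    except RuntimeError as err:
        raise RuntimeError(f"cycle {index}: {err}") from err

    n_on = len(t_on)
    forces_on = np.array([force_from_vector(y, p) for y in y_on])
    peak = float(forces_on.max())
    mean = float(forces_on.mean())
    mean_xb = {
        name: float(y_on[:, i].mean())
        for i, name in enumerate(("P", "A1", "A2", "A3"))
    }
    forces_all = np.concatenate([
        forces_on,
        np.array([force_from_vector(y, p) for y in y_all[n_on:]]),
    ])
    end_state = y_all[-1].copy()
    if spec.store_trajectory:
        return CycleResult(index, t_start, peak, mean, end_state, mean_xb,
                           t_all, y_all, forces_all)
    return CycleResult(index, t_start, peak, mean, end_state, mean_xb)


def simulate_protocol(spec: ProtocolSpec, p: ModelParameters) -> ProtocolResult:
    """Chain n_cycles contraction cycles with metabolite carryover."""
    result = ProtocolResult(spec=spec, params=p)
    state = None
    for j, iemg_j in enumerate(spec.iemg, start=1):
        y0 = init_cycle(j, state, float(iemg_j), p)
        cyc = simulate_cycle(y0, p, spec, index=j, t_start=(j - 1) * spec.T_cyc)
        result.cycles.append(cyc)
        state = cyc.end_state
    return result


def extend_protocol(
    result: ProtocolResult,
    extra_cycles: int,
    clamp: Optional[Dict[str, float]] = None,
    iemg: Optional[float] = None,
) -> ProtocolResult:
    """Continue a finished protocol with clamped metabolites.

    `clamp` maps metabolite names to scale factors applied to their
    end-of-protocol concentration; every metabolite derivative is zeroed
    during the extension (the named ones are additionally rescaled first).
    Recruitment holds at the final cycle's value unless overridden.
    """
    clamp = dict(clamp or {})
    for name in clamp:
        if name not in _CLAMPABLE:
            raise KeyError(
                f"unknown metabolite {name!r}; expected one of {_CLAMPABLE}"
            )
    spec = result.spec
    p = result.params
    iemg_j = float(spec.iemg[-1]) if iemg is None else float(iemg)

    state = result.end_state.copy()
    for name, scale in clamp.items():
        idx = STATE_NAMES.index(name)
        state[idx] = state[idx] * float(scale)

    ext = ProtocolResult(spec=spec, params=p, cycles=list(result.cycles))
    n0 = result.n_cycles
    for k in range(1, extra_cycles + 1):
        y0 = init_cycle(n0 + k, state, iemg_j, p)
        cyc = simulate_cycle(
            y0, p, spec, index=n0 + k,
            t_start=(n0 + k - 1) * spec.T_cyc, metabolites_frozen=True,
        )
        ext.cycles.append(cyc)
        state = cyc.end_state
    return ext
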