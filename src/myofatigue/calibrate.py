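"""Parameter estimation: max-normalized least squares with multistart.

The objective sums, over the four measured channels (total force, PCr, Pi,
H+), the squared per-cycle residuals divided by the channel's maximum
observed value.  The proton channel is fitted in concentration space (uM);
observed pH is converted first.  Minimization is bound-constrained
least-squares (trust-region reflective with numerical Jacobian) repeated
from log-uniform random starts inside the search box, keeping the best.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .parameters import FITTED_NAMES, ModelParameters
from .protocol import ProtocolSpec, simulate_protocol

__all__ = ["ObservationSet", "FitResult", "objective", "fit", "default_bounds"]

_CHANNELS = ("force", "PCr", "Pi", "H")
_PENALTY = 1e6   # residual magnitude assigned when the simulation fails


@dataclass
class ObservationSet:
    """Per-cycle timestamped samples of force [N], PCr/Pi [mM], H+ [uM]."""

    times: np.ndarray
    force: np.ndarray
    PCr: np.ndarray
    Pi: np.ndarray
    H: np.ndarray
    iemg: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in _CHANNELS + ("iemg",):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        if n == 0:
            raise ValueError("observation set must contain at least one sample")
        for name in _CHANNELS:
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length mismatch")
        if np.any((self.iemg < 0) | (self.iemg > 1)):
            raise ValueError("iEMG fractions must lie in [0, 1]")

    @property
    def n_cycles(self) -> int:
        return len(self.iemg)

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def to_csv(self, path) -> None:
        import pandas as pd
        rows = []
        for name in _CHANNELS:
            for t, v in zip(self.times, self.channel(name)):
                rows.append({"time_s": t, "channel": name, "value": v})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, iemg: Sequence[float]) -> "ObservationSet":
        import pandas as pd
        df = pd.read_csv(path)
        wide = df.pivot_table(index="time_s", columns="channel", values="value")
        return cls(
            times=wide.index.to_numpy(),
            force=wide["force"].to_numpy(),
            PCr=wide["PCr"].to_numpy(),
            Pi=wide["Pi"].to_numpy(),
            H=wide["H"].to_numpy(),
            iemg=np.asarray(iemg, dtype=float),
        )


@dataclass
class FitResult:
    params: ModelParameters
    objective: float
    rmse: Dict[str, float]
    restart_objectives: List[float]
    seed: Optional[int]
    free_names: Tuple[str, ...]
    bounds: Dict[str, Tuple[float, float]]

    def to_json(self, path) -> None:
        payload = {
            "best_parameters": self.params.to_dict(),
            "objective": self.objective,
            "rmse": self.rmse,
            "restart_objectives": self.restart_objectives,
            "seed": self.seed,
            "free_parameters": list(self.free_names),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# --------------------------------------------------------------------- #

def _simulate_channels(p: ModelParameters, obs: ObservationSet,
                       rtol: float, atol: float) -> Dict[str, np.ndarray]:
    spec = ProtocolSpec(iemg=obs.iemg, store_trajectory=False,
                        rtol=rtol, atol=atol, output_dt=0.02)
    sim = simulate_protocol(spec, p)
    met = sim.end_metabolites()
    return {
        "force": sim.peak_forces,
        "PCr": met["PCr"].to_numpy(),
        "Pi": met["Pi"].to_numpy(),
        "H": met["H"].to_numpy(),
    }


def _residuals(p: ModelParameters, obs: ObservationSet,
               rtol: float, atol: float) -> np.ndarray:
    """Stacked residuals weighted so that sum(r^2) equals the objective."""
    norms = {}
    for name in _CHANNELS:
        m = float(np.max(obs.channel(name)))
        if m <= 0:
            raise ValueError(f"channel {name!r} has non-positive maximum; "
                             "max-normalization is undefined")
        norms[name] = m
    try:
        sim = _simulate_channels(p, obs, rtol, atol)
    except (RuntimeError, FloatingPointError):
        return np.full(sum(len(obs.channel(c)) for c in _CHANNELS), _PENALTY)
    parts = [
        (obs.channel(name) - sim[name]) / math.sqrt(norms[name])
        for name in _CHANNELS
    ]
    return np.concatenate(parts)


def objective(p: ModelParameters, obs: ObservationSet,
              rtol: float = 1e-8, atol: float = 1e-10) -> float:
    """Max-normalized sum-of-squares misfit over the four channels.

    Returns a large penalty (not an exception) if the simulation fails at
    the proposed parameters, so optimizers can move on.
    """
    r = _residuals(p, obs, rtol, atol)
    return float(np.dot(r, r))


def default_bounds(
    base: ModelParameters,
    names: Sequence[str],
    lo: float = 0.01,
    hi: float = 100.0,
) -> Dict[str, Tuple[float, float]]:
    """Search box [lo x, hi x] around the reference value of each parameter."""
    out = {}
    for name in names:
        v = getattr(base, name)
        out[name] = (lo * v, hi * v)
    return out


def fit(
    obs: ObservationSet,
    free_names: Sequence[str] = FITTED_NAMES,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    n_starts: int = 100,
    seed: Optional[int] = None,
    base: Optional[ModelParameters] = None,
    include_base_start: bool = False,
    max_nfev: int = 60,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    log_scale: bool = True,
) -> FitResult:
    """Multistart bound-constrained least squares.

    Start points are drawn log-uniformly inside the bounds (seeded); each is
    refined with trust-region-reflective least squares, and the restart with
    the smallest objective wins.  Rate-like parameters span orders of
    magnitude, so the search runs in log-parameter space by default.
    Per-channel RMSEs are evaluated at the optimum.  `include_base_start`
    additionally seeds one restart at `base`.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    base = ModelParameters() if base is None else base
    free_names = tuple(free_names)
    for name in free_names:
        if name not in FITTED_NAMES:
            raise KeyError(f"unknown fitted parameter {name!r}")
    bounds = default_bounds(base, free_names) if bounds is None else bounds
    lo = np.array([bounds[n][0] for n in free_names])
    hi = np.array([bounds[n][1] for n in free_names])
    if np.any(lo <= 0) or np.any(~np.isfinite(hi)):
        raise ValueError("bounds must be finite and positive")

    rng = np.random.default_rng(seed)
    starts = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=(n_starts, len(free_names)))
    )
    if include_base_start:
        starts[0] = [getattr(base, n) for n in free_names]

    def resid(x: np.ndarray) -> np.ndarray:
        values = np.exp(x) if log_scale else x
        p = base.replace(**dict(zip(free_names, values)))
        return _residuals(p, obs, rtol, atol)

    if log_scale:
        opt_lo, opt_hi, opt_starts = np.log(lo), np.log(hi), np.log(starts)
    else:
        opt_lo, opt_hi, opt_starts = lo, hi, starts

    best = None
    trace: List[float] = []
    failures: List[str] = []
    for x0 in opt_starts:
        try:
            # finite-difference step must sit well above the ODE-solver noise
            # floor, or the Jacobian is noise and the optimizer stalls
            res = least_squares(
                resid, x0, bounds=(opt_lo, opt_hi), max_nfev=max_nfev,
                method="trf", diff_step=1e-3,
            )
        except Exception as err:  # noqa: BLE001 - diagnostics, then continue
            failures.append(str(err))
            trace.append(float("inf"))
            continue
        fobj = 2.0 * res.cost   # least_squares cost = 0.5 * sum(r^2)
        trace.append(float(fobj))
        if best is None or fobj < best[0]:
            x_nat = np.exp(res.x) if log_scale else res.x.copy()
            best = (float(fobj), x_nat)
    if best is None:
        raise RuntimeError(
            "all restarts failed to converge; first error: "
            + (failures[0] if failures else "unknown")
        )

    fobj, x_best = best
    p_best = base.replace(**dict(zip(free_names, x_best)))
    sim = _simulate_channels(p_best, obs, rtol, atol)
    rmse = {
        name: float(np.sqrt(np.mean((obs.channel(name) - sim[name]) ** 2)))
        for name in _CHANNELS
    }
    return FitResult(
        params=p_best, objective=fobj, rmse=rmse, restart_objectives=trace,
        seed=seed, free_names=free_names,
        bounds={n: (float(bounds[n][0]), float(bounds[n][1])) for n in free_names},
    )
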