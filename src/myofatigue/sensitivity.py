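"""Local (central-difference) and global (Latin-hypercube neighborhood)
sensitivity of protocol force to the model parameters.

The local sensitivity of the force functional F to parameter x_i is the
normalized central difference

    S_i = [F(x_i + dx) - F(x_i - dx)] / F(x0) * x_i / (2 dx),  dx = h x_i

with h = 1% by default; the functional is the end-of-protocol (final cycle)
peak force.  The global analysis draws Latin-hypercube samples from the
+-radius box around the best-fit set and repeats the local analysis at each
sample, summarizing the per-parameter sensitivity distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import qmc, spearmanr

from .parameters import FITTED_NAMES, ModelParameters
from .protocol import ProtocolSpec, simulate_protocol
from .synthetic import make_iemg_profile

__all__ = [
    "SensitivityReport", "final_force", "local_sensitivity",
    "global_sensitivity", "dissociation_sweep",
]


@dataclass
class SensitivityReport:
    names: Tuple[str, ...]
    local: Dict[str, float]
    samples: Optional[np.ndarray] = None      # (n_samples, n_params) S values
    sampled_sets: Optional[np.ndarray] = None
    radius: Optional[float] = None
    n_failed: int = 0
    seed: Optional[int] = None

    def summary(self) -> pd.DataFrame:
        """Per-parameter local S and global quartiles (mirrors the box plot)."""
        rows = []
        for i, name in enumerate(self.names):
            row = {"parameter": name, "local_S": self.local[name]}
            if self.samples is not None:
                col = self.samples[:, i]
                col = col[np.isfinite(col)]
                row.update(
                    global_median=float(np.median(col)),
                    global_q1=float(np.percentile(col, 25)),
                    global_q3=float(np.percentile(col, 75)),
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def rank_conservation(self) -> float:
        """Spearman correlation between |local S| and median |global S|."""
        if self.samples is None:
            raise ValueError("no global samples in this report")
        local_mag = [abs(self.local[n]) for n in self.names]
        global_mag = np.nanmedian(np.abs(self.samples), axis=0)
        rho, _ = spearmanr(local_mag, global_mag)
        return float(rho)


def _default_protocol(n_cycles: int = 60) -> ProtocolSpec:
    return ProtocolSpec(
        iemg=make_iemg_profile("linear-decline", n_cycles),
        store_trajectory=False,
    )


def final_force(p: ModelParameters, spec: Optional[ProtocolSpec] = None) -> float:
    """End-of-protocol peak force [N] — the fatigue endpoint functional."""
    spec = _default_protocol() if spec is None else spec
    return float(simulate_protocol(spec, p).peak_forces[-1])


def local_sensitivity(
    p: ModelParameters,
    names: Sequence[str] = FITTED_NAMES,
    rel_step: float = 0.01,
    output: Optional[Callable[[ModelParameters], float]] = None,
    spec: Optional[ProtocolSpec] = None,
) -> Dict[str, float]:
    """Central-difference normalized sensitivities, one per parameter."""
    if rel_step <= 0:
        raise ValueError("rel_step must be positive")
    spec = _default_protocol() if spec is None else spec
    F = output if output is not None else (lambda q: final_force(q, spec))
    F0 = F(p)
    if F0 == 0:
        raise ZeroDivisionError("reference force is zero; S is undefined")
    out: Dict[str, float] = {}
    for name in names:
        x0 = getattr(p, name)
        dx = rel_step * x0
        fp = F(p.replace(**{name: x0 + dx}))
        fm = F(p.replace(**{name: x0 - dx}))
        out[name] = (fp - fm) / F0 * x0 / (2.0 * dx)
    return out


def global_sensitivity(
    p: ModelParameters,
    names: Sequence[str] = FITTED_NAMES,
    radius: float = 0.10,
    n_samples: int = 10_000,
    seed: Optional[int] = None,
    rel_step: float = 0.01,
    spec: Optional[ProtocolSpec] = None,
) -> SensitivityReport:
    """Latin-hypercube neighborhood sensitivity.

    Samples the +-radius box around `p` (seeded LHS), runs the local
    analysis at every sample; failed simulations are recorded and excluded.
    The published analysis uses 10,000 samples over the full parameter set;
    pass a smaller `n_samples`/`names` subset for desk-scale runs.
    """
    if not (0.0 < radius < 1.0):
        raise ValueError("radius must lie in (0, 1)")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    names = tuple(names)
    spec = _default_protocol() if spec is None else spec
    x0 = np.array([getattr(p, n) for n in names])
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n=n_samples)
    sets = qmc.scale(unit, x0 * (1.0 - radius), x0 * (1.0 + radius))

    local = local_sensitivity(p, names, rel_step, spec=spec)
    rows: List[np.ndarray] = []
    n_failed = 0
    for x in sets:
        q = p.replace(**dict(zip(names, x)))
        try:
            s = local_sensitivity(q, names, rel_step, spec=spec)
            rows.append(np.array([s[n] for n in names]))
        except (RuntimeError, ZeroDivisionError, FloatingPointError):
            n_failed += 1
            rows.append(np.full(len(names), np.nan))
    return SensitivityReport(
        names=names, local=local, samples=np.vstack(rows), sampled_sets=sets,
        radius=radius, n_failed=n_failed, seed=seed,
    )


def dissociation_sweep(
    p: ModelParameters,
    which: str,
    factors: Sequence[float] = (0.75, 1.0, 1.25, 1.5, 1.75, 2.0),
    spec: Optional[ProtocolSpec] = None,
) -> pd.DataFrame:
    """Final protocol force as the Pi or H+ dissociation constant is scaled.

    `which` is "K_Pi" or "K_H"; factors span the published 0.75-2.00 range.
    """
    if which not in ("K_Pi", "K_H"):
        raise KeyError(f"sweep parameter must be 'K_Pi' or 'K_H', got {which!r}")
    factors = np.asarray(factors, dtype=float)
    if np.any((factors < 0.75) | (factors > 2.0)):
        raise ValueError("factors must lie within [0.75, 2.0]")
    spec = _default_protocol() if spec is None else spec
    base = getattr(p, which)
    forces = [
        final_force(p.replace(**{which: base * f}), spec) for f in factors
    ]
    return pd.DataFrame({"factor": factors, "final_force_N": forces})
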