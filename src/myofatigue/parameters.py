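"""Model constants for the knee-extension cross-bridge fatigue model.

Two groups of constants live here:

* the 22 fitted kinetic/force/metabolic constants of the published
  knee-extension parameterization (rates in s^-1, dissociation constants in
  mM except the proton constant in uM, stiffnesses in mN mm^-2 um^-1,
  bimolecular metabolic constants in mM^-1 s^-1), and
* structural constants of the reconstruction (power-stroke size, effective
  cycling-site concentration, cross-sectional force scaling, proton buffering
  and clearance, protocol timing, resting metabolite pools) that are not part
  of the fitted set but are required to close the model.  They are calibrated
  once against the published summary physiology of the protocol (first-cycle
  force, first-minute Pi/PCr excursions, the pH time course) and are
  config-exposed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields
from typing import Dict, Iterator, Tuple

__all__ = ["ModelParameters", "RestingState", "FITTED_NAMES"]

#: names of the fitted constants, in the order the published table lists them
FITTED_NAMES: Tuple[str, ...] = (
    "ka", "kd", "k1", "km1", "k2", "km2", "k3",
    "alpha1", "alpha2", "alpha3", "s3",
    "K_ATP", "K_ADP", "K_Pi", "K_H",
    "kstiff1", "kstiff2",
    "k_CKf", "k_CKr", "k_Gly", "k_Pidil", "k_adk",
)


@dataclass
class RestingState:
    """Resting (pre-exercise) metabolite pools, mM except pH.

    PCr, ATP and pH sit at the literature resting values for human quadriceps;
    resting Pi is set to 2.0 mM, the value required for the model's Pi
    excursion to be simultaneously consistent with a ~16-fold first-minute
    rise and a ~30 mM end-of-exercise plateau given phosphate conservation
    (free Pi can only come from PCr breakdown and net ATP drop).  AMP is
    placed on the adenylate-kinase equilibrium (unit equilibrium constant).
    """

    PCr: float = 35.0
    Pi: float = 2.0
    pH: float = 7.05
    ATP: float = 8.2
    ADP: float = 0.01
    Cr: float = 10.0

    @property
    def AMP(self) -> float:
        return self.ADP ** 2 / self.ATP

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"resting {f.name} is not finite: {v!r}")
        if not (0.0 < self.pH < 14.0):
            raise ValueError(f"resting pH out of range: {self.pH}")
        for name in ("PCr", "Pi", "ATP", "ADP", "Cr"):
            if getattr(self, name) < 0:
                raise ValueError(f"resting {name} must be non-negative")


@dataclass
class ModelParameters:
    """All constants of the model.

    The first 22 fields default to the published knee-extension estimates.
    Internal units: time s, concentrations mM (free protons carried in uM),
    distortion um (the printed s3 of 0.1 nm is stored as 1e-4 um).
    """

    # -- cross-bridge cycle rates [1/s] --
    ka: float = 1305.6      # P -> A1 attachment
    kd: float = 1482.0      # A1 -> P detachment (Pi rebinding)
    k1: float = 1419.4      # A1 -> A2 (proton-release step)
    km1: float = 1004.0     # A2 -> A1
    k2: float = 638.0       # A2 -> A3 ratcheting (power stroke)
    km2: float = 1077.0     # A3 -> A2 unratcheting
    k3: float = 371.2       # A3 -> P detachment (ADP off / ATP on)
    # -- stretch sensing [1/um]; s3 [um] --
    alpha1: float = 74.2
    alpha2: float = 405.0
    alpha3: float = 40.4
    s3: float = 1.0e-4      # printed as 0.1 nm
    # -- dissociation constants --
    K_ATP: float = 3.3          # mM
    K_ADP: float = 18.6e-5      # mM
    K_Pi: float = 40.9          # mM
    K_H: float = 0.62           # uM
    # -- stiffness constants [mN mm^-2 um^-1] --
    kstiff1: float = 265.8
    kstiff2: float = 95115.2
    # -- metabolic rate constants --
    k_CKf: float = 0.75         # mM^-1 s^-1, creatine kinase, ATP-forming
    k_CKr: float = 0.3e-3       # mM^-1 s^-1, creatine kinase, ADP-forming
    k_Gly: float = 0.93         # mM^-1 s^-1, glycolytic/oxidative ATP supply
    k_Pidil: float = 0.2e-3     # 1/s, Pi dilution/export
    k_adk: float = 55.3         # mM^-1 s^-1, adenylate kinase

    # -- structural constants (reconstruction plumbing, config-exposed) --
    delta_r: float = 0.008      # um, power-stroke displacement
    rho_myo: float = 10.0       # mM, effective ATP-turnover coupling per cycle flux
    A_cs: float = 2300.0        # mm^2, effective cross-sectional scaling
    beta_buf: float = 90.0      # mM per pH unit, lumped proton buffering capacity
    gamma_gly: float = 0.30     # H+ produced per glycolytic ATP
    k_Hclear: float = 1.8       # mM s^-1 per pH unit, proton clearance/efflux
    F_pee: float = 0.0          # N, parallel-elastic offset (fixed joint angle)
    T_cyc: float = 5.0          # s, cycle period
    T_on: float = 3.0           # s, contraction-phase duration

    resting: RestingState = field(default_factory=RestingState)

    # ------------------------------------------------------------------ #

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = FITTED_NAMES + (
            "delta_r", "rho_myo", "A_cs", "beta_buf", "T_cyc", "T_on",
        )
        for name in positive:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"parameter {name} must be finite and > 0, got {v!r}")
        for name in ("gamma_gly", "k_Hclear", "F_pee"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v!r}")
        if self.T_on > self.T_cyc:
            raise ValueError(
                f"contraction phase T_on={self.T_on} exceeds cycle period T_cyc={self.T_cyc}"
            )
        self.resting.validate()

    def replace(self, **updates: float) -> "ModelParameters":
        """Return a copy with the named fields replaced (validated)."""
        resting_updates = {
            k[len("resting_"):]: updates.pop(k)
            for k in list(updates)
            if k.startswith("resting_")
        }
        new = dataclasses.replace(self, **updates)
        if resting_updates:
            new.resting = dataclasses.replace(self.resting, **resting_updates)
        new.validate()
        return new

    def fitted_values(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in FITTED_NAMES}

    def to_dict(self) -> Dict[str, float]:
        d = {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "resting"
        }
        d.update({f"resting_{f.name}": getattr(self.resting, f.name)
                  for f in fields(self.resting)})
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, float]) -> "ModelParameters":
        resting_kwargs = {}
        kwargs = {}
        valid = {f.name for f in fields(cls)} - {"resting"}
        valid_resting = {f.name for f in fields(RestingState)}
        for key, value in d.items():
            if key.startswith("resting_") and key[len("resting_"):] in valid_resting:
                resting_kwargs[key[len("resting_"):]] = value
            elif key in valid:
                kwargs[key] = value
            else:
                raise KeyError(f"unknown model parameter: {key!r}")
        return cls(resting=RestingState(**resting_kwargs), **kwargs)

    def __iter__(self) -> Iterator[Tuple[str, float]]:
        return iter(self.to_dict().items())
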