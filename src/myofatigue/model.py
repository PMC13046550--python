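"""Model kernel: state space, rate laws, force computation and the ODE
right-hand side for one knee-extension contraction.

The contractile element is a four-state actin-myosin cross-bridge cycle

    P  -ka->  A1  -k1->  A2  -k2->  A3  -k3->  P
       <-kd-      <-km1-     <-km2-

where P is the permissible (detached) state, A1 the loosely bound state, A2
the strongly bound pre-power-stroke state and A3 the post-power-stroke
(ratcheted) state.  Each attached state is a lump of actomyosin complexes in
rapid equilibrium with the surrounding metabolites, so the transition rates
are modulated by saturation fractions of Pi, H+, ADP and ATP:

* Pi release gates attachment: ka_eff = ka (1 - fPi), and Pi rebinding drives
  detachment: kd_eff = kd fPi;
* the proton carried from ATP hydrolysis is released on the way to the
  strongly bound state, so H+ gates both the A1->A2 step and ratcheting:
  k1_eff = k1 (1 - fH), km1_eff = km1 fH, k2_eff = k2 (1 - fH);
* final detachment requires ADP release and fresh ATP binding:
  k3_eff = k3 (1 - fADP) fATP.

The attached populations are represented by the zeroth and first moments of
their elastic-distortion distributions (distribution-moment closure).  Under
the isometric protocol the sliding velocity is zero and new attachments carry
zero distortion, so the first moments stay at zero and the ratcheting term
k_stiff2 * delta_r * A3_0 dominates the force.

The metabolite block couples the cycle to creatine kinase, a lumped
glycolytic/oxidative ATP supply, adenylate kinase, Pi dilution and proton
buffering/clearance, all mass action.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import NamedTuple, Sequence

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "CrossBridgeState", "MetaboliteState", "RateSet", "ForceComponents",
    "ph_to_h", "h_to_ph", "saturation_fraction", "effective_rates",
    "xb_force", "system_rhs", "pack_state", "unpack_state",
    "N_STATES", "STATE_NAMES",
]

LN10 = math.log(10.0)

#: layout of the packed state vector
STATE_NAMES = (
    "P", "A1_0", "A2_0", "A3_0", "A1_1", "A2_1", "A3_1",
    "ATP", "ADP", "AMP", "PCr", "Cr", "Pi", "H",
)
N_STATES = len(STATE_NAMES)
_XB_SLICE = slice(0, 7)
_MET_SLICE = slice(7, 14)


# --------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------- #

@dataclass
class CrossBridgeState:
    """Occupancies (zeroth moments) and first distortion moments [um]."""

    P: float = 1.0
    A1_0: float = 0.0
    A2_0: float = 0.0
    A3_0: float = 0.0
    A1_1: float = 0.0
    A2_1: float = 0.0
    A3_1: float = 0.0

    def validate(self) -> None:
        for name in ("P", "A1_0", "A2_0", "A3_0"):
            v = getattr(self, name)
            if not math.isfinite(v) or not (-1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError(f"occupancy {name}={v!r} outside [0, 1]")
        for name in ("A1_1", "A2_1", "A3_1"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"first moment {name} is not finite")

    @property
    def total(self) -> float:
        return self.P + self.A1_0 + self.A2_0 + self.A3_0


@dataclass
class MetaboliteState:
    """Free metabolite pools; concentrations in mM, protons in uM."""

    ATP: float
    ADP: float
    AMP: float
    PCr: float
    Cr: float
    Pi: float
    H: float

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"metabolite {f.name}={v!r} must be finite and non-negative"
                )

    @property
    def pH(self) -> float:
        return h_to_ph(self.H)


class RateSet(NamedTuple):
    """Effective transition rates [1/s] after metabolite/strain modulation."""

    ka_eff: float
    kd_eff: float
    k1_eff: float
    km1_eff: float
    k2_eff: float
    km2_eff: float
    k3_eff: float


class ForceComponents(NamedTuple):
    friction: float   # mN/mm^2, k_stiff1 * (first moments of A2, A3)
    ratchet: float    # mN/mm^2, k_stiff2 * delta_r * A3_0
    total_N: float    # N, scaled by cross-section + parallel-elastic offset


# --------------------------------------------------------------------- #
# elementary operations
# --------------------------------------------------------------------- #

def ph_to_h(ph: float) -> float:
    """Convert pH to free proton concentration in uM (pH 7 -> 0.1 uM)."""
    if not (isinstance(ph, (int, float)) and math.isfinite(ph)):
        raise ValueError(f"pH must be a finite number, got {ph!r}")
    if not (0.0 < ph < 14.0):
        raise ValueError(f"pH out of physical range (0, 14): {ph!r}")
    return 10.0 ** (6.0 - ph)


def h_to_ph(h: float) -> float:
    """Inverse of :func:`ph_to_h`; h in uM."""
    if not (isinstance(h, (int, float)) and math.isfinite(h) and h > 0):
        raise ValueError(f"[H+] must be a finite positive number, got {h!r}")
    return 6.0 - math.log10(h)


def saturation_fraction(conc: float, K: float) -> float:
    """Equilibrium bound fraction conc/(K + conc) for a single binding site.

    `conc` and `K` must share units.  Monotone nondecreasing in `conc`,
    in [0, 1).
    """
    if not (math.isfinite(K) and K > 0):
        raise ValueError(f"dissociation constant must be > 0, got {K!r}")
    if not (math.isfinite(conc) and conc >= 0):
        raise ValueError(f"concentration must be >= 0, got {conc!r}")
    return conc / (K + conc)


def _strain_factors(mean_distortions: Sequence[float], p: ModelParameters):
    """Strain modulation evaluated at the per-state mean distortions [um].

    Forward rates carry exp(-alpha s); detachment carries the quadratic
    1 + alpha3^2 (s - s3)^2 with its minimum at the printed s3.  Isometric
    runs keep all mean distortions at zero, where the exponentials are 1 and
    the detachment factor is 1 + (alpha3 s3)^2 ~ 1.
    """
    s1, s2, s3bar = mean_distortions
    for s in (s1, s2, s3bar):
        if not math.isfinite(s):
            raise ValueError("mean distortions must be finite")
    g1 = math.exp(-p.alpha1 * s1)
    g2 = math.exp(-p.alpha2 * s2)
    g3 = 1.0 + (p.alpha3 * (s3bar - p.s3)) ** 2
    return g1, g2, g3


def effective_rates(
    met: MetaboliteState,
    mean_distortions: Sequence[float],
    p: ModelParameters,
) -> RateSet:
    """Metabolite- and strain-modulated transition rates.

    Raises ValueError on negative concentrations or non-finite distortions.
    """
    met.validate()
    fPi = saturation_fraction(met.Pi, p.K_Pi)
    fH = saturation_fraction(met.H, p.K_H)
    fADP = saturation_fraction(met.ADP, p.K_ADP)
    fATP = saturation_fraction(met.ATP, p.K_ATP)
    g1, g2, g3 = _strain_factors(mean_distortions, p)
    return RateSet(
        ka_eff=p.ka * (1.0 - fPi),
        kd_eff=p.kd * fPi,
        k1_eff=p.k1 * (1.0 - fH) * g1,
        km1_eff=p.km1 * fH,
        k2_eff=p.k2 * (1.0 - fH) * g2,
        km2_eff=p.km2,
        k3_eff=p.k3 * (1.0 - fADP) * fATP * g3,
    )


def xb_force(xb: CrossBridgeState, p: ModelParameters) -> ForceComponents:
    """Force decomposition: friction (first moments) + ratcheting (A3 pool).

    friction = kstiff1 (A2_1 + A3_1), ratchet = kstiff2 delta_r A3_0, both in
    mN/mm^2; total_N converts through the effective cross-section and adds
    the parallel-elastic offset.
    """
    xb.validate()
    friction = p.kstiff1 * (xb.A2_1 + xb.A3_1)
    ratchet = p.kstiff2 * p.delta_r * xb.A3_0
    total_N = (friction + ratchet) * p.A_cs / 1000.0 + p.F_pee
    return ForceComponents(friction, ratchet, total_N)


def force_from_vector(y: np.ndarray, p: ModelParameters) -> float:
    """Total force [N] from a packed state vector (no validation; hot path)."""
    friction = p.kstiff1 * (y[5] + y[6])
    ratchet = p.kstiff2 * p.delta_r * y[3]
    return (friction + ratchet) * p.A_cs / 1000.0 + p.F_pee


# --------------------------------------------------------------------- #
# packed-state helpers
# --------------------------------------------------------------------- #

def pack_state(xb: CrossBridgeState, met: MetaboliteState) -> np.ndarray:
    return np.array([
        xb.P, xb.A1_0, xb.A2_0, xb.A3_0, xb.A1_1, xb.A2_1, xb.A3_1,
        met.ATP, met.ADP, met.AMP, met.PCr, met.Cr, met.Pi, met.H,
    ])


def unpack_state(y: Sequence[float]):
    xb = CrossBridgeState(*[float(v) for v in y[_XB_SLICE]])
    met = MetaboliteState(*[float(v) for v in y[_MET_SLICE]])
    return xb, met


# --------------------------------------------------------------------- #
# ODE right-hand side
# --------------------------------------------------------------------- #

def _rhs(
    t: float,
    y: Sequence[float],
    p: ModelParameters,
    xb_active: bool = True,
    metabolites_frozen: bool = False,
) -> list:
    """Time derivative of the packed state.

    `xb_active=False` freezes the cross-bridge states (relaxation phase:
    transitions disabled, metabolic recovery continues).
    `metabolites_frozen=True` zeroes every metabolite derivative (the clamped
    in-silico perturbation experiments).
    """
    (P, A10, A20, A30, A11, A21, A31,
     ATP, ADP, AMP, PCr, Cr, Pi, H) = [float(v) for v in y]

    # guard rapid-equilibrium fractions against tiny negative excursions
    Pi_c = Pi if Pi > 0.0 else 0.0
    H_c = H if H > 0.0 else 0.0
    ADP_c = ADP if ADP > 0.0 else 0.0
    ATP_c = ATP if ATP > 0.0 else 0.0

    fPi = Pi_c / (p.K_Pi + Pi_c)
    fH = H_c / (p.K_H + H_c)
    fADP = ADP_c / (p.K_ADP + ADP_c)
    fATP = ATP_c / (p.K_ATP + ATP_c)

    s1 = A11 / A10 if A10 > 1e-12 else 0.0
    s2 = A21 / A20 if A20 > 1e-12 else 0.0
    s3bar = A31 / A30 if A30 > 1e-12 else 0.0

    ka = p.ka * (1.0 - fPi)
    kd = p.kd * fPi
    k1 = p.k1 * (1.0 - fH) * math.exp(-p.alpha1 * s1)
    km1 = p.km1 * fH
    k2 = p.k2 * (1.0 - fH) * math.exp(-p.alpha2 * s2)
    km2 = p.km2
    k3 = p.k3 * (1.0 - fADP) * fATP * (1.0 + (p.alpha3 * (s3bar - p.s3)) ** 2)

    if xb_active:
        J_a = ka * P - kd * A10      # net P -> A1 (releases Pi)
        J_1 = k1 * A10 - km1 * A20   # net A1 -> A2 (releases H+)
        J_2 = k2 * A20 - km2 * A30   # net ratcheting
        J_3 = k3 * A30               # detachment (ATP -> ADP)
        dP = -J_a + J_3
        dA10 = J_a - J_1
        dA20 = J_1 - J_2
        dA30 = J_2 - J_3
        # first moments: isometric (v = 0), attachments carry zero distortion
        dA11 = -(kd + k1) * A11 + km1 * A21
        dA21 = k1 * A11 - (km1 + k2) * A21 + km2 * A31
        dA31 = k2 * A21 - (km2 + k3) * A31
    else:
        J_a = J_1 = J_3 = 0.0
        dP = dA10 = dA20 = dA30 = dA11 = dA21 = dA31 = 0.0

    if metabolites_frozen:
        return [dP, dA10, dA20, dA30, dA11, dA21, dA31,
                0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]

    # metabolic fluxes, mM/s
    J_CK = p.k_CKf * PCr * ADP_c - p.k_CKr * Cr * ATP_c
    J_Gly = p.k_Gly * ADP_c * Pi_c
    J_adk = p.k_adk * (ADP_c * ADP_c - ATP_c * AMP)
    J_Pidil = p.k_Pidil * Pi_c

    # All solution-side metabolite exchange is booked at the detachment flux,
    # where ATP binds and one full hydrolysis turnover closes (1 ATP in, ADP +
    # Pi + H+ out).  In steady cycling this equals the attachment and
    # proton-release fluxes; booking at detachment keeps the accounting exact
    # across the per-cycle state resets of the protocol.  The sequential
    # release of Pi (P->A1) and H+ (A1->A2) still acts through the rate
    # modulation above.
    rho = p.rho_myo
    J_ATPase = rho * J_3
    J_Pi_rel = J_ATPase
    J_H_rel = J_ATPase

    dATP = -J_ATPase + J_CK + J_Gly + J_adk
    dADP = J_ATPase - J_CK - J_Gly - 2.0 * J_adk
    dAMP = J_adk
    dPCr = -J_CK
    dCr = J_CK
    dPi = J_Pi_rel - J_Gly - J_Pidil

    # proton bookkeeping against the buffer, then through the pH relation
    pH = 6.0 - math.log10(H_c) if H_c > 0 else 14.0
    J_Hclear = p.k_Hclear * (p.resting.pH - pH)   # >0 when acidified
    J_H_net = J_H_rel - J_CK + p.gamma_gly * J_Gly - J_Hclear  # mM/s
    dH = LN10 * H_c * J_H_net / p.beta_buf        # uM/s

    deriv = [dP, dA10, dA20, dA30, dA11, dA21, dA31,
             dATP, dADP, dAMP, dPCr, dCr, dPi, dH]
    return deriv


def system_rhs(t: float, state: Sequence[float], p: ModelParameters) -> np.ndarray:
    """Public right-hand side (contraction phase, free metabolites).

    Validates finiteness of the result and names the offending component on
    failure, as an integration diagnostic.
    """
    deriv = _rhs(t, state, p, xb_active=True, metabolites_frozen=False)
    for name, d in zip(STATE_NAMES, deriv):
        if not math.isfinite(d):
            raise FloatingPointError(
                f"non-finite derivative for state component {name!r} at t={t}"
            )
    return np.asarray(deriv)
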