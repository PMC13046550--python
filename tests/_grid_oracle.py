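"""Independent brute-force oracle: the attached cross-bridge populations
resolved on an explicit elastic-distortion grid.

Instead of the production code's moment closure, every attached state is a
full distribution p_i(t, s) on a distortion grid.  Transitions preserve s,
attachment feeds the s = 0 bin, and each strain-sensitive rate is evaluated
bin by bin.  Metabolites are held fixed so that both formulations see the
same rates.  Occupancies are the sums over bins.
"""

import numpy as np
from scipy.integrate import solve_ivp

from myofatigue.model import saturation_fraction


def simulate_grid(p, met, iemg=1.0, t_end=1.0, n_bins=41, s_max=0.004):
    """Integrate one isometric contraction on the distortion grid.

    `met` maps metabolite names (Pi, H, ADP, ATP) to fixed concentrations.
    Returns (t, occupancies) where occupancies has columns P, A1, A2, A3.
    """
    s = np.linspace(-s_max, s_max, n_bins)
    i0 = int(np.argmin(np.abs(s)))
    assert abs(s[i0]) < 1e-12, "grid must contain s = 0 exactly"

    fPi = saturation_fraction(met["Pi"], p.K_Pi)
    fH = saturation_fraction(met["H"], p.K_H)
    fADP = saturation_fraction(met["ADP"], p.K_ADP)
    fATP = saturation_fraction(met["ATP"], p.K_ATP)

    ka = p.ka * (1.0 - fPi)
    kd = p.kd * fPi
    k1_s = p.k1 * (1.0 - fH) * np.exp(-p.alpha1 * s)
    km1 = p.km1 * fH
    k2_s = p.k2 * (1.0 - fH) * np.exp(-p.alpha2 * s)
    km2 = p.km2
    k3_s = p.k3 * (1.0 - fADP) * fATP * (1.0 + (p.alpha3 * (s - p.s3)) ** 2)

    n = n_bins

    def rhs(t, y):
        P = y[0]
        p1 = y[1:1 + n]
        p2 = y[1 + n:1 + 2 * n]
        p3 = y[1 + 2 * n:]
        attach = np.zeros(n)
        attach[i0] = ka * P
        dp1 = attach - (kd + k1_s) * p1 + km1 * p2
        dp2 = k1_s * p1 - (km1 + k2_s) * p2 + km2 * p3
        dp3 = k2_s * p2 - (km2 + k3_s) * p3
        dP = kd * p1.sum() + (k3_s * p3).sum() - ka * P
        return np.concatenate([[dP], dp1, dp2, dp3])

    y0 = np.zeros(1 + 3 * n)
    y0[0] = iemg
    t_eval = np.linspace(0.0, t_end, 101)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12, t_eval=t_eval)
    assert sol.success, sol.message
    P = sol.y[0]
    occ = np.column_stack([
        P,
        sol.y[1:1 + n].sum(axis=0),
        sol.y[1 + n:1 + 2 * n].sum(axis=0),
        sol.y[1 + 2 * n:].sum(axis=0),
    ])
    return sol.t, occ
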