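# Methods

## Model structure

The contractile element is a four-state cross-bridge cycle. P is the
permissible state (actin and myosin detached but free to interact), A1 the
loosely bound state, A2 the strongly bound pre-power-stroke state, A3 the
post-power-stroke (ratcheted) state. The forward path P→A1→A2→A3→P carries
one ATP turnover per completed cycle. Each attached state is treated as a
set of actomyosin complexes in rapid equilibrium with the free metabolites,
so ligand effects enter as saturation fractions f_X = [X]/(K_X+[X]) on the
transition rates:

| transition | effective rate | reading |
|---|---|---|
| P→A1  | ka·(1−f_Pi)·               | attachment requires the P_i site to be empty |
| A1→P  | kd·f_Pi                    | P_i rebinding drives detachment |
| A1→A2 | k1·(1−f_H)·e^(−α₁s̄₁)      | the hydrolysis proton must be released |
| A2→A1 | k‑1·f_H                    | proton rebinding reverses the step |
| A2→A3 | k2·(1−f_H)·e^(−α₂s̄₂)      | ratcheting proceeds from deprotonated A2 |
| A3→A2 | k‑2                        | unratcheting |
| A3→P  | k3·(1−f_ADP)·f_ATP·(1+α₃²(s̄₃−s₃)²) | ADP off, fresh ATP on |

The proton factor on ratcheting as well as on the A1→A2 step follows from
the sequential-release picture in which the hydrolysis proton travels with
the complex until the strongly bound state is formed; with only the A1→A2
step modulated, the simulated proton attributions come out roughly half
their reported size. A corresponding P_i factor on k1 was evaluated and
rejected: it makes the phosphate-doubling experiment about twice too strong
(see Limitations).

Attached populations are distribution-moment closed: each state carries its
occupancy (zeroth moment) and mean elastic distortion (first moment). The
protocol is isometric — sliding velocity zero, new attachments at zero
distortion — so first moments remain identically zero, the strain
exponentials evaluate to one, and force reduces to the ratcheting term

    F = k_stiff,2 · Δr · A3₀ · A_cs + F_PEE,

with the frictional term k_stiff,1·(A2₁+A3₁) identically zero. The
decomposition is computed and reported anyway; the ratchet share is ~100%
throughout, consistent with the dominance of k_stiff,2 in the sensitivity
ranking. A dedicated test checks the moment solution against a brute-force
simulation that resolves the attached populations on an explicit distortion
grid (agreement < 1e-4 occupancy over a 1-s contraction).

## Metabolite block

Mass-action fluxes, concentrations in mM (free H⁺ carried in μM):

- cross-bridge ATPase: one ATP consumed and one ADP, P_i and H⁺ delivered
  to solution per completed cycle, at flux ρ_myo·k3,eff·A3₀. Booking all
  solution-side exchange at the detachment step keeps the accounting exact
  across the per-cycle state resets (the attached pool is re-initialized
  each cycle, so fluxes booked at the attachment or proton-release steps
  would create phosphate/protons with no matching ATP consumption);
- creatine kinase: J_CK = k_CKf·[PCr][ADP] − k_CKr·[Cr][ATP], consuming one
  H⁺ in the ATP-forming direction;
- lumped glycolytic/oxidative ATP supply: J_Gly = k_Gly·[ADP][P_i],
  consuming one free P_i and producing γ_gly H⁺ per ATP. The stoichiometric
  P_i debit is what makes P_i plateau around 30 mM once PCr is spent —
  without it P_i grows without bound;
- adenylate kinase: J_adk = k_adk·([ADP]² − [ATP][AMP]);
- P_i dilution: k_Pi,dil·[P_i];
- proton balance: net proton flux (in mM/s against the buffer) divided by
  the buffering capacity β_buf and converted through the pH relation,
  d[H]/dt = ln10·[H]·J_H/β_buf, plus a clearance flux
  J_Hclear = k_Hclear·(pH_rest − pH) lumping lactate/H⁺ co-transport and
  washout. Clearance gives the pH trajectory its observed shape — a fall to
  a quasi-steady level that recovers slightly as the ATPase flux fatigues;
  with buffering alone pH falls monotonically for as long as flux persists.

Adenine (ATP+ADP+AMP), creatine (PCr+Cr) and within-contraction occupancy
sums are conserved exactly by construction; integration keeps drift below
1e-6 over the full protocol.

## Protocol

60 cycles of 3-s contraction + 2-s relaxation. Cycle j starts with
P = iEMG_j and the attached states emptied; metabolites carry over from the
previous cycle. During relaxation, cross-bridge transitions are disabled
(states held) while the metabolic recovery fluxes continue — the protocol
never states how relaxation is handled, and this choice reproduces
between-contraction metabolite recovery without inventing a deactivation
transient. The per-cycle force summary is the contraction-phase peak (the
conventional MVC readout; a mean-force summary is available). The default
recruitment profile declines linearly 1.0→0.7 over the 60 cycles, the
observed ~30% iEMG decline; a measured profile can be supplied as CSV.

Integration is stiff LSODA (odeint) with rtol 1e-8 / atol 1e-10 and 0.01-s
output steps by default; rate constants span 1e-4 to 1e3 s⁻¹. Fits run at
rtol 1e-6 / 0.02-s output, which changes the per-cycle channels by ~1e-4 —
far below the instrument noise they are compared with.

## Parameters

The 22 fitted constants default to the published knee-extension estimates
(rates in s⁻¹, K's in mM except K_H⁺ in μM, stiffnesses in mN·mm⁻²·μm⁻¹,
metabolic constants in mM⁻¹s⁻¹; the printed s₃ = 0.1 nm is stored as 1e-4
μm). Structural constants close the model and are config-exposed:

| constant | default | role |
|---|---|---|
| Δr | 0.008 μm | power-stroke displacement in the force term |
| ρ_myo | 10 mM | couples cycle flux to bulk metabolite turnover |
| A_cs | 2300 mm² | scales specific force to joint force |
| β_buf | 90 mM/pH | lumped non-PCr proton buffering |
| γ_gly | 0.30 | H⁺ per glycolytic ATP |
| k_Hclear | 1.8 mM·s⁻¹·pH⁻¹ | proton clearance/efflux |
| resting pools | PCr 35, P_i 2.0, ATP 8.2, ADP 0.01, Cr 10 mM, pH 7.05 | initial conditions |

These were calibrated once, jointly, against the published summary
physiology of the protocol — first fully-activated cycle ≥ 550 N, ~16-fold
first-minute P_i rise, ~77% first-minute PCr depletion, ~300% proton rise
by two minutes, ~343 nM protons at five minutes — and then frozen. Resting
P_i = 2.0 mM (rather than the 3–5 mM literature range) is forced by
phosphate conservation: free P_i can only come from PCr breakdown (~27 mM
in the first minute) plus a small ATP drop, so a 16-fold rise and a ~30 mM
end-of-exercise level are only simultaneously consistent with a resting
level near 2 mM. ρ_myo is an effective coupling, not a literal myosin-site
concentration: with the ADP-throttled detachment rate the per-site cycle
flux is ~0.1–0.5 s⁻¹, and ρ_myo = 10 mM reproduces the whole-muscle ATP
turnover of ~1 mM/s that the PCr and P_i excursions demand. β_buf and
k_Hclear likewise absorb transport and compartment effects that the model
does not resolve.

## Calibration module

The objective is the max-normalized sum of squares over the four measured
channels (per-cycle peak force, end-of-cycle PCr, P_i and H⁺; observed pH
is converted to concentration, since the objective is written in H⁺ terms).
Minimization is trust-region-reflective least squares with box constraints,
restarted from log-uniform draws inside [0.01×, 100×] of the reference
values (the published procedure says only "random points within the sample
space"; two decades either way spans the spread between exercise-modality
fits). The search runs in log-parameter space, and the finite-difference
step (1e-3 relative) is set well above the ODE-solver noise floor —
with the default machine-epsilon step the Jacobian is integration noise and
the optimizer stalls at the start point. Noiseless self-generated data are
recovered to ≲0.2% from 10 restarts. With noise at the instrument scales,
the stiffness and metabolic rate constants remain identifiable (within
50%), while the dissociation constants are noise-dominated at desk-scale
problem sizes and wander; tests assert recovery only for the identifiable
set.

## Sensitivity module

S_i is the 1% central difference of end-of-protocol peak force, normalized
to x_i/F(x⁰). The output functional is the fatigue endpoint that all the
headline results discuss (a force–time-integral functional is a one-line
switch). The global analysis Latin-hypercube samples the ±10% box (10,000
samples at full scale; tests use 200 samples, a six-parameter subset with
well-separated sensitivities, and an 8-cycle protocol — the ranking
structure is established well before cycle 60). The strain parameters
α₁–α₃ and s₃ are exactly flat directions under isometric data and are
asserted as such, not fitted.

## Synthetic data

The generator emulates the instrumented protocol's end products: per-cycle
strain-gauge force and ³¹P-MRS metabolite samples at the 5-s cycle spacing,
with independent additive Gaussian noise at the published per-channel fit
residuals (42.6 N, 1.9 mM PCr, 2.0 mM P_i, 0.1 pH; pH noise applied in pH
space). Additive rather than proportional noise matches the absolute
per-channel residuals being emulated. What it deliberately does not emulate:
EMG/MRS signal processing, inter-subject variability, motor-unit
heterogeneity, and any model-misspecification component of real residuals —
so parameter-recovery tests demonstrate self-consistency of the pipeline,
not accuracy on real muscle.

## Problem sizes

Defaults follow the study protocol (60 cycles; 10,000 LHS samples; 100
restarts). The test suite runs reduced versions chosen as the smallest
sizes at which each property is cleanly expressed: 12–24-cycle observation
sets for calibration tests, 5–10 restarts, 200 LHS samples on an 8-cycle
protocol for rank conservation, and a 20×20 metabolite grid for
monotonicity.

## Known limitations

- The rapid-equilibrium closure uses single-site saturation with the
  printed dissociation constants. Its force–[H⁺] response keeps rising
  through the 0.3–0.7 μM range (K_H⁺ = 0.62 μM), where the original
  analysis shows signs of saturating: the simulated force loss when H⁺ is
  clamped at twice its end-of-exercise level is ~44% against the reported
  ~33%, and the recruitment-recovery fraction comes out ~19% against the
  reported 13% for the same reason (the force gap between constant and
  declining recruitment scales with the same proton lever).
- The reported positive modulation of A1 accumulation by P_i implies a P_i
  factor on the A1→A2 step; with the single shared K_Pi that factor roughly
  doubles the phosphate-doubling force loss, so it is omitted. In
  consequence the P_i-alone grid attribution is ~5% against the reported
  ~9%, and the A1 fraction is flat rather than increasing in the P_i
  state-fraction scan.
- Ca²⁺ handling, compartmentalized metabolite pools, motor-unit
  heterogeneity and free-energy (thermodynamic) effects are out of scope,
  as in the original analysis.
- Non-isometric protocols are structurally supported (first moments and
  strain factors are in place) but untested against data; under shortening
  the moment closure is an approximation, not exact.
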