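# Methods

## Model

The cell is four well-mixed compartments — cytosol (volume 0.7 pL), ER
(volume ratio `r_ercyt = V_cyt/V_er = 10`), mitochondria
(`r_mitcyt = 13.6`) and the extracellular space (ECS) treated as an
infinite bath at 1.3 mM free calcium.  All fluxes `J` are expressed as
rates of change of *cytosolic* concentration (µM/s, positive into the
cytosol).  The 15 dynamical states are: free Ca²⁺ in cytosol and ER, IP₃
and PIP₂, three myosin cross-bridge fractions (Mp, AMp, AM; M by
conservation), three retained IP₃R gate probabilities (X00, X01, X10; X11
by conservation), three retained RyR probabilities (R10, R11, R01; R00 by
conservation), and two clearance accumulators (sink → ECS, source ←
mitochondria) integrated as ODE states so they inherit solver error
control.

Free cytosolic calcium obeys

    dc/dt = (α_er J_er→cyt + α_mit J_mit→cyt + α_pm J_ecs→cyt + J_cyt→cyt) / b_cyt(c)

with the rapid-buffer factor `b_cyt = 1 + Σ K_i B_i/(K_i+c)²` over a
calmodulin-like and a lumped "other" buffer (b_cyt(0.1 µM) ≈ 101, i.e. ~1%
of a calcium increment stays free).  Total (free+bound) calcium is the
saturable form `c + Σ B_i c/(K_i+c)` whose derivative is exactly `b_cyt`;
this consistency is what makes the mass-balance audit exact.  The ER
equation is `dc_er/dt = −r_ercyt (α_er J_er→cyt)/b_er(c_er)` with dynamic
calreticulin-type buffering (two site classes).

The mitochondrial matrix free calcium is a *parameter*, not a state: the
model's premise is that dissolution/aggregation of calcium-phosphate
clusters is fast relative to membrane transport, clamping the matrix at its
saturation concentration while the clusters last.  The three
matrix-membrane pathways are a unidirectional MCU (Michaelis/allosteric
form with the 2.3-power allosteric term and the `e^{p₁ΔΨ}` voltage factor),
the NCLX exchanger `ν_nclx (Ca_mit/c) e^{p₂ΔΨ}`, and an Ohmic leak
`ν_leak (E_Ca,mit − ΔΨ_m)` with `E_Ca,mit = (RT/2F) ln(Ca_mit/c)`.
Membrane potentials (ΔΨ_m = 140 mV, φ_ecs = −54 mV) and sodium
concentrations are fixed; temperature is taken as 310 K (RT/2F ≈
13.357 mV), a choice corroborated by the NCX prefactor check below.

ER release uses a four-state IP₃R reduction (rapid-equilibrium IP₃ binding
with `k₁ = b₁/(a₁[IP₃])` on inactivation-free states and
`k₃ = b₃/(a₃[IP₃])` on inactivated ones; calcium activation proceeds from
the IP₃-bound fraction) and a four-state RyR with independent activation
(`K_r1 c²`/`K_-r1`) and inactivation (`K_r2 c`/`K_-r2`) site classes.  The
IP₃R channel conducts when ≥3 of 4 subunits are activated
(`P_open = X10⁴ + 4X10³(1−X10)`); RyR flux is `ν_ryr R10² (c_er − c)`.
SERCA is a two-state King–Altman cycle; written with `u = (c/K₁)²` and
`w = (K₃ c_er)²` its cycle rate is
`(k₂k₄u − k₋₂k₋₄w) / (uw(k₂+k₋₂) + u(k₂+k₄) + w(k₋₂+k₋₄) + (k₄+k₋₄))`,
which reproduces the published algebraic form term by term.

Myosin follows the Hai–Murphy four-state latch scheme with
`K₁ = K₆ = γ c³`; tension is reported as `Fr = AMp + AM`.  By default the
myosin cycle is a *readout*: its calcium consumption flux
`J_cyt→cyt = −s·[Myo]·d(Mp+AMp)/dt` is controlled by the stoichiometry
parameter `s = myosin_ca_stoich`, default 0.  See "Design choices" below.

## Calibration

Three constants close the resting fixed point (c = 0.1, c_er = 500,
Ca_mit = 0.1, all µM):

* `ν_mit_leak = (J_mcu + J_nclx)/ΔΨ_m ≈ 8.84×10⁻³ µM s⁻¹ mV⁻¹` — the
  calcium Nernst potential vanishes at rest, so the leak cancels NCLX
  extrusion plus MCU uptake exactly.
* `Q_ncx ≈ 3.708×10⁶ µM/s` — the NCX prefactor carrying the plasma-membrane
  imbalance `−(J_vocc + J_pmca + J_ecs,leak) ≈ −0.0107 µM/s` at rest.  This
  calibrated value agrees to 0.2% with the dimensional reading
  `k_ncx2/(2 F V_cyt)` of the literature prefactor (0.5 µA / (2·96487
  C mol⁻¹·0.7 pL) = 3.70×10⁶ µM/s), an independent confirmation of both the
  NCX functional form and the 310 K temperature choice.
* `serca_scale ≈ 5.28×10⁻³` — multiplier on the SERCA cycle so uptake
  balances the resting IP₃R + RyR release (≈ 0.224 µM/s).  The balance is
  absorbed into SERCA rather than the release channels because the gating
  constants trace to the channel literature while the pump concentration is
  a model-specific choice; scaling the release up to the raw pump magnitude
  instead (a ≈ 190-fold increase) produces unphysiological 100-µM
  oscillations and was rejected.

IP₃/PIP₂, gate and myosin fixed points are closed-form or 4×4 stationary
solves (independent of the ODE right-hand sides, which the tests
cross-check to 10⁻¹⁰).  The assembled rest state has residual
< 10⁻⁹ (natural units/s; observed ~2×10⁻¹⁵).  Because every compartment
aggregate is zero at rest, any rescaling triple (α_er, α_mit, α_pm) — each
aggregate multiplied by its α wherever it appears, which keeps the audit
exact — preserves the fixed point.

## Numerics

`scipy.integrate.solve_ivp` with LSODA; rtol 1e-7, atol 1e-9 µM for
concentrations/accumulators and 1e-12 for fractions (the state spans five
orders of magnitude).  The nominal literature tolerance of 1e-6 leaves
~1.3×10⁻⁴ µM of mass-balance drift over a 30-minute oscillatory run in this
stack; one extra decade brings it to ~2×10⁻⁵ at no measurable runtime cost
and changes no reported quantity (clearance agrees to six digits).  Rate
laws are numba-compiled; a 30-minute run takes ~0.1 s, so the full 9×9×9
rescaling sweep (729 runs) completes in ~3 minutes on one CPU.  A 10⁻⁶ µM
floor guards the NCLX ratio and Nernst logarithms inside the kernels (never
reached in nominal runs; `simulate` warns if it is).  Scalar API calls
raise on non-positive inputs instead.

Oscillation classification discards a 600-s transient (the observed
settling time constant near onset is ~3 min) and, for the scan and sweep,
uses the trailing 600-s window of the 1800-s protocol.  A run is
oscillatory when the half peak-to-trough amplitude of Ca_cyt exceeds
10⁻³ µM (1% of rest) *and* the Hann-tapered, 4× zero-padded periodogram has
a peak ≥ 10× the median power *and* the implied period fits at least twice
into the window — the last condition rejects slow settling trends that
would otherwise masquerade as long-period oscillations in cells whose α
rescalings slow every flux tenfold.  Peak frequency is refined by parabolic
interpolation (period error < 5% for noisy synthetic sinusoids across
5–300 s periods).  Period averages integrate over the largest whole number
of cycles fitting the window (trapezoid rule), or the full window for
quiescent runs.

The Hopf threshold is located by bisection on the classification between
the last quiescent and first oscillatory grid point, to a bracket of
0.005 µM, with full 1800-s simulations per probe.  Near the bifurcation the
amplitude criterion necessarily places the classified onset slightly above
the linear-stability boundary; with the default settings the onset resolves
at ≈ 0.227 µM (leading Jacobian eigenvalue crosses zero at ≈ 0.225 µM).

## Design choices

* **Myosin–calcium coupling (`myosin_ca_stoich`, default 0).**  The printed
  reaction flux (one calcium sequestered per phosphorylated head, with a
  "three calcium" stoichiometry mentioned in prose) makes the myosin cycle
  the dominant damping term near rest — its Jacobian contribution
  (−[Myo]·3γc²·(M+AM)/b_cyt) exceeds the NCLX term — and with it the model
  has *no* Hopf bifurcation at any matrix calcium (leading eigenvalue peaks
  at −0.006 s⁻¹): no oscillations, contradicting the documented dynamics
  and the stated intent that myosin be "small" relative to the other
  buffers.  With the coupling off, the bifurcation, the growth of amplitude
  with Ca_mit, and the quiescent/oscillatory bracket at 0.20/0.30 µM all
  appear in the right place.  The default therefore treats myosin as a
  contraction readout; setting the stoichiometry to 1 (or 3) restores the
  printed coupling for sensitivity studies, and the mass-balance audit uses
  the same parameter so conservation is exact in every configuration.
* **Total-calcium form.**  The saturable form consistent with the buffering
  factor is used throughout; the variant with an extra dissociation-constant
  factor is not the antiderivative of `b_cyt` and would break the audit.
* **Eliminated gate states.**  X11 = 1−X00−X01−X10 and R00 = 1−R10−R11−R01;
  the RyR state naming (R10 activation-bound, R01 inactivation-bound) is
  fixed by detailed balance against the enforced steady-state occupancies.
* **ATP stoichiometry.**  `atp_rate = protons_per_Ca · J_mit→cyt / 3` with
  `protons_per_Ca` configurable (default 2: each liberated phosphate and
  hydroxide associates with protons; the exact cluster stoichiometry is
  unsettled).  The sign follows the flux: matrix emptying supports ATP
  production, refilling opposes it.

## Synthetic signals in the tests

Oscillation-analysis tests use constructed trajectories (known sinusoids,
offsets, 10% additive noise) rather than model output, so period and
amplitude recovery is checked against exact ground truth; model-based tests
then only need classification, not waveform regression.  These synthetic
signals share none of the model's stiffness or multi-timescale structure —
they validate the analysis pipeline, not the physiology.

## Known limitations

* With uptake and release calibrated to balance at rest, IP₃R release
  (∝ X10³, effectively ∝ c³ with IP₃ feedback) outgrows SERCA uptake
  (∝ c²) at elevated cytosolic calcium, so the ER *drains* toward a lower
  quasi-steady level (~70 µM free at Ca_mit = 0.25 µM) rather than loading;
  cumulative mitochondrial release therefore trails cumulative efflux even
  though the period-averaged mitochondrial flux at 30 minutes is directed
  out of the matrix.  The oscillatory window closes again above
  Ca_mit ≈ 0.38 µM.
* Fixed membrane potentials, fixed sodium, no pH/phosphate speciation, no
  nucleation kinetics, no ATP depletion, no spatial coupling — the model is
  a single well-mixed cell.
* The contraction readout is the latch fraction only; vessel radius would
  additionally depend on pressures and wall mechanics.
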