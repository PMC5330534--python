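# Methods

`astrosim` simulates glutamate-evoked calcium signaling in a single
cylindrical astrocyte compartment in which two routes feed the cytosolic
Ca²⁺ pool:

* the **store-release (mGluR) pathway** — glutamate binding to metabotropic
  receptors drives PLCβ-mediated IP₃ production; IP₃ and Ca²⁺ gate the
  IP₃-receptor channel of the endoplasmic reticulum (Li–Rinzel gating),
  balanced by SERCA uptake and a passive ER leak; and
* the **transmembrane (GluT) pathway** — glutamate uptake by the glutamate
  transporter loads the compartment with Na⁺ (3 Na⁺ per cycle, 1 K⁺ out,
  net +2 charge), the Na⁺/K⁺-ATPase counteracts the load, and the Na⁺/Ca²⁺
  exchanger (3 Na⁺ : 1 Ca²⁺), pushed into reverse mode by the Na⁺ rise,
  admits Ca²⁺ across the plasma membrane.

The relative weight of the two routes is set by the geometry: the ER volume
fraction `ratio_er` scales every store flux seen by the cytosol, and the
surface-to-volume ratio `SVR` scales every membrane flux. Perisynaptic
processes are thin (high SVR, little or no ER); the soma is the opposite.
An empirical anatomical map, `ratio_er(SVR) = 0.15·exp(−(0.002·SVR)^2.32)`,
is provided as a convenience; experiments may also pin SVR and sweep
`ratio_er` independently.

## State, balances, units

The dynamical state is (Ca_i, Ca_ER, Na_i, K_i, V, IP₃, h) plus the
synapse variables (x, y, g). Ca²⁺/IP₃/glutamate are in µM, Na⁺/K⁺ in mM,
V in mV, currents in pA/µm². A membrane current density I contributes
`SVR·10⁹/F · I` µM/s to an intracellular concentration (the single unit
conversion of the package, `geometry.membrane_rate_factor`; ≈1.0364·10⁴
µM/s per pA/µm² at SVR = 1 µm⁻¹). Ion stoichiometry is folded into the
summed currents of each balance, exactly as the source model writes them:

* dCa_i/dt = conv·I_NCX + ratio_er·(J_IP3R − J_Serca + J_leak)
* dCa_ER/dt = −(J_IP3R − J_Serca + J_leak)
* dNa_i/dt = conv′·(3 I_GluT − 3 I_NKA − 3 I_NCX − I_Na,leak)
* dK_i/dt = conv′·(−I_GluT + 2 I_NKA − I_K,leak)
* dV/dt = −(1/C_m)·(−2Ĩ_IP3R + 2Ĩ_Serca − 2Ĩ_CERleak + I_NCX − 2 I_GluT
  + I_NKA + I_Na,leak + I_K,leak)

ER fluxes J are volumetric rates (µM/s): their F·Vol/A current prefactor is
cancelled analytically against the A/(F·Vol) of the balance; the voltage
equation converts them back through the same factor (Ĩ = J/conv). Positive
I_NCX raises cytosolic Ca²⁺ (reverse mode); the exchanger current vanishes
exactly at the closed-form reversal `Ca_i = Ca_o·(Na_i/Na_o)³·exp(VF/RT)`.

Extracellular Ca²⁺/Na⁺/K⁺ are not independent states: with equal intra-
and extracellular volumes and fixed total content they mirror the
intracellular pools algebraically at every step (the Ca²⁺ constraint also
credits store depletion to the extracellular pool, as printed in the source
model, which makes it the one balance that is not strictly conserving).

## Stimulus

Poisson spike trains (homogeneous, seeded, reproducible) drive a
Tsodyks–Markram synapse: recovered fraction x, utilization y, cleft
glutamate g. The δ-spike terms are applied as discrete impulses at
grid-snapped spike times — facilitation first (y += U₀(1−y)), then release
with the post-update y (r = x·y; x −= r; g += ρ_C·G_T·r) — and the three
variables decay exponentially between spikes. Two spikes landing in one
1 ms bin collapse to one (counted and logged). Constant-glutamate and
explicit spike-list protocols bypass or feed the same machinery.

The published synapse table prints its three time constants with
inverse-second units. Read as *rates* (τ_facil = 0.5 s, τ_rec = 1 s,
τ_clear = 1/60 s ≈ 17 ms) the model produces tens-of-µM cleft transients,
commensurate with the transporter's 34 µM glutamate affinity; read as
*seconds* (τ_clear = 60 s) the cleft integrates to millimolar levels and
saturates both pathways. The rate reading is the default
(`tm_taus_are_rates=True`); the alternative remains selectable.

Two constants of the synapse/membrane are not published: `G_T` defaults to
200 mM so that ρ_C·G_T = 130 µM (a single full release yields a ~32.5 µM
transient), and `C_m` defaults to 1.0 pF/µm² (below).

## Calibration

`calibrate_rest` derives the rest state from the stated zero-derivative
conditions rather than trusting the published initial values, because those
are not mutually consistent with the published rate constants:

* IP₃_rest: bracketed 1-D root of the production/degradation balance at
  zero glutamate (0.15659 µM at Ca_i = 0.073 µM — this one the published
  table reproduces to all printed digits);
* h_rest = h_inf(Ca_rest, IP₃_rest);
* Ca_ER_rest: ER flux balance J_IP3R + J_leak = J_Serca, linear in Ca_ER
  (≈ 8.77 µM). The published initial value, 25 µM, equals the same balance
  evaluated with SERCA at its *maximal* rate (Hill factor dropped) and is
  available as `store_init="printed"`;
* g_Na_leak, g_K_leak from dNa_i/dt = 0 and dK_i/dt = 0 at rest
  (≈ 0.0135 and 0.1514 nS/µm²). The published conductances (0.0065,
  0.0791) equal the same formulas evaluated with half the published NKA
  maximal current and are reproduced by `calibration="printed"`;
* with an active exchanger, resting Ca_i is placed at the NCX reversal
  point (≈ 0.0828 µM instead of the published 0.073 µM). The model has no
  plasma-membrane Ca²⁺ leak, so a finite resting NCX current cannot be
  cancelled; at the reversal point *every* derivative vanishes, and the
  calibrated rest is an exact fixed point (enforced to a scaled residual
  of 10⁻⁹).

Pathway toggles (`mglur_only`, `block_glut`) recalibrate the leaks, so
every experiment starts at its own rest with a flat unstimulated baseline.

The store load deserves emphasis: with membrane currents silenced,
Ca_i + ratio_er·Ca_ER is an exact invariant, so the *initial* ER load is a
study condition, not a numerical detail. The default is the balanced
(stationary) load; `store_init="printed"` reproduces the larger published
load, at the price of an initial store-drain transient.

## Numerics

The reference scheme is forward Euler with dt = 1 ms, the scheme of the
source model. Stability is governed by the fastest mode, the membrane
voltage: the calibrated leaks total Σg ≈ 0.165 nS/µm², so τ_V = C_m/Σg.
With the textbook 0.01 pF/µm² (1 µF/cm²), τ_V ≈ 0.1 ms and Euler at 1 ms
diverges violently; no printed capacitance exists for this model, and V is
slaved to the conductances on every slower timescale, so C_m acts purely as
a numerical relaxation constant. The default C_m = 1.0 pF/µm² puts
τ_V ≈ 6 ms — resolved by the grid, still far below the seconds-scale ion
dynamics. Halving dt changes 5-s endpoints by <1%, and the Euler engine
agrees with an adaptive stiff integrator (LSODA, rtol 10⁻⁸) running the
identical RHS to within 2% on 5-s runs (both are tests).

The integrator aborts with a diagnostic (step index and cause) rather than
emitting garbage if an extracellular pool is driven to zero, an
intracellular cation goes non-positive, or any state becomes non-finite or
exceeds 10⁹. There is exactly one RHS implementation (a numba kernel); the
test suite cross-checks it against an independent assembly built from the
pure per-flux functions.

## Trace analysis

* **Oscillation detection**: after discarding a 20 s settle window, Ca_i
  peaks and troughs are found by prominence (≥ 0.05 µM); the trace counts
  as oscillating with ≥ 2 prominent peaks and troughs and a mean
  peak-to-trough excursion ≥ 0.05 µM. Frequency = peak count / analyzed
  duration (time-reversal invariant; no spectral estimate). Both thresholds
  are exposed; the source model states no criterion, so these are package
  choices validated on synthetic sines.
* **Onset** (`critical_ratio_er`): smallest grid value of `ratio_er` at
  which a majority of Poisson-seed replicates oscillates.
* **Na⁺ saturation**: ΔNa = final − resting Na_i; t_sat = first time after
  which Na_i stays within 1% of |ΔNa| of its final value.
* **Block reduction**: 100·(⟨Ca⟩_ctrl − ⟨Ca⟩_block)/(⟨Ca⟩_ctrl − Ca_rest)
  with matched spike trains; undefined (NaN) when the control does not rise
  above rest.

## Fidelity to the published results

What the packaged defaults reproduce, as measured by the test suite and
`scripts/acceptance.py`:

* resting IP₃ 0.15659 µM and gate fraction 0.7892 to all printed digits;
* the SVR-map limit 0.15 exactly;
* transporter-block attenuation ≈ 94% (published: 97%) at ratio_er = 0.03,
  I_NCX_max = 0.5 pA/µm²;
* the qualitative structure throughout: no Ca²⁺ response without store and
  exchanger, elevated non-oscillating Ca²⁺ below onset, amplitude growing
  with ratio_er, no onset at 5 Hz stimulation and a rate-independent onset
  from 20–100 Hz, store depletion and extracellular Ca²⁺ accumulation
  (≈ +4.8 µM) under a strong exchanger.

What the printed equations do **not** reproduce — these checks are kept at
their published values and fail honestly:

* the oscillation onset at ratio_er = 0.06: the balanced store yields
  ≈ 0.14, and the published 25 µM store suppresses oscillations entirely
  (Ca locks at an elevated stable point with the IP₃R inactivated);
* the Na⁺ loading window of 10–20 mM under constant 100 µM glutamate: the
  fully-specified balance gives ≈ 5.6 mM, because the 1:1 extracellular
  mirror raises K_o from 3 to ≈ 8 mM and the stimulated Na⁺/K⁺-ATPase
  clamps the load (without the mirror the same balance gives ≈ 35 mM —
  the published window lies between the two variants of its own
  assumptions); saturation time (≈ 2.5 s) is comfortably below the
  published 60 s bound;
* the intracellular Ca²⁺ elevation of ≈ 0.1 µM under a strong exchanger:
  measured ≈ 0.014 µM, a direct consequence of the small Na⁺ excursions
  above.

## What the synthetic stimulus does and does not emulate

Poisson trains with short-term depression/facilitation capture mean rate,
burst statistics and vesicle depletion of a single afferent, but not
multi-synapse convergence, receptor desensitization, or transmitter
spillover geometry. Passing tests therefore demonstrate correctness of the
model mechanics under the stated drive, not quantitative prediction of
in-situ astrocytic signals.

## Known limitations

Single compartment (no Ca²⁺ diffusion, no astrocyte networks); no
GluT-coupled anion conductance; H⁺ and Glu⁻ pools are not tracked; the
extracellular space is a 1:1 closed mirror rather than a buffered bath;
fixed-step Euler is the reference integrator by design, with the adaptive
integrator reserved for validation.
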