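# Methods

## The model

`camkinet` implements a rule-based kinetic model of the proteins that
control CaMKII autophosphorylation in the postsynaptic density (PSD):
calcium, calmodulin (CaM), neurogranin (Ng), CaMKII and protein
phosphatase 1 (PP1), in a single well-mixed compartment of volume
V = 0.0156 μm³ (≈ 9.39 molecules per μM).

Calmodulin carries two Ca²⁺ sites on each of its two lobes; sites within a
lobe are indistinguishable, so a CaM molecule occupies one of nine
occupancy states (0–2 C-lobe × 0–2 N-lobe ions). Stepwise Ca²⁺ on/off
rates differ between free CaM and CaMKII-bound CaM. Ng binds only
calcium-free, unbound CaM (binding to Ca²⁺ and to Ng are mutually
exclusive), sequestering it with K_d = koffNg/konNg = 0.2 μM. CaM binds
CaMKII with state-dependent affinity (weak for apo-CaM, strong for
4-Ca²⁺ CaM); a CaM-bound subunit is in the active conformation. An active
kinase phosphorylates a CaM-bound, Ca²⁺-loaded substrate at a rate indexed
by the *substrate's* CaM state (no rate exists for a substrate whose CaM
carries zero Ca²⁺). A phosphorylated (T286/7) subunit stays active after
CaM dissociates, releases CaM slowly (kp,offCaM = 0.07 s⁻¹) and rebinds it
with its own rate set. PP1 dephosphorylates via an explicit
enzyme–substrate complex parameterized to reproduce the printed
Michaelis–Menten constants (k_cat = 0.41 s⁻¹, K_m = 11 μM). The T305/306
site, subunit exchange, holoenzyme disintegration, compact/dimerized
subunit conformations and spatial structure are all outside the model.

Two model variants share this rule set:

* **Monomer model (deterministic).** Truncated CaMKII monomers at 80 μM.
  Autophosphorylation requires two CaM-bound monomers to form a transient
  dimer (konCaMKII/koffCaMKII); inside a dimer either member may be
  phosphorylated by the other, after which the dimer dissociates at the
  same koffCaMKII. The rule set is expanded by fixpoint closure into a
  concrete network (214 species, ~1.5k reactions) and integrated with a
  stiff ODE solver (LSODA).
* **Holoenzyme model (stochastic, network-free).** 63 complete dodecamers
  (756 subunits; 80 μM rounds to 752 monomers, which is not divisible
  by 12 — we keep every holoenzyme complete and report both numbers).
  Each holoenzyme is two independent rigid hexameric rings; the kinase at
  ring position *i* can phosphorylate only position *(i+1) mod 6* of the
  same ring. A kinase is active when CaM-bound (any calcium load) or
  phosphorylated. Simulation is an exact Gillespie SSA over discrete
  agents; event channels are grouped by rule-instantiation class and a
  participant is drawn uniformly within the selected class, which is
  probabilistically identical to one channel per concrete event pair.

## Dimer and complex conventions (monomer model)

Dimers are unordered pairs of CaM-bound monomers. Within a dimer, calcium
exchange on the members' CaM continues (CaMKII-bound rates) and either
unphosphorylated member with ≥1 Ca²⁺ may be phosphorylated; CaM does not
dissociate from a dimer member (the complex is short-lived,
koffCaMKII = 60 s⁻¹, so the omitted pathway is negligible) and PP1 engages
phosphorylated monomers only outside dimers. Reactions between two copies
of the same species carry the standard 1/2 mass-action symmetry factor;
symmetric rule embeddings (e.g. calcium binding to either member of a
symmetric dimer) carry their multiplicity. While a PP1·substrate complex
exists, the substrate's CaM is frozen; the complex resolves in ~10 ms
(koffPP1 + kcat ≈ 110 s⁻¹), so this freeze is inconsequential.

Calcium binding to CaM on *phosphorylated* CaMKII reuses the
CaMKII-bound-CaM calcium rates: the rate table distinguishes binding
context, not phosphorylation state, for calcium kinetics. The two sites
within a lobe are treated as a count with the printed stepwise constants
used as-is (no additional ×2 statistical factor).

The phosphatase rule tests only the substrate's phosphorylation flag, so
PP1 also engages phosphorylated monomers that are momentarily inside a
kinase–substrate dimer; because the pair dissociates in ~17 ms (and at
high CaM occupancy most monomers are paired at any instant), this access
matters quantitatively. It is modeled as capture-with-displacement — the
PP1·substrate complex forms and the partner is released — rather than by
tripling the dimer state space with an in-complex phosphatase flag.

## Dose–response setup

CaM dose–response scans fix **total** calcium (default 10 μM) in a closed
system: calcium is conserved, so its partitioning shifts with total CaM —
at sub-μM CaM every calmodulin is heavily loaded, while at very high CaM
the per-molecule load (and the free-calcium level) collapses and apo-CaM
dominates. This is what produces the characteristic dose–response
features: the crossover of the 3/4-Ca²⁺ CaM curves with vs without Ng,
the low-CaM phosphorylation peak driven by fully loaded CaM (larger and
more prominent with Ng, which keeps the Ca²⁺:free-CaM ratio high), the
second peak driven by 1–2-Ca²⁺ CaM, and the decline of steady-state
phosphorylation toward zero at ultra-high CaM. A free-calcium *clamp* is
used only for resting-baseline equilibration (the cell holds ~100 nM);
clamping free calcium at 10 μM would make per-CaM occupancy independent
of total CaM and erase all of these features. The n-Ca-bound CaM classes
count calmodulin in any binding context (free, CaMKII-bound, in dimers),
since nearly all calcium-loaded CaM is kinase-bound when CaMKII is at
80 μM.

## Calcium inputs

Pulses inject calcium with the envelope A·((t−t₀)/τ_R)·e^(−(t−t₀)/τ_F)
(defaults τ_R = 5 ms, τ_F = 15 ms); overlapping envelopes sum. Free
calcium leaves by first-order efflux k_e·[Ca] and a constant influx
k_e·baseline maintains the 100 nM resting level. No explicit buffer
molecules exist; CaM/Ng/CaMKII provide all buffering, so the amplitude A
is calibrated per condition by bisection on the deterministic model until
the free-calcium peak reaches the 10 μM target (tolerance 2%).

The efflux default is k_e = 1000 s⁻¹. The decisive constraint is the
shape of the free-calcium transient: a ~10 μM peak that returns near
baseline on the 100 ms scale. After a calibrated spike the tail of free
calcium is fed by calcium re-released from CaM C-lobes (koff2C ≈ 9.3 s⁻¹,
koffK2C ≈ 2.4 s⁻¹), so the tail level is approximately (release flux)/k_e:
at k_e = 100 s⁻¹ free calcium is still ≈ 1.7 μM (17× baseline) 100 ms
after the peak, whereas at 1000 s⁻¹ it is below 1 μM at 100 ms and within
2× baseline by ≈ 0.2 s. No first-order efflux meets the literal
100 ms/2×-baseline window because bound-calcium release is rate limiting;
each calibration therefore measures and reports its actual return time
(`CalibrationResult.return_time`, `decay_ok`). The train-response
capacity k is sensitive to this choice because the post-spike calcium
tail sets how long substrates remain phosphorylation-competent.

In the SSA the influx channel is time-inhomogeneous and simulated by
thinning: each pulse envelope is bounded by its analytic peak
A·(τ_F/τ_R)·e⁻¹ before the peak time and by its current (strictly
decreasing) value after it; steps never cross a pulse onset. The
buffer-free simulator reproduces the analytic filtered-Poisson mean to
within sampling error.

## [PP1] default

The paper-scale analyses require a PP1 concentration that no table
provides. The repository default is **1.25 μM**. Two independent
considerations support it: (i) the single-spike phosphorylation lifetime
of the monomer model comes out at ~115 s, i.e. "on the order of minutes";
(ii) at a leaky-integrator plateau the leak a·k must equal the
Michaelis–Menten rate kcat·[PP1]·k/(K_m+k), and inverting this for the
published fit pairs (k = 7.24, a = 0.025) and (k = 0.36, a = 0.045) gives
[PP1] ≈ 1.1 and ≈ 1.25 μM respectively. All PP1-dependent results depend
on this default; it is exposed in the configuration.

## Numerical choices

The reaction network compiles to sparse stoichiometry with an analytic
sparse-assembled Jacobian. Time courses use LSODA with the analytic
Jacobian and a step cap of τ_R/2 while a pulse envelope is active (so the
stiff solver cannot step over a millisecond transient); steady-state
relaxations use BDF in doubling time chunks until the maximum derivative
falls below 10⁻⁹ (clamped equilibration, polished by a damped Newton root
solve when it converges to a non-negative state) or 10⁻⁷ (closed-system
dose–response points, integration only, since conservation laws make the
Jacobian singular at the fixed point). Clamped-calcium equilibration
treats free calcium as an algebraic constraint: its derivative is zeroed
and the implied total calcium is reported as an output. Concentrations
are clipped at zero on output; reactions between two copies of one
species carry the ½ mass-action symmetry factor.

## Initial states and burn-in

Stochastic runs draw CaM occupancies (free state, Ng-bound, subunit-bound)
from the deterministic 100 nM-clamp equilibrium marginals, place bound CaM
on uniformly chosen subunits, draw the free-calcium count from a Poisson
distribution at baseline, and then relax for a 3–5 s SSA burn-in before
the protocol starts. All randomness derives from a single integer seed;
identical (state, protocol, seed) reproduce trajectories bit-identically.

## Analysis conventions

Responses are baseline-subtracted (mean over the pre-stimulus window) and
time-referenced to the first pulse onset. AUC uses the trapezoid rule;
the lifetime is the post-peak time to 10% of the peak with linear
interpolation between samples, censored at the record end when the level
is not reached. A stochastic run is a *responder* when at least one
phosphorylation event fires during the protocol (threshold configurable).
Single-spike ensembles average responders only; train ensembles average
all runs. The train response is fit by nonlinear least squares to
x(t) = k(1 − e^(−a·t)) from the first onset to shortly after the last
pulse (the fitted form is monotone, so the post-train decay is excluded);
R² is computed on the fitting grid with uniform weights, matching a
default curve-fitting tool. Per-run free-calcium peaks are the running
maxima of the discrete ion count; they exceed the deterministic
calibration target by ~1 μM on average because the maximum of a
fluctuating count is biased upward — the same effect visible in published
stochastic peak reports.

## Problem sizes

Deterministic dose–response scans use ~25 CaM values from 0.1 μM to
100 mM, dense around the first phosphorylation peak (2–10 μM) and
logarithmic elsewhere. Stochastic ensembles use 30 runs for
single-spike responder statistics, 10 runs for 10-pulse trains and 12–30
runs for 30-pulse trains (12 in the test suite, 24 in the acceptance
script); capacity/rate estimates stabilize to a few percent at these
sizes. A 30-pulse train run simulates ~75 s of biology and ~1–2 million
events.

## What the synthetic inputs do and do not emulate

The protocols reproduce the amplitude, duration and frequency structure
of spine calcium transients (100 nM rest, ~10 μM peaks decaying on the
100 ms scale, 0.5 Hz trains) but not their biophysical origin: no NMDA
receptor or voltage-gated channel kinetics, no explicit endogenous
buffers or extrusion pumps, no diffusion or spine geometry, and no
trial-to-trial amplitude variability beyond intrinsic molecular noise.
Passing tests therefore validate the signaling network's response to
idealized inputs, not the upstream calcium machinery of real spines.

## Known limitations

* The capacity k of the train response varies severalfold with the
  calcium-tail assumption (see the k_e discussion); quantities that
  depend on integrated calcium exposure inherit this uncertainty.
* The monomer model's phosphorylation lifetime (~2 min) exceeds
  fluorescence-derived spine time constants, as expected for a model
  without spatial organization or additional inactivation pathways.
* CaM unbinding from dimer members and PP1 action inside dimers are
  omitted (negligible at koffCaMKII = 60 s⁻¹ but formally absent).
* Baseline holoenzyme phosphorylation is effectively zero; basal
  phosphorylation in the monomer model arises only through transient
  dimers and is small (~0.3 μM at 30 μM CaM).
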