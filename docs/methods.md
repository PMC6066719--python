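# Methods

`fracatrial` simulates atrial action-potential propagation over a
structurally heterogeneous myocardium modeled as a discrete-scale-invariant
fractal. This note documents the model, the numerical scheme, the choices
made where the problem statement was open, and the known limitations.

## Model

The monodomain equation with a complex fractional order:

    dV/dt = kappa * (Hx^gamma V + Hy^gamma V) - I_ion + I_stim

with `gamma = alpha + j*beta`, `1 < alpha <= 2`, `beta >= 0`. The operator
`H^gamma = -1/2 [(-d^2/dx^2)^(gamma/2) + (-d^2/dx^2)^(conj(gamma)/2)]` is a
complex-conjugate pair of fractional Laplacians. Its Fourier symbol is real:

    s(k) = -|k|^alpha * cos(beta * ln|k|),     s(0) := 0.

`alpha` plays the role of a fractal dimension of the tissue (alpha = 2,
beta = 0 recovers classical diffusion over a homogeneous continuum); `beta`
is a log-periodic correction that appears when the self-similarity of the
medium holds only at discrete magnification factors. Increasing
heterogeneity (smaller alpha, larger beta) weakens high-wavenumber
diffusion, which slows the wavefront, abbreviates the action potential, and
destabilizes reentrant rotors.

The reaction term is the Courtemanche-Ramirez-Nattel (CRN) human atrial
membrane formalism — 21 state variables, 12 membrane currents — transcribed
from the original 1998 publication with currents expressed per unit
capacitance (pA/pF, C = 100 pF). Chronic-AF (CAF) electrical remodeling
multiplies g_to and g_CaL by 0.65, the g_Kur scale by 0.49 and g_K1 by 2.1,
and adds the acetylcholine-activated potassium current I_KACh (Kneller
dose-response, [ACh] in micromolar inside the fit; the interface takes
nanomolar) at 5 nM.

Two conventions of the cellular model deserve emphasis:

* **Na+/K+ clamp.** Intracellular Na+ and K+ are held constant by default
  (`IonicParameters.clamp_na_k`), the standard practice for long
  AF-substrate simulations; it suppresses the slow ionic drift that
  otherwise accumulates over minutes of pacing. With the clamp the
  CAF-remodeled cell paced for 60 s at BCL 400 ms reads APD90 = 94.6 ms and
  diastolic V = -84.6 mV; without it, 82 ms. Set `clamp_na_k=False` for the
  fully conservative formulation.
* **Rate adaptation.** The CRN model intrinsically shortens APD at fast
  rates: at BCL 400 ms the non-remodeled cell settles near APD90 = 263 ms,
  while a single beat from rest gives 304 ms and BCL-1000 pacing 297 ms.
  Single-cell numbers must therefore always be quoted with their pacing
  protocol.

## Numerical scheme

* **Space.** Semi-spectral: fields live on a uniform grid (reference strand
  L = 2 cm, N = 128; reference sheet 128 x 128 at dx = 321.5 um; the
  "reduced sheet" used for desk-scale rotor work is 64 x 64 at 643 um).
  Zero-flux boundaries are realized by the half-sample even (mirror)
  extension, i.e. a type-II DCT per axis. Diffusion advances each cosine
  mode by the exact exponential factor `exp(kappa * s(k) * dt)`
  (unconditionally stable for s <= 0, mean-conserving since s(0) = 0).
* **Dealiasing.** The tissue scheme zeroes the top third of the cosine
  spectrum per axis (the 2/3 rule; `lowpass_frac = 2/3` in the configs).
  Besides standard dealiasing of the stiff reaction coupling, this sets the
  stability bound on beta (below). Pass `lowpass_frac=None` for the
  unfiltered operator; the operator-level API (`apply_H`,
  `spectral_symbol`) is always unfiltered.
* **Wavenumber unit.** Because `cos(beta ln|k|)` is not scale-free, the
  unit of k is part of the model. The pure operator uses rad/cm. The tissue
  configurations default to `k_scale = 2` (wavenumbers in rad per
  half-centimetre): this is the convention under which the published
  diffusivity calibration — kappa = 0.40 cm^2/s giving a 63 cm/s plane wave
  in the non-remodeled strand at gamma = 2 — is reproduced, and it
  simultaneously reproduces the entire beta = 0 CAF conduction-velocity
  table to within a few percent. It is an inference from the published
  calibration, exposed as a config field precisely so its sensitivity can
  be probed.
* **Stability of the imaginary order.** The propagator contracts iff
  `cos(beta ln|k|) >= 0` on every retained mode, i.e.
  `beta <= beta_max = (pi/2) / max|ln|k||`. On the reference strand under
  the tissue convention this gives beta_max = 0.2809; on the sheet, 0.3226.
  The package's simulations therefore cap beta at 0.28. In plain rad/cm
  units the sheet bound is 0.343.
* **Time.** Operator splitting at dt = 0.01 ms: Lie (reaction first, then
  diffusion), with Strang available behind `splitting="strang"`. The
  reaction step advances V and the five concentrations by forward Euler and
  the fifteen gates by Rush-Larsen exponential relaxation. Pure forward
  Euler on the gates is not an option at this dt: the fast Na+ gate's rate
  sum exceeds 2/dt below about -86.6 mV, so any hyperpolarizing ripple
  (e.g. spectral ringing at a stimulus edge) makes the gate oscillate
  divergently. Rush-Larsen is unconditionally stable and changes the
  single-cell and strand benchmarks by less than 0.5%.
* **Determinism.** There is no random number generator anywhere in the
  simulator; identical configurations give bit-identical results. The
  acceptance script takes `--seed` for interface uniformity only.

## Protocols and biomarkers

* **Diastolic threshold**: bisection (1% relative) on the amplitude of a
  2-ms left-edge pulse; capture = a node >= 1 cm away crossing -40 mV. All
  protocol stimuli use twice this threshold.
* **Single-cell pacing**: 60 s at BCL 400 ms; the final state is the tissue
  initial condition (every node identical).
* **Strand measurements**: activation = upward -40 mV crossing
  (interpolated, 50-ms lockout); APD90 relative to the pre-upstroke
  diastolic V; CV between the nodes at L/3 and 2L/3; strand APD maps pace
  the left edge at BCL 1000 ms for 10 s and read the middle cell's last
  beat. APD dispersion profiles drop five nodes at each end to suppress
  mirror-boundary artifacts.
* **Cross-field S1-S2**: S1 plane waves from the left edge (BCL 400 ms); a
  single S2 over the lower-left quadrant. The coupling interval (CI) is S2
  onset minus last S1 onset; the useful range brackets the moment the last
  repolarization wave clears the domain midline (first time the midline
  column's max V falls below -70 mV after activating). The vulnerable
  window is the CI range (1-ms scan) whose episodes hold a phase
  singularity for >= 2 rotations.
* **Phase analysis**: per-node Hilbert transform of the de-meaned voltage;
  singularities from the winding of wrapped phase differences around 2x2
  plaquettes (threshold pi*(2 - 0.1)); greedy nearest-neighbour linking
  with a 0.3 cm/frame jump limit; rotation count = unwrapped phase advance
  at the node nearest the filament's mean position over the filament's
  lifetime, divided by 2*pi. Classifying an episode as a sustained rotor
  requires both the persistent singularity and >= 2 rotations, so paced
  plane waves (which also advance the local phase) never qualify. The tip
  displacement D is the maximum pairwise planar distance between filament
  points.

## Benchmark problem sizes

The benchmark drivers (`fracatrial.benchmarks`) and the acceptance script
run: two 60-s single-cell pacing runs; strand threshold bisections; two
10-s strand APD runs; four 300-ms strand CV runs. Desk-scale rotor checks
use the 64 x 64 sheet with a single S1 followed by S2 (coupling intervals
118 ms for gamma = 2 + j0 and 140 ms for gamma = 2 + j0.28, each located
inside the corresponding vulnerable window by a 4-10-ms scan on this grid)
and a post-S2 observation window of 1.1 s, long enough for a dozen
rotor rotations. Tip-displacement
comparisons between orders are made over this full window: sub-second
windows are dominated by the formation transient of the newly created tip,
and the D statistic there fluctuates by ~10% under floating-point-level
changes of the initial state, in either direction. Even at 1.1 s the
reduced-sheet D ordering between beta = 0 and beta = 0.28 is marginal;
the published contrast is a 5-s full-resolution statistic. Full-fidelity vulnerable-window
tables (128 x 128, 1-ms CI scans, multi-second episodes) use the same code
through `vulnerable_window` and the `vw` CLI subcommand but are
long-running jobs by design.

## Reproduction notes

Against the published study the package reproduces: the CAF single-cell
biomarkers (94.6 ms / -84.6 mV vs 96 ms / -84.67 mV); the strand APD at
standard diffusion (104.5 vs 108 ms) and the sign and rough size of the
beta effect (-13.8 vs -9 ms); the non-remodeled calibration CV (65.3 vs
63 cm/s) and the CAF beta = 0 velocity (61.5 vs 60.10 cm/s); sustained
reentry induction inside a finite vulnerable window; and the qualitative
rotor phenomenology (quasi-stable meander at standard diffusion, larger
tip excursions at complex order).

Known discrepancies, all traceable to unpublished details of the original
semi-spectral implementation and to the baseline pacing protocol: the
non-remodeled 60-s BCL-400 APD90 (263 vs 309 ms — the printed value matches
a from-rest beat, not a rate-adapted one); and the beta = 0.28 strand rows,
where this package's unsmoothed exponential propagator lets the wavefront
carry more high-wavenumber content and hence damps it more strongly (CV
34.1 vs 41.11 cm/s at alpha = 2; 27.2 vs 28.94 at alpha = 1.2; slow
propagation instead of block at alpha = 1.1).

## What the fixtures do and do not show

The synthetic fixtures (sine eigenmodes, travelling rectangular pulses,
rigidly rotating spirals) have closed-form ground truth and validate the
operator algebra, the biomarker arithmetic and the phase/tip machinery in
isolation. They contain none of the reaction-diffusion physics — no
restitution, no curvature effects, no wavefront-tail interaction — so
passing them says nothing about rotor dynamics beyond the correctness of
the measurement chain; that is what the tissue benchmarks above are for.

## Limitations

* 2-D isotropic monodomain only: no fiber anisotropy, no 3-D scroll waves,
  no conductivity tensors, no alternative atrial cell models.
* The complex order is spatially uniform; regionally varying gamma is out
  of scope.
* The wavenumber-unit scale and the spectral filter are calibration-pinned
  conventions, not first-principles derivations; beta != 0 quantities are
  sensitive to them (beta = 0 quantities are not).
* Euler/Rush-Larsen at dt = 0.01 ms is first-order accurate; halving dt
  changes CV by well under 1%, but stiff-limit studies should use smaller
  dt rather than trust asymptotics.
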