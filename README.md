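# fracatrial

Complex fractional-order monodomain simulation of atrial action-potential
propagation and rotor dynamics.

## What this is for

Rotors — spiral waves re-exciting atrial tissue around an unexcited core —
are a leading mechanistic account of atrial fibrillation (AF). Standard
rotor simulations treat the myocardium as a homogeneous continuum with
ordinary diffusion, which ignores its discrete, heterogeneous architecture.
This package implements a propagation model in which structural
heterogeneity enters through the *order* of the diffusion operator: the
tissue is treated as a discrete-scale-invariant fractal, whose dimension is
a complex number `gamma = alpha + j*beta`. The membrane potential V obeys

    dV/dt = kappa * (Hx^gamma + Hy^gamma) V - I_ion + I_stim,

where `H^gamma = -1/2 [(-Δ)^(gamma/2) + (-Δ)^(conj(gamma)/2)]` is a
complex-conjugate pair of spectral fractional Laplacians with the real
Fourier symbol

    s(k) = -|k|^alpha * cos(beta * ln|k|).

`alpha = 2, beta = 0` recovers classical diffusion; lowering `alpha`
(fractal dimension) and raising `beta` (log-periodic correction from
discrete-scale invariance) encode increasing structural heterogeneity. The
ionic current `I_ion` is the Courtemanche human atrial model, with
chronic-AF electrical remodeling (g_to, g_CaL ×0.65; g_Kur ×0.49;
g_K1 ×2.1) and the acetylcholine-activated K⁺ current at 5 nM ACh.

The package is aimed at computational cardiac electrophysiologists: it
provides the cell model, the spectral operator with its stability analysis,
an operator-splitting tissue solver (1-D strands, 2-D sheets), S1–S2
stimulation protocols (diastolic-threshold search, cross-field rotor
induction, restitution, vulnerable-window scans), electrophysiological
biomarkers (APD90, conduction velocity, APD dispersion, peak-current
profiles), and Hilbert-phase rotor-tip tracking with the tip-displacement
metric D.

## Worked example

`examples/01_single_cell_remodeling.py` paces the atrial cell for 60 s at a
basic cycle length of 400 ms, with and without chronic-AF remodeling:

```
baseline : APD90 = 263.17 ms, diastolic V =  -78.22 mV
CAF      : APD90 =  94.62 ms, diastolic V =  -84.61 mV
```

APD90 is the duration of the last paced action potential at 90%
repolarization; the diastolic V is read just before the final stimulus.
Remodeling shortens the action potential by roughly a factor three and
hyperpolarizes the cell — the substrate that lets a reentrant wave fit
inside a few centimetres of atrium.

`examples/03_strand_conduction.py` propagates plane waves along a 2-cm
strand of CAF-remodeled tissue and measures the conduction velocity between
L/3 and 2L/3:

```
gamma = 2 + j0.00, kappa = 0.40 cm^2/s:  CV = 61.53 cm/s
gamma = 2 + j0.28, kappa = 0.40 cm^2/s:  CV = 34.11 cm/s
```

At identical diffusivity, the imaginary order damps the high-wavenumber
content the upstroke needs and slows conduction — the propagation-level
signature of structural heterogeneity.

`examples/04_rotor_phase_analysis.py` runs the Hilbert-phase rotor-tip
machinery on an analytic spiral with known core, chirality and rotation
rate, recovering the tip to machine precision, the rotation count to 0.2%,
and D = 0 for a pinned spiral.

Other entry points: the `fracatrial` CLI (`single-cell`, `strand`, `sheet`,
`restitution`, `vw`, `phase` subcommands) for shell-driven runs, and
`fracatrial.benchmarks` for the full published protocols.

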