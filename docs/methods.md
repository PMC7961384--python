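# Methods

## Model and assumptions

`reesfel` models a fluorescent ligand with a ground state (GS) and a single
charge-transfer excited state (CT), bound to a protein in one of *m*
discrete microstates along a collective protein–ligand coordinate *x*
(units eV^0.5, so the shared curvature κ is dimensionless and defaults
to 1). The model stands on four assumptions:

1. **Ground-state thermal equilibrium.** Microstate populations at each *x*
   follow the Boltzmann distribution over the GS surfaces at the configured
   temperature (298 K default). Only relative weights matter, so any
   distribution prefactor cancels in the normalization.
2. **Static heterogeneity.** The environment relaxes slowly compared to
   fluorescence: there is no transfer between microstates, and no solvent
   relaxation, during the excited-state lifetime. Emission within a
   microstate is therefore independent of the excitation energy, and a
   single-microstate system shows exactly zero REES — a limit the test
   suite enforces.
3. **State-independent reorganization.** The CT displacement x_CT, and with
   it the reorganization energy λ = κ·x_CT²/2, is the same in every
   microstate (the Stokes shift is dominated by the ligand's own
   inner-sphere relaxation).
4. **Parametric landscape.** The GS offsets follow A·i^b with microstates
   indexed i = 0 … m−1 and spaced by x_GS; the landscape span is
   A·(m−1)^b. "m microstates" always means the count, with the top index
   m−1. The CT–GS gap interpolates linearly in i between ΔG_CTGS0 and
   ΔG_CTGSN so that both endpoints are met exactly.

Per-microstate absorption is the linear function
ΔG_CTGS(i) + λ − κ·x·x_CT of the coordinate, identical in slope for every
state; emission is the constant ΔG_CTGS(i) − λ. Taking instead the vertical
gap between the two harmonic surfaces would add a κ·i·x_GS·x_CT cross-term
to absorption; that variant is available as a diagnostic
(`strict_surfaces=True`) but is not the default, because the default form
keeps the Stokes-shift and gap-average identities exact per state and the
single-state REES strictly zero.

Peak and mean emission are treated interchangeably: the ensemble emission
at each *x* is the population-weighted mean of the per-state emission
energies, even though an experiment reports the peak of a composite band.
Band shapes (widths) are not modelled, only peak positions.

## Parameters

| symbol | meaning | units | default / typical |
|---|---|---|---|
| κ | curvature of all harmonic surfaces | — | 1 |
| T | temperature | K | 298 |
| x_CT | CT-surface displacement | eV^0.5 | 0.89–1.08 (fitted) |
| ΔG_CTGS0, ΔG_CTGSN | CT–GS gaps of extreme states | eV | ~3.0–3.4 |
| A | landscape energy scale | eV | 10⁻⁵–0.2 (fit bounds) |
| b | landscape exponent | — | 2 (1 linear, 3 cubic) |
| x_GS | microstate spacing | eV^0.5 | 0.005–0.5 (fit bounds) |
| m | number of microstates | count | scanned, typically 3–20 |

The ligand block (x_CT, ΔG_CTGS0, ΔG_CTGSN) is never fit freely: it is
calibrated from the absorption maximum and the blue/red emission endpoints
via λ = (abs − em_blue)/2, ΔG_CTGS0 = (abs + em_blue)/2,
ΔG_CTGSN = ΔG_CTGS0 − (em_blue − em_red). κ ≠ 1 rescales x_CT without
changing any observable.

## REES curves and their shape

Sweeping *x* over [−1, 2] (1001 points by default) and converting energies
with hc = 1239.84193 eV·nm yields the theoretical curve of emission versus
excitation wavelength. Curve summaries report the two emission endpoints,
the excitation wavelength where emission crosses halfway between them
(located by linear interpolation of the first crossing), and the central-
difference slope d(em)/d(ex) there. A flat curve returns an
undefined-midpoint flag instead of raising.

Three shape trends follow from the model and are enforced as tests:
a steeper landscape (larger A) pushes the mid-point to longer excitation
wavelengths; more microstates shift the mid-point red and flatten the
transition; and wider spacing x_GS steepens the transition **while the
spacing stays below the thermal mixing width** ~k_BT/(κ·x_GS). Beyond that
point the weight crossovers between successive states separate into a
staircase and the mid-point slope falls again — the steepening trend is
genuinely non-monotone, peaking near x_GS ≈ 0.05–0.1 eV^0.5 for the default
parameter families. Trend tests therefore probe the ascending branch, and
the many-state family uses a widened sweep ([−1, 3.8]) so that a 20-state
transition completes inside the grid.

## Fitting pipeline

1. **Sigmoid representation.** Observed (λ_ex, λ_em) points are fit with the
   four-parameter Boltzmann sigmoid
   `em_red + (em_blue − em_red)/(1 + exp((λ − mid)/width))` by bounded
   least squares (scipy `curve_fit`) from six starts built off the data
   extremes, the median and the half-transition crossing. At least five
   points are required; flat data yield a flagged degenerate fit.
2. **Ligand calibration** from the sigmoid's asymptotes plus the absorption
   maximum (reordered with a warning if given red-first).
3. **Landscape fit.** For each candidate (m, b), (A, x_GS) — optionally b —
   are optimized by Nelder–Mead with bounds, A in log space, from a 5×5
   multistart grid (3×3 with three b starts for the free-exponent fit),
   stopping at 10⁻¹⁰ on the objective. The objective is the sum of squared
   emission differences (nm²) between the simulated curve, resampled by
   monotone linear interpolation, and a target.
4. **Model comparison.** Candidates are ranked by SLSQ, or by
   AIC = 2k + n·ln(LSQ) when parameter counts differ (k = 2 for fixed m and
   b, +1 when m is scanned, +1 when b is free). Ties break toward smaller m.

**Choice of fit target.** Two targets are supported. The default target for
a single fit is the sigmoid itself, evaluated on 50 points across its 1–99%
transition band — useful when only a fitted sigmoid (not the raw data) is
available. For model selection and recovery studies the package fits the
raw points instead (`data=` argument, `--fit-raw` on the CLI). The reason
is quantitative: the theoretical curve is intrinsically asymmetric relative
to a symmetric sigmoid (dense-fit residuals ~0.3 nm rms, asymptote bias of
several nm on a 10-point sample), and that correlated smoothing error
exceeds the emission differences that distinguish neighbouring state
counts. Fit against the sigmoid, the SLSQ-versus-m curve is nearly flat and
its minimum is not meaningful; fit against the points, the minimum at the
generating state count is sharp (SLSQ ~10⁻¹⁴ at truth for noiseless data).
The sigmoid is still fit, reported, and used for calibration in every
pipeline.

## Synthetic data and recovery

The generator samples the theoretical curve on an excitation grid —
by default 10 evenly spaced wavelengths covering the 2–98% emission
transition band — and adds independent Gaussian noise (sd in nm) to the
emission values only. Seeds are mandatory in the API; identical seeds give
identical datasets. Two reconstructed reference datasets ship as code: a
p38α-kinase-like complex (quadratic landscape, ten states, span 0.144 eV)
and an APH-like complex (quadratic, five states, span 0.028 eV), each
noiseless, with the absorption maximum implied by the ligand parameters.

The recovery experiment closes the loop for landscape spans between 0.041
and 0.240 eV (ten states, b = 2, spacing fixed at the p38α-fitted
0.153 eV^0.5, since no independent value is available): simulate, fit the
sigmoid, then refit with the state count scanned over 5–15 and the exponent
free. At zero noise all three recovered quantities (span, m, b) match their
inputs to well under 1%; a regression guard further checks that 0.3 nm
noise leaves the median recovered span over 20 seeds within 10% of truth.

What the generator does *not* emulate: instrument response, wavelength-
dependent noise, finite spectral bandpass, temperature series, and any
deviation of real emission-peak estimates from the model's weighted-mean
emission. Passing recovery tests therefore demonstrate the internal
consistency and identifiability of the pipeline at realistic sampling
density, not robustness to every artefact of real spectra.

## Derived thermodynamics

From a fitted landscape the package reports state minima A·i^b, successive
gaps A[(i+1)^b − i^b] (constant A for b = 1, A(2i+1) for b = 2), the
ground-state reorganization energy RE = κ·x_GS²/2, and Marcus activation
barriers (gap + RE)²/(4·RE), which reduce to RE/4 for degenerate states and
are undefined (an error) at x_GS = 0. Barriers are always reported straight
from this formula; with the p38α-fitted landscape the largest barrier
(between the two topmost states) evaluates to 0.0376 eV, and with the
APH-fitted landscape to 0.0154 eV — both within ~1.5 k_BT at 298 K.

Unit conversions use 1 eV = 96.485 kJ/mol = 23.0605 kcal/mol and
k_B = 8.617333262×10⁻⁵ eV/K. Dissociation constants map to binding free
energies via ΔG = k_BT·ln(K_d/1 M) (standard state 1 M, 298 K default).
The binding decomposition ΔG_assoc = ΔG_total − ΔG_intrusion is exact
bookkeeping, with ΔG_intrusion identified as the negative landscape span.

## Numerical choices

- Boltzmann weights are stabilized by subtracting the row-minimum energy
  before exponentiation; the partition value is kept in log space.
- The excitation axis must be strictly decreasing in energy along *x*
  (guaranteed for x_CT > 0 in the default absorption form); simulation
  raises otherwise, which also catches zero-Stokes-shift ligands.
- Wavelengths are meaningful to 0.1 nm; energies are computed in double
  precision throughout and identities (weight normalization, Stokes shift,
  gap averages) hold to 10⁻¹².
- Optimizer failures in a scan flag the candidate rather than aborting;
  an A fitted at its lower bound is logged as "no resolvable transition".

## Known limitations

- The number of microstates is what the spectroscopic model can
  distinguish; it need not equal counts from structural or simulation
  studies.
- Landscape forms are restricted to A·i^b; rugged or multi-well landscapes
  are out of scope.
- No kinetic model: barriers are reported without attempting rate
  constants or residency times.
- Curves that are not sigmoid-like over the measured window (truncated
  transitions) make the inverse problem ill-posed; fits then hit parameter
  bounds and are flagged rather than prevented.
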