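# Methods

Models, conventions, and numerical choices used by `nmrmap`, with the
assumptions stated explicitly so results can be audited.

## Chemical-shift perturbation

The combined amide perturbation is

    CSP = sqrt((Δδ15N / 10)² + (Δδ1H)²)   [ppm]

with the ¹⁵N dimension down-weighted by exactly 10 (the conventional ratio of
¹H to ¹⁵N shift dispersions). A residue is *significant* when its CSP exceeds
`mean + k·SD` of the full matched residue set, `k = 1` by default. The SD here
is the **population** SD (`ddof = 0`): the threshold describes the observed
CSP distribution itself, not an estimate for unseen residues. Overlapped
peaks are excluded from matching; disappeared peaks carry no shift
information and are skipped by CSP (but drive the `broadened` class in
competition analysis).

### Fast-exchange K_D fitting

In fast exchange the observed shift is population-weighted, so each residue's
combined shift at ligand concentration L is `f_bound(P, L, K_D) · Δδmax` with
the exact two-state isotherm

    f_bound = 2L / (s + sqrt(s² − 4PL)),   s = P + L + K_D.

This conjugate-root form equals the textbook
`((s − sqrt(s²−4PL)) / 2P)` exactly but is free of subtractive cancellation
as P → 0. The exact isotherm matters at millimolar K_D and millimolar
protein: ligand depletion makes the weak-binding form `L/(L+K_D)` wrong by a
relative `K_D·P/(L+K_D)²` at first order (≈9×10⁻⁵ even at P = K_D/10⁴), so
the package never uses the approximation.

All moving residues share one K_D; per-residue Δδmax are free amplitudes.
The fit runs in `log K_D` (positivity, better conditioning) via
Levenberg–Marquardt least squares; σ(K_D) is the asymptotic (Jacobian-based)
standard error mapped through the delta method. At least 4 titration points
are required, the first ligand-free, concentrations strictly increasing.

## PRE analysis

Raw ratios `I_para/I_dia` are normalized by `α = 1/mean(raw over reference)`
so the reference mean is exactly 1. The reference set is either user-supplied
or chosen automatically by two passes of sigma clipping that drop residues
below 0.8× the running mean — i.e., residues plausibly affected by the label.
Normalization requires ≥ 5 records.

Distances are calibrated linearly, `d = 12 + 18·min(PRE, 1)` Å, valid on
12–30 Å. Restraints follow three branches:

| observation            | restraint              |
|------------------------|------------------------|
| disappeared or PRE = 0 | bounds [1.8, 12] Å     |
| 0 < PRE < 0.8          | bounds [12, d_calc+3] Å|
| PRE ≥ 0.8              | none (unaffected)      |

Site classification uses region-specific attenuation cutoffs (defaults 0.88
for residues 1–182 and 0.70 for 183–352, strict inequality), reflecting the
different intrinsic linewidths of the flexible N-terminal arm and the rigid
C-terminal core.

## ¹⁵N relaxation

Decays are fit to `I(t) = I₀·exp(−R·t)` by two-parameter nonlinear least
squares initialized from a log-linear regression over the positive points.
Three-point schedules (defaults: R₁ at 0.020/0.300/0.600 s, R₂ at
8.65/16.96/33.92 ms) are supported as the minimal design. Isolated
non-positive intensities are tolerated (noise routinely pushes a late R₂
point below zero); at least two positive points are required. σ(R) comes
from 200 Monte-Carlo noise replicates at the stated per-point noise. At
SNR 50 the Cramér–Rao bound for these schedules is ~6% relative σ per
residue; the fitter reaches it, so per-residue spread at that level is the
information limit, not a defect — accuracy is characterized by the *signed*
median bias (<0.5% in validation) and by σ coverage (~68%).

Rotational correlation times use the R₂/R₁ ratio:

    τc = sqrt(6·R2/R1 − 7) / (4π·νN)   (valid for R2/R1 > 7/6),

with `νN = 0.1013756 · νH`. Per-domain values use the trimmed mean ratio:
residues outside ±1 sample SD (`ddof = 1`) of the domain mean are removed
once, the mean recomputed, and τc evaluated there; σ(τc) propagates the
trimmed ratio SD through the derivative of the formula. Exchange flagging
(ratio > untrimmed domain mean + 1 SD) marks residues whose R₂ is inflated
by conformational exchange. Free-vs-bound comparisons use Welch's unequal-
variance t-test on the trimmed ratio sets (≥ 5 residues per condition).

## Competition classification

Three conditions — free, +client, +client+competitor — yield per-residue
classes: `broadened` (disappears in either ligand condition), `competitive`
(significant client CSP and a strictly larger CSP with the competitor
present, beyond an optional margin), `client_only` (significant client CSP,
no additional movement), else `none`. The significance threshold is computed
once, from the client-vs-free comparison.

## Structure comparison

Superposition is the Kabsch algorithm (SVD of the covariance matrix with a
determinant sign correction to enforce a proper rotation), pairing common
residues on a chosen atom (default Cα). Because published RMSD values rarely
state which ensemble member and residue range were used, `rmsd_grid` scans
model-pair and residue-range choices explicitly rather than guessing one.
Correctness is validated against an independent quaternion (Horn)
implementation in the test suite.

## Synthetic generators

Every generator returns a `SyntheticGroundTruth` alongside the data and is
deterministic in its seed (`numpy.random.default_rng`). Design choices:

- **Titration**: site residues get Δδmax with ¹H in ±[0.03, 0.15] and ¹⁵N in
  ±[0.3, 1.5] ppm; peaks move along straight lines by the exact isotherm
  fraction; ¹⁵N noise is 10× the ¹H noise, matching the dispersion ratio.
- **PRE**: raw ratios invert the linear calibration divided by a true α;
  residues closer than 12 Å disappear.
- **Relaxation**: per-residue R₂/R₁ ratios are drawn around the domain value
  implied by inverting the τc formula, with fractional Gaussian scatter;
  R₁ is fixed at a plausible scale (1.1 s⁻¹) and R₂ = ratio·R₁; intensities
  are exact exponentials plus Gaussian noise at the stated SNR; a
  configurable residue fraction gets exchange-inflated R₂.
- **Competition**: designed sites draw Δδmax with ¹H in ±[0.08, 0.15] and
  ¹⁵N in ±[0.8, 1.5] ppm — large enough that, at zero noise, every designed
  site clears the whole-protein mean + 1 SD threshold by construction for
  site fractions up to ~25%, making the zero-noise dataset exactly separable
  (the generator's contract). Shared sites gain a 1.8× shift with the
  competitor present.

Generator realism is deliberately limited: peaks move on straight lines (no
intermediate-exchange curvature or broadening), noise is i.i.d. Gaussian,
ratio scatter ignores anisotropic tumbling, and no assignment errors are
simulated. They validate the analysis pipeline, not spectrometer physics.

## Known limitations

- The τc formula assumes isotropic tumbling and neglects high-frequency
  spectral-density terms; values are apparent τc, most meaningful as
  domain-to-domain contrasts.
- The PRE distance calibration is a linear approximation of the r⁻⁶
  dependence, valid only in the 12–30 Å window; restraints are intentionally
  generous interval bounds for data-driven docking, not precise distances.
- Three-point decays cannot diagnose multi-exponential relaxation; the
  monoexponential model is asserted, not tested, by the fit.
- The shared-K_D model assumes a single binding event in fast exchange;
  residues in intermediate exchange bias the fit and should be excluded
  upstream.
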