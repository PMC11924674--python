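# Methods

This note documents the model implemented by `endoraman`: the synthetic data
generator, the preprocessing chain, the quality and similarity statistics, the
two-stage classifier, and the evaluation protocol. It states only what the
code computes; all quantitative claims about behaviour are checked by the test
suite or by `scripts/acceptance.py`.

## Synthetic data generator

No public spectra exist for endonasal Raman measurements of sellar tissues, so
the package generates labelled raw acquisitions from nine tissue profiles.
Each profile is a list of band specifications (center, FWHM, ordinal strength
1–5 mapped linearly to amplitude `k·A₀`), a positive autofluorescence baseline
(quartic polynomial plus one broad FWHM-600 cm⁻¹ Gaussian whose amplitude
dominates the peaks), and optionally an admixture of another tissue's clean
signal. The registry encodes the discriminative chemistry: the 961 cm⁻¹
phosphate stretch is strongest in sellar bone (5) and one step weaker in the
dura covering it (4); CH-deformation bands at 1438/1449 cm⁻¹ run the other way
(bone 1, dura 2); white and gray matter differ at 1298 cm⁻¹ (2 vs 1) and
1650.5 cm⁻¹ (2 vs 3). The dura profile mixes 0.35 of the bone clean signal,
modeling excitation of the bone beneath the thin dura; this makes dura/bone
the hardest class pair while keeping them separable.

A raw record is a stack of accumulation frames plus a dark frame on a
1601-pixel axis spanning 400–2000 cm⁻¹. Frames are
`dark + baseline + Σ band peaks + noise`, with pseudo-Voigt peaks (50%
Lorentzian, FWHM 15 cm⁻¹), one multiplicative log-normal head effect per
(head, band), a per-record amplitude jitter, heteroscedastic shot noise with
standard deviation `noise_scale·√signal`, and Poisson-rate cosmic-ray spikes.
With every random effect switched off each frame equals the closed-form mean
function exactly; that closed form is the oracle for the generator tests.

Pituitary-gland records on designated heads are additionally emitted under
three preparation methods. Method structure is driven by three ordered maps:
amplitude-variance multipliers (in_situ 1.6 > ex_situ 1.0 > in_section 0.55),
dura-signal contamination fractions (0.12 / 0.05 / 0.01 — in-place
measurements see surrounding tissue), and noise multipliers (1.0 / 0.6 / 0.35
— in-place endonasal acquisition collects less light than bench measurement of
the excised or sectioned gland). Ordering violations are configuration
errors.

Frozen study conditions (the `GeneratorConfig` defaults): 6 heads, 5 records
per tissue per head, head effect sd 0.06, record effect sd 0.04, noise scale
0.7, contamination jitter sd 0.04, cosmic-ray rate 0.1/frame, 10
accumulations, dark level 100 counts, amplitude unit 120 counts, prep heads
(1, 2, 3). All generation is reproducible from (seed, config).

## Preprocessing

Nine ordered steps take a raw acquisition to an SNV fingerprint:

1. **Dark subtraction** — elementwise; negative results permitted.
2. **Despiking** — per pixel, frame values more than 8 MAD above the
   across-frame median are replaced by that median (single-frame input falls
   back to a within-spectrum median despiker).
3. **Axis calibration** — least-squares degree-2 polynomial mapping pixel to
   cm⁻¹ through detected acetaminophen reference lines; a non-monotone fit is
   an error.
4. **Response correction** — division by the instrument response scaled to
   unit mean (so a flat response is the identity).
5. **Accumulation averaging.**
6. **BubbleFill baseline removal** — the baseline is the envelope of the
   largest circular arcs ("bubbles") grown from below under the spectrum; the
   interval splits at the touch point and recursion continues on both sides,
   stopping when an interval is narrower than the 50 cm⁻¹ minimum bubble
   width. The spectrum is first rescaled to the unit square and its straight
   chord removed, so the arcs are scale-free. When a bubble touches at an
   interval endpoint, rolling continues over the interval minus that endpoint;
   without this the algorithm strands wide arcs on monotone stretches. The
   baseline never exceeds the spectrum, carries no feature narrower than the
   bubble floor, and absorbs broad structure (FWHM ≫ 50 cm⁻¹) while passing
   narrow peaks; these recovery properties are verified against known-truth
   baselines in the acceptance suite.
7. **Savitzky–Golay smoothing** — order 3, window 1, which is declared and
   tested as an exact no-op (the study condition).
8. **Truncation** to 800–1800 cm⁻¹.
9. **SNV normalization** — `(x − mean)/sd` with the population (1/N) standard
   deviation, chosen to match the QF convention below.

## Quality factor

For an SNV fingerprint `r` with `N` bins, `QF = (1/N)·Σ sgn(rᵢ)·rᵢ²`. Since
SNV fixes `Σ rᵢ² = N`, QF lies in (−1, 1]; it is ≈ 0 for pure noise and
(N−2)/N for a one-hot spike. Records with QF below the threshold (default
0.3; the keep rule is inclusive, QF ≥ threshold) are eliminated, and the
quality report lists per-tissue counts before and after. Eliminating every
record is a warning, not an error.

## Spectral similarity

The spectral angle mapper (SAM) between two spectra is the angle between them
as vectors, in degrees: 0 for identical (or positively scaled) spectra, 90 for
orthogonal ones. The module computes pairwise SAM between class mean spectra,
within/between-record tables, and a preparation-method comparison on gland
records: per-head and pooled summed per-bin variance plus pairwise SAM between
method means. The pooled row is a **paired** analysis restricted to heads
measured with every method, because pooling unpaired heads confounds method
contrasts with between-head differences.

## Classification

Two stages, both linear max-margin classifiers:

* **Stage one (band selection).** Candidate bins are restricted to ±25 cm⁻¹
  around the registry band centers. An L1-penalized linear SVM is swept over
  13 half-decade regularization strengths (10⁻³…10³). Each strength proposes
  a bin subset — its nonzero support if already under 20 bins, otherwise its
  19 largest-|coefficient| bins — and every proposal is scored by the
  fivefold cross-validated accuracy of the downstream L2 model refit on those
  bins alone. Ties break toward fewer bins, then stronger penalty. A task
  whose median proposal score across the grid does not beat chance + 0.05 is
  flagged uninformative (the median, not the maximum, because the maximum
  over a 13-point grid exceeds chance by selection bias alone).
* **Stage two (classifier).** An L2-penalized linear SVM (one-vs-rest for the
  four-class task) tuned over the same strength grid by seeded, stratified
  fivefold cross-validation on the selected bins; validation confusion
  matrices are aggregated over folds.

Model I is the suite of seven gland-vs-other binary tasks; model II is the
four-class task gland / sellar bone / dura / optic chiasm. Every trained
model exposes its selected bins (always fewer than 20), weights,
hyperparameters and split. A trained four-class model can also be applied to
gland records from the other preparation methods (method transfer).

## Evaluation protocol

Splits are by head, never by record: test heads are chosen by subset
enumeration targeting a test fraction in [0.33, 0.40] (midpoint 0.365), and
the split is certified disjoint. Any head appearing in both train and test —
at split construction or at evaluation time — raises `LeakageError`
immediately; leakage is a hard failure, never a degraded metric. Reported
metrics are per-class sensitivity/specificity, accuracy, confusion matrices
(fold-aggregated validation and held-out test) and ROC/AUC for binary tasks.

## Numerical choices

* Dataset CSVs are written with 17 significant digits and read back with
  round-trip float parsing, so write→read is bit-exact.
* SNV and QF share the population-sd convention; this makes `Σ rᵢ² = N` exact
  and the QF bound analytic.
* All randomness flows through seeded NumPy generators; the pipeline manifest
  embeds the full configuration and a stable hash of it.

## Limitations

* The generator is a statistical emulation: ordinal band strengths, an
  assumed linear amplitude map, and assumed linewidths. It does not claim
  radiative-transport realism or absolute photon counts, and results on it
  are recovery checks, not claims about real tissue.
* The BubbleFill contract here is the documented lower-envelope
  interpretation of the algorithm, not a claim of bit-equality with any other
  implementation.
* Pseudo-Voigt peak tails are partially climbed by the bubble envelope, so
  peak-height recovery is shape-dependent; the quantitative recovery bounds
  are verified for Gaussian peaks.
* The despiker cannot remove a spike present at the same pixel in both of two
  frames (the median equals the spike).
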