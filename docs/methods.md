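# Methods

This note documents the models, estimators, numerical choices and known
limitations of `rsnet`, in the order the pipeline applies them.

## Synthetic cohort model

Real resting-state EEG has no accessible ground-truth network, so the
package ships a generator whose network *is* the ground truth. It is not
a biophysical head model; it is the minimal generative model that
exposes exactly the two properties the wPLI estimator is claimed to have
— sensitivity to consistently *lagged* phase coupling and blindness to
*zero-lag* (volume-conducted) mixing — plus realistic 1/f background.

**Sources and dynamics.** Per frequency band, one phase oscillator per
source follows Kuramoto dynamics on a Watts–Strogatz graph
(ring lattice of even degree *k*, each edge rewired with probability
*p*). Each undirected edge is randomly oriented; the receiver *i* of an
edge from *j* evolves as

    dθ_i = ω_i dt + Σ_j K_ij sin(θ_j − θ_i − α) dt + σ √dt ξ,

so coupled pairs lock near the offset α rather than at zero lag — a lag-
sensitive estimator sees them, an instantaneous-correlation estimator's
blind spot (α = 0 or π) is explicitly forbidden. Integration is explicit
Euler at the sampling rate (dt = 1/fs ≤ 2 ms, far below the oscillation
period, so integration error is negligible next to the injected phase
noise).

**Working point.** Defaults: coupling gain K = 3 rad/s, locking offset
α = π/4, phase noise σ = 0.7 rad/√s, per-source natural-frequency jitter
0.2 Hz around the band center, oscillation amplitude 5 µV on 10 µV RMS
1/f background (exponent 1), 1 µV white sensor noise. This point was
chosen so that direct neighbours phase-lock detectably while the network
stays below global synchronization: strong global locking makes *every*
channel pair coherent and erases topology from the measured graph.
Subject random effects (band-frequency shift SD 0.15 Hz, log-normal
noise-amplitude SD 0.15) make subjects distinct but reproducible.

**Condition effect.** The emulated experiment has six within-subject
conditions (PRE, ACUTE1–3, REG1–2, sixteen subjects by default). The
injected effect at the exhaustion analog (ACUTE3) randomizes the
theta-band graph (rewiring 1.0) *and* reduces its coupling gain to 1/6.
The coupling reduction is essential, not cosmetic: random graphs are
better synchronizers than small-world graphs at equal gain, so rewiring
alone *raises* overall theta phase-locking and moves measured network
metrics in the wrong direction. The joint effect models a disorganized,
weakened theta network and produces the expected sensor-level signature
— a clustering-driven drop of the normalized small-world index, specific
to theta, at ACUTE3 — detectable by the end-to-end ANOVA in well over
80 % of seeded replicates at n = 16.

**What the generator does not emulate.** Eye-blink/EMG artifact
morphologies, electrode impedance drift, realistic volume-conduction
geometry (mixing is an arbitrary user matrix, identity by default), and
1/f knees. Passing tests therefore demonstrate correctness of the
estimators and calibration of the statistics under controlled coupling,
not robustness to every property of real recordings.

**Determinism.** A cohort is a pure function of its spec. The global
seed is expanded through `numpy` `SeedSequence` spawn keys per subject,
condition and stage, so enlarging a cohort never perturbs existing
cells.

## Preprocessing

Order: notch → FIR band-pass → common-average re-reference (with the
online reference electrode reinstated as an explicit zero channel before
averaging) → polyphase resampling → epoching. All filtering is
zero-phase: the notch (IIR, Q = 30) is applied forward–backward, and the
band-pass is a symmetric windowed-sinc (Hamming, transition width 25 %
of the low edge, order rounded to even) applied by FFT convolution with
exact group-delay compensation. Phase integrity is a precondition for
phase-lag connectivity, so a test asserts zero cross-correlation lag
between band-limited input and output.

Defaults mirror a 500 Hz acquisition chain: notch 60/120 Hz, band-pass
3–40 Hz, downsample to 256 Hz, 8 s epochs with 4 s overlap, first 50
epochs retained. The notch frequencies are configurable; component-based
artifact removal (ASR, ICA) is out of scope and replaced by an optional
absolute-amplitude epoch-rejection threshold (off by default — synthetic
data is clean). Epochs start at sample 0; a trailing incomplete epoch is
dropped; rejection happens before the first-N selection, and a shortfall
is recorded in provenance rather than raised.

## Spectral analysis

PSD is the Hann-tapered periodogram of each 8 s epoch (one segment per
epoch, 0.125 Hz resolution), averaged over epochs and restricted to
3–30 Hz. Band power is the *mean* PSD over bins whose center lies in the
half-open interval [low, high) — shared edges (8, 10.5 Hz) count once —
and ROI power is the mean over member electrodes (frontal, central,
parietal, occipital midline groups). Default bands: theta 4–8, alpha-1
8–10.5, alpha-2 10.5–13 Hz. Both absolute (µV²/Hz) and log10 values are
reported.

## Connectivity (wPLI)

Per epoch and band: 4th-order Butterworth band-pass applied
forward–backward, Hilbert analytic signal, 0.5 s trimmed at each end
(filter + Hilbert edge artifacts must not enter the statistic), then

    wPLI_ij = |Σ_t Im(z_i z_j*)| / Σ_t |Im(z_i z_j*)|.

Numerical conventions: a pair whose total imaginary cross-spectral mass
is below 10⁻⁹ of its total cross-spectral magnitude scores 0 (the 0/0
convention — pure zero-lag relations leave only floating-point noise in
the numerator and denominator); constant channels score 0 against
everything. The estimator is computed over time within each epoch —
matching the one-matrix-per-epoch design, where an expectation across
epochs is unavailable — and epoch matrices are never averaged before
graph metrics unless explicitly requested.

**Min–max normalization.** Before graph analysis, wPLI values of one
subject-condition stack are affinely mapped to [0, 1] using the observed
off-diagonal range. Three pooling scopes are implemented; the default
pools over epochs *within each band*. The across-band scope
("individual", pooled over epochs and bands) is available behind a flag
but not default: it couples the bands' scales, so a genuine effect
confined to one band shifts the affine map applied to the other bands of
the same recording and can masquerade as a spurious condition effect in
bands where nothing changed (observed as inflated alpha-2 false
positives in cohort simulations). A per-matrix scope is also available.
The min/max actually used are stored for audit.

## Graph metrics

Networks are weighted, undirected, fully dense (no binary threshold).

- **CC** — geometric-mean (Onnela-form) weighted clustering with weights
  scaled by the matrix maximum; nodes with fewer than two neighbours
  score 0; global CC is the unweighted node mean.
- **PL** — mean shortest-path distance over ordered pairs with edge
  length 1/weight; computed by a vectorized Floyd–Warshall (exact for
  nonnegative lengths, and faster than per-call sparse-graph routines at
  montage sizes ≤ 65); unreachable pairs are excluded with a warning.
- Both are computed per epoch and averaged (matrix-first averaging is a
  flagged alternative).
- **Cross-band normalization** — per subject and metric, each
  (condition, band) cell is divided by the mean of all *other* cells
  (leave-one-out; include-self and within-condition-across-bands
  variants behind flags). SWI = normalized CC / normalized PL, computed
  from the epoch-averaged, normalized values — the ratio-of-normalized
  definition forces this order. By construction normalized metrics
  satisfy `norm = raw·(n−1)/(Σ−raw)` and hover near 1.

The default normalization pools cells over conditions *and* bands; a
bands-only scope is available. Leave-one-out was chosen to match the
"mean of all other values" reading; with 18 cells the two variants
differ by < 6 %.

## Statistics

One-way within-subject ANOVA per outcome (single factor, condition):
`SS_total = SS_condition + SS_subject + SS_error`,
`F = MS_condition / MS_error`, partial η² = SS_c/(SS_c+SS_e). Sphericity
is assessed by Mauchly's W on the contrast-projected covariance with the
standard second-order chi-square refinement (the SPSS/ezANOVA
convention); the Greenhouse–Geisser ε and ε-corrected p are always
reported, and the pipeline's decision p (`p_selected`) uses the GG
correction when Mauchly rejects at .05. Post-hoc: all k(k−1)/2 two-sided
paired t-tests with Bonferroni–Holm step-down adjustment
(`p_(i) → max_{j≤i} min(1, (m−j+1)p_(j))`), run only when the main
effect is significant; a zero-variance pair is reported with p = 1 and a
note rather than raised.

Implementations are pinned by tests to independent definitional oracles
(sums-of-squares loops, step-down enumeration) and cross-checked against
`pingouin` and `statsmodels`.

## Problem sizes used by tests and the acceptance script

End-to-end simulations use the reduced mode: 32-channel montage (which
contains all 21 ROI electrodes), 128 Hz synthesis with no resampling
step, theta + alpha-2 bands, and 12 epochs of 8 s per recording
(60 s recordings), 16 subjects × 6 conditions per cohort. These sizes
were chosen as the smallest at which the epoch-sampling noise of the
graph metrics leaves the injected effect clearly detectable at n = 16;
full-scale runs (65 channels, 500 Hz, 5 minutes, 3 bands, 50 epochs) use
the identical code path via the default `CohortSpec`/`PipelineConfig`.
Type-I calibration and power are each assessed over 20 seeded cohorts;
the acceptance script uses 8 replicates per arm and reports rates.

## Known limitations

- Sensor-level analysis only; no source reconstruction or leakage
  correction beyond wPLI's built-in zero-lag blindness.
- The generator's condition effect operates through coupling topology
  and gain; it cannot emulate effects mediated by amplitude or spectral
  shifts (to which wPLI is deliberately insensitive).
- Mauchly's p relies on the asymptotic chi-square approximation; at very
  small n it is approximate (the GG-corrected p is always available).
- The min–max normalization makes graph metrics relative within a
  subject-condition stack; absolute CC/PL levels are not comparable
  across studies with different channel counts or epoch counts.
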