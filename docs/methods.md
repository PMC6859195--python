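# Methods

## Signal model and training-data generator

The generator emulates the indirect-dimension interferograms of a
protein ¹⁵N–¹H correlation spectrum. A synthetic FID on an `np`-point
Nyquist grid with sweep width `sw` is

    x[j] = Σₖ Iₖ·exp(iφₖ)·exp((i2πνₖ − R₂ₖ)·jΔt),  Δt = 1/sw,

a standard States-mode quadrature signal; ν is the offset from the
carrier on [−sw/2, +sw/2). Per-FID parameters: the number of signals is
uniform on {1, …, ⌊(3/8)·sp⌋} — two complex points determine one
Lorentzian, so the cap stays well below the sp/2 identifiability bound
to avoid ill-posed training targets — with I ~ U(0,1), R₂ ~ U(3,100) s⁻¹
(linewidths 1–32 Hz, spanning sharp amides through exchange-broadened
lines), ν uniform over the sweep width, and φ ~ U(−5°,+5°) applied per
signal (small phase errors model miscalibration and off-resonance
effects). FIDs are normalised by |x[0]|; the divisor is kept so
reconstructions can be rescaled. No noise is added by default (a
complex-Gaussian `noise_sigma` knob exists on the 2D fixture generator
for robustness studies); ε = 1e-12 guards the first-point division.

What the generator does *not* emulate: thermal noise, solvent/baseline
artefacts, J-coupling multiplets, non-Lorentzian lineshapes, and the
correlated intensity structure of real spectra. Tests passing on this
distribution therefore demonstrate correctness of the machinery and
learnability of the Lorentzian signal class, not performance on
experimental data.

Default axis: sw = 5100 Hz, np = 256 (¹⁵N of the evaluation geometry);
fast tests use np = 64 or 32. Generation is streamed in batches so the
training set size is not memory-bound.

## Sampling schedules

Index 0 is always sampled — first-point normalisation downstream
requires it. Random schedules draw sp−1 further indices uniformly
without replacement. Poisson-gap schedules walk the grid drawing gaps
from Poisson(λ·sin(π/2·(k+0.5)/np)) — small gaps early, large gaps
late — with λ rescaled multiplicatively (damping exponent 0.7) between
walks until exactly sp points land on the grid. Schedule files are
plain one-index-per-line, 0-based; 1-based files import via
`one_based=True`.

## Network

All shapes derive from (sp, np): data encoder tanh 2sp→2np, schedule
encoder tanh 2np→2np (input: 0/1 mask with ones at the real slot i and
imaginary slot np+i of each sampled index), four sigmoid gate layers
2np→2np, head linear 4np→2np. The sparse 2×sp matrix is flattened
row-major (full real row then full imaginary row). The cell wiring —
gates f, i, g, o computed from h alone, c′ = c⊙f + i⊙g, h′ = o⊙c′ —
uses exactly the operations of the architecture diagram (sigmoid linear
layers, elementwise + and ×) and mirrors a standard LSTM; it is stored
in model files as the named configuration `lstm-v1` so alternative
wirings can be added without invalidating saved models. The data
encoder feeds h₀ and the schedule encoder c₀. N (cell applications)
defaults to 3; weights are shared across applications (an untied mode
exists). Initialisation is Glorot-uniform with zero biases, fully
seeded.

Forward, reverse-mode gradient and ADAM are plain numpy. The analytic
gradient is validated against central finite differences at 1e-4
relative on every parameter of a tiny instance. Minibatch arithmetic
runs in float32 (≈3.6× faster on one CPU); master weights and the
gradient check stay float64. Determinism: single-threaded runs are
reproducible bit-for-bit given (seed, config).

## Training

Per run: generate `n_fids` fresh FIDs, normalise, hold out 10% for
cross-validation, minimise the MSE between the 2×np network output and
the fully sampled FID with ADAM (lr 0.00012, β = 0.9/0.999, ε = 1e-8,
batch 256). Runs of `epochs_per_run` (20) epochs repeat until
validation MSE *and* MAE drop below the stopping thresholds — 12.5%
sampling: (5e-4, 0.013); 18.75%: (1.5e-4, 0.008); other fractions
require explicit values. One model is trained per schedule, and model
files record the schedule and refuse mismatched inference.

Desk-scale sizes: the package defaults to 5×10⁴ FIDs per run; the
reduced instance exercised by the test-suite is np = 64, sp = 16,
N = 2, two runs of 20 epochs (~70 s, one CPU). At this scale the model
reliably halves the median frequency-domain RMSD of the zero-filled FT
on held-out FIDs, but remains orders of magnitude above the stopping
thresholds: converged training needs millions of FIDs per run over
tens of GPU-hours. The training *procedure* is identical at every
scale; only `n_fids`/`max_runs` change.

## 2D pipeline

Layout: time/time data are complex (td_direct, 2, np_indirect), axis 1
holding the cosine/sine quadrature components of the indirect
evolution. `ft_direct` transforms the direct dimension (first point
halved, downfield-to-upfield frequency ordering), discards the direct
imaginaries after phasing (fixtures are generated in phase) and
assembles the complex indirect FID per ¹H frequency. Slice
reconstruction normalises each slice by its |first sampled point|,
applies the model in one batch, rescales, and finally re-imposes the
measured values at sampled points — they are known exactly, so
reconstruction only ever fills unmeasured points, and with a full
schedule the pipeline is an exact identity for any scale-preserving
model. Slices whose first-point magnitude is below 1e-6 of the
spectrum-wide maximum bypass the model (noise-only slices must not be
amplified by normalisation). The indirect dimension is then apodised
with w(j) = sin(π(0.42 + 0.58·j/(np−1)))² — "end" = 1.0 so the window
reaches zero at the last point, power 2 for the square-sine; both
configurable — and transformed, keeping the absorption part. No
zero-filling beyond np by default. ppm axes decrease with bin index;
conversions are involutive and derived from (sw, obs, carrier).

nmrPipe I/O is a minimal single-file implementation of the 512-float32
header plus float32 traces (direct dimension contiguous; complex traces
stored as all real then all imaginary points; indirect quadrature pairs
as consecutive traces). Round-trips preserve data to single precision
and the axis metadata; byte-swapped or truncated files raise with the
offending header field named.

## IST baseline

A generic iterative-soft-thresholding reconstruction: per pass, FFT the
zero-filled residual, move the part of the spectrum above a threshold
into the accumulated estimate (magnitude shrinkage, phase preserved),
and recompute the residual at the sampled points. With the initial and
end level multipliers equal (0.98), the threshold is the single
geometric schedule τₖ = τ₀·0.98ᵏ with τ₀ the initial spectral maximum.
Defaults: 1000 iterations, first-point correction 0.5 (applied by the
2D pipeline at FT time, in both dimensions, never to network inputs or
outputs — the training data carry no such scaling). The output equals
the measured data exactly at sampled points; residual energy at sampled
points is non-increasing.

## Evaluation

Per-slice RMSD is normalised by the global maximum of the fully sampled
frequency-domain spectrum (configurable to per-slice maxima) so values
are comparable across slices; ⟨RMSD⟩_spec averages over ¹H 6.5–9.6 ppm.
Peak heights are refined by three-point parabolic interpolation
independently per dimension around the local grid maximum (the standard
peak-centering estimate); peaks are matched between spectra within a
0.1 ppm (¹H) × 0.5 ppm (¹⁵N) box around known fixture positions.
Intensity fidelity is the RMSD (in %) of max-normalised paired heights
plus their squared Pearson correlation; replicate reconstructions are
summarised as mean ± sample SD.

## Numerical choices and degenerate inputs

- First-point guard ε = 1e-12 (normalisation), slice guard 1e-6
  relative (2D pipeline). Empty signal lists, empty schedules,
  out-of-range indices, mismatched shapes and non-finite losses raise
  immediately with context.
- Parabolic refinement returns not-found on plateaus or when the
  search box has no interior local maximum; the correction term is
  zero (not NaN) when the three points are collinear.
- Sampling-fraction thresholds are matched within 1e-9 (exact binary
  fractions for the two studied schedules).

## Measurement-resolution constraints in the oracles

Two test oracles operate where the quantity is physically measurable:

- Linewidth vs R₂/π is verified on a fully decayed acquisition
  (np = 16384, ×4 zero-fill) rather than the 256-point training grid:
  a 50 ms acquisition truncates slow decays, and the apparent FWHH of
  lines narrower than the ~24 Hz sinc kernel reflects the truncation,
  not R₂. Peak *positions* are checked on the 256-point grid directly.
- Half-bin peak-height interpolation is validated on a line resolved
  over ~3 bins (5 Hz digital resolution, R₂ = 50 s⁻¹): three-point
  parabolas cannot reconstruct lines much narrower than the grid
  spacing, which is a property of the estimator, shared by any
  peak-centering tool, not of this implementation.

## Known limitations

- Desk-scale trained models are deliberately under-trained; they
  demonstrate the learning dynamics and beat zero-filling, not
  converged reconstruction quality.
- Only in-phase, 2D, States-mode data are supported; no phase
  correction, solvent suppression, or 3D/4D pipelines.
- The nmrPipe reader supports the package's own dialect (native byte
  order, single 2D stream) — it is an I/O convenience, not a general
  nmrPipe implementation.
- The Poisson-gap construction follows the canonical sinusoidal-gap
  recipe; exact index sets from other generators will differ seed for
  seed.
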