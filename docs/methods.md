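# Methods

## Signal model and preprocessing

Input records are synchronized ECG/PPG/ABP triplets sampled at
f_s = 125 Hz.  ECG and PPG amplitudes are in arbitrary units; ABP is in
mmHg because the per-cycle SBP/DBP labels are read directly from it.

Baseline wander (respiration, electrode drift) occupies the band below
f_c = 0.1 Hz and is removed in the DFT domain: with a transform of
length N, all bins k < k_c = ⌊N·f_c/f_s⌋ are zeroed and the signal is
restored by the inverse transform.  Zeroing only the low bins of a
one-sided range would destroy conjugate symmetry, so the mirror bins
N−k_c+1 … N−1 are zeroed as well; the reconstruction is then real by
construction and the implementation asserts a < 1e−9 relative imaginary
residue.  The DC bin is inside the zeroed band, so the filter also
removes the mean — intended baseline removal, not a side effect.

Two transform-length policies are provided (`FilterSpec.mode`):

* `full` (default): one DFT over the whole record with k_c recomputed
  from the actual length.  No block-edge discontinuities; preferred for
  records of minutes.
* `blocks`: non-overlapping N = 4096-sample blocks with the final short
  block zero-padded then truncated, for streaming or very long records.

A stop-band component is annihilated *exactly* only when its frequency
falls on a DFT bin; off-bin drift leaks part of its energy above the
cutoff, which no bin-zeroing filter can remove.  Filter tests therefore
use bin-aligned probes (e.g. 0.05 Hz in a 40 s record, where it is bin
2), and quantify off-bin behavior separately.

Amplitude normalization is min–max to [0, 1]:
x′ = (x − min x)/(max x − min x), applied to the whole (filtered)
record.  A constant signal is a dead channel and raises an error rather
than returning zeros.

## Fiducial detection

ECG R peaks come from a Pan–Tompkins chain parameterized for 125 Hz:
zero-phase Butterworth band-pass 5–15 Hz (order 2), five-point
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds (THR1 = NPK + 0.25·(SPK − NPK), search-back at 0.5·THR1 when
an interval exceeds 1.66 × the running RR estimate), a 200 ms
refractory period, and final refinement to the local ECG maximum within
±75 ms.  All constants are module-level and documented in
`pulsebp.fiducials`.

PPG landmarks are detected per beat, a beat being delimited by two
consecutive R peaks:

* **foot** — waveform minimum between the two R peaks;
* **systolic peak** — waveform maximum between the foot and the next
  foot;
* **dicrotic notch** — minimum of (signal − chord), the chord drawn
  from the systolic peak to the *next* foot.  The descent the chord
  must span ends at the following pulse's onset, which is why the
  next foot (not the same beat's) anchors it;
* **second peak** — minimum of the discrete second difference
  x[n+1] − 2x[n] + x[n−1] after the notch (the reflected wave's crest
  is the point of most negative curvature);
* **maximum-slope point** — maximum of the forward difference
  x[n+1] − x[n] on the rising edge; this is the distal timing reference
  for PTT.

Every arg-extremum resolves ties to the earliest index, within a 1e−9
relative tolerance so that numerically flat segments (a linear descent,
a quadratic arc) behave deterministically.  Degenerate geometry — a
flat chord residual (no distinct notch; such pulses occur in practice)
or constant curvature — raises a per-beat flag instead of an error, and
flagged beats are excluded from feature extraction.

## Cycles, features, labels

A *cycle* spans three consecutive R peaks (two RR intervals) and is
valid when it is at most 200 samples (1.6 s at 125 Hz) and its PPG
landmarks are present and unflagged; invalid cycles are skipped and
counted per reason (`too_long`, `flagged`, `incomplete`).  At 50 bpm
every cycle is 300 samples, so the window rule correctly discards all
of them; per-beat feature recovery at low heart rates is therefore
measured with the rule disabled (`max_window_samples=None`) while the
pipeline default keeps it.

Per valid cycle, on the min–max-normalized PPG:

| feature | definition | unit |
|---|---|---|
| PTT | (max-slope − R)/f_s, constrained to 0 < PTT < first RR | s |
| HR | 60·f_s/(R₂ − R₁), the cycle's first RR interval | bpm |
| RI | b/a with a = PPG[peak] − PPG[foot], b = PPG[second] − PPG[foot] | – |
| ST | (notch − foot)/f_s | s |
| UT | (peak − foot)/f_s | s |
| SV | trapezoidal ∫ PPG, foot → notch, dt = 1/f_s | a.u. |
| DV | trapezoidal ∫ PPG, notch → next foot | a.u. |

Design choices where the procedure was open: RI amplitudes are measured
relative to the first foot (invariant to baseline level); HR uses the
first RR interval of the cycle; "within half a cycle" for the PTT
search is read as one RR interval, since a cycle spans two; SBP/DBP
labels are the ABP extrema over the *foot-to-foot* span (the window
containing exactly one pressure pulse).  Cycles whose max-slope point
is non-causal or beyond the first RR are dropped and counted
(`ptt_invalid`).

BP exclusion removes cycles with SBP ≥ 180, SBP ≤ 80, DBP ≥ 130 or
DBP ≤ 60 mmHg (removal *at* the printed value, i.e. survivors satisfy
the strict open box).  Each removed cycle is attributed to the first
rule it violates in the fixed order (sbp_high, sbp_low, dbp_high,
dbp_low), so per-rule counts sum to the removals; the filter is
idempotent.

## Dataset

Features form a 7×T matrix (row order PTT, HR, RI, ST, UT, SV, DV;
columns time-ordered by record then cycle), targets a 2×T matrix.
Cycles are split 80/20 at random (`round(0.8·T)` training columns,
seeded).  Feature rows are z-scored and target rows min–max scaled to
[0, 1] using statistics from the **training columns only** (default
`stats_scope='train'`, avoiding test-set leakage; `'all'` reproduces
whole-dataset scaling).  The standard-deviation convention is
population (divide by n) throughout.  Test-time targets outside the
training min–max clip to [0, 1] with a warning.  All statistics are
stored on the dataset and in its JSON sidecar for exact inversion.

## Models

The sequence regressors share one topology: BiLSTM(d) →
n × LSTM(d) → FC(d) + ReLU → linear(2), with dropout 0.2 on every
recurrent layer's output and d = 256 hidden units by default.  Model 1
has n = 4 plain LSTM layers; Models 2/3/4 have n = 4/5/6 layers each
wrapped in an identity residual shortcut Y = F(x) + x.  The BiLSTM's
forward and backward outputs are **summed**, not concatenated, so its
output width equals d and every residual shortcut is parameter-free —
consequently Models 1 and 2 have identical parameter counts, and each
extra layer costs exactly 4·(d·(d+d)+d) parameters.

Training: MSE on the normalized (SBP, DBP) pair at every time step
(sequence-to-sequence), Adam with initial rate 0.003 multiplied by 0.2
every 125 iterations (a config switch changes the schedule unit to
epochs), at most 50 epochs, Glorot-uniform initialization with
forget-gate bias 1, all randomness driven by explicit seeds.  The
cycle stream is cut into fixed-length subsequences
(`sequence_length`, default 200 cycles) with recurrent state reset per
subsequence; equal-length subsequences are batched together and the
trailing short block rides in its own mini-batch.  A non-finite loss
aborts with the epoch/iteration in the message.

Prediction traverses the stream in the same non-overlapping windows
with state reset, emitting one denormalized (SBP, DBP) per cycle.
Streaming prediction buffers cycles until a window fills and then
flushes it — identical computation, so batch and streaming outputs
coincide to machine precision, and a skipped cycle becomes a gap
marker without disturbing the window buffer.  The BiLSTM's backward
pass is what forces the one-window look-back latency.

Baselines: per-target OLS (rank-deficient designs raise an error naming
the collinear features), bootstrap-aggregated regression trees and
least-squares boosting of depth-3 trees (scikit-learn;
`n_estimators=0` boosting degenerates to the training-mean predictor),
and a five-layer fully-connected comparator (256 units in layers 1–4,
identity shortcuts on the width-preserving layers, no recurrence)
built from the same NumPy layer stack.

The NumPy implementation was chosen deliberately: the models are small
enough that BPTT on CPU trains the benchmark configurations in
seconds, and the absence of a framework dependency keeps the package
self-contained.  Gradients are verified against finite differences in
the test suite.

## Synthetic data: what it emulates and what it does not

The simulator generates triplets with fully known ground truth.  Beats
are scheduled from the (per-cycle or constant) heart rate; the ECG is a
narrow Gaussian R spike (σ = 8 ms) plus small optional P/T bumps; the
PPG beat is two Gaussian lobes (systolic at 18 % of the beat span,
reflected at 45 %, relative amplitude = configured reflection index)
minus the chord through the beat endpoints, plus a small parabolic
bulge 4u(1−u)·0.05 that keeps the diastolic tail strictly decreasing
into the next foot — so the foot is the unique per-beat minimum and all
four landmarks exist analytically.  The pulse is positioned so the
maximum-slope point lags the R peak by the configured PTT (±1 sample).
The ABP shares the PPG's beat shape, rescaled per beat so the
foot-to-foot extrema equal the configured DBP/SBP exactly.  Record
edges are filled with virtual-beat context so the pulse train has no
flat segments (a flat segment acts as a boxcar envelope whose
sub-cutoff DFT leakage would reappear as baseline ripple after
filtering and bias the volume features).  Drift (a sub-0.1 Hz sinusoid
on ECG/PPG) and white noise (all channels) are added only after ground
truth is extracted from the clean signals.  One
`numpy.random.default_rng(seed)` stream drives everything, so records
are bit-reproducible.

Ground-truth feet, systolic peaks and max-slope points are geometric
(construction/argmax); the truth notch and second peak are located by
their *definitional* procedures (chord subtraction, second-difference
minimum) applied to the clean waveform, since those procedures are what
defines the landmarks.

A separate feature-level benchmark (`planted_feature_table`) plants a
known pressure law, SBP = 200 − 120·PTT + N(0, 1 mmHg) and
DBP = SBP − 40, with the other six features as uninformative noise.
The 1 mmHg residual gives an analytic floor for the achievable test
MAE, the half-normal mean σ·√(2/π) ≈ 0.80 mmHg, which the OLS baseline
attains and against which the sequence models are judged (< 3 mmHg at
the benchmark size of 2,000 cycles).

Limitations of the synthetic conditions: waveform morphology does not
vary beat-to-beat, arrhythmias/ectopy, motion artifacts and
sensor-specific noise are absent, and the planted pressure law is
linear in one feature.  Passing the recovery and benchmark tests shows
the pipeline is internally correct and unbiased under controlled
conditions; it does not certify accuracy on clinical recordings, whose
error levels depend on signal quality and population diversity.

## Numerical choices and problem sizes

* Tie-breaks: earliest index for every arg-extremum (tolerance 1e−9
  relative).
* Discrete derivatives: forward first difference, centered second
  difference; 0-based indices, half-open intervals.
* Integrals: trapezoidal, dt = 1/f_s.
* Filter realness asserted at 1e−9 relative; normalization round-trips
  at 1e−9.
* Benchmark/test problem sizes are chosen for single-CPU runs: 2,000
  planted cycles, 32 hidden units, subsequence length 50, batch 8,
  ≤ 50 epochs for the Model 1 vs Model 2 comparison; unit tests use
  smaller configurations.  The architecture defaults
  (`hidden_units=256`, `sequence_length=200`) reflect the reference
  training protocol and remain available for larger runs.

## Evaluation conventions

Errors are signed, e = prediction − reference.  STD is the population
standard deviation of signed errors, giving the exact decomposition
RMSE² = ME² + STD² (verified to 1e−9 in the suite) and matching the
AAMI criterion's ME/SD semantics.  BHS grades require all three
cumulative thresholds of a row simultaneously (A: 60/85/95 %, B:
50/75/90 %, C: 40/65/85 % within 5/10/15 mmHg; otherwise D).  The
third BHS column is 15 mmHg per the published BHS protocol.  AAMI
passes iff |ME| < 5 mmHg, STD < 8 mmHg and the subject count exceeds
85; with simulated cohorts the "subject" count is the number of
records.
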