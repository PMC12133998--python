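# Methods

## Scope and model

`fpevent` processes continuous force-plate recordings from event-related
cognitive experiments into per-trial scalar summaries. The recording is a
multichannel time series (forces in N, moments in N·m) sampled at a fixed
rate (default 1000 Hz) together with a *level-held* trigger stream: the
experimental program holds an integer code on the parallel port until the
next event replaces it, so the code series is piecewise constant and a
maximal constant run is one event. All time-locking references event
*onsets* (the first sample of a run). Code 0 (all pins low) is a legal
event, conventionally the inter-trial interval.

## Filtering

The default filter is a 4th-order low-pass Butterworth with a 10-Hz
cutoff, designed by bilinear transform with frequency prewarping
(`scipy.signal.butter`), so the single-pass gain at the cutoff is exactly
$2^{-1/2}$ and DC gain is 1 (to ~1e-11 float noise). Ten hertz sits well
above postural-sway energy (< ~1 Hz) and below muscle-twitch and
line-noise artifacts; situational balance adjustments take on the order of
100 ms, so 10 Hz preserves them.

Zero-phase application uses a reversed-prefix pad rather than plain
forward–backward filtering: before each pass the series' first
$k = \min(\text{pad\_count}, N-1)$ samples (default pad 2000) are
prepended in reverse order, the filter runs with zero initial conditions,
and the $k$ padded outputs are dropped; the second pass applies the same
prepend–filter–drop to the time-reversed intermediate. The pad exists to
absorb the IIR start-up transient, which makes results insensitive to the
zero-initial-condition choice; with `pad_count=0` the scheme degenerates
to plain forward–backward filtering. Two properties worth noting:

- In the interior the scheme agrees with textbook zero-phase filtering
  (`filtfilt`) to float precision; it differs only in edge handling.
- The scheme is *not* exactly time-reversal symmetric: the pad always sits
  at the current beginning of each pass, so filtering a reversed signal
  and reversing back matches direct filtering only once the edge
  transients have decayed (tested as an interior property).

Any stable rational filter can replace the default via
`FilterCoefficients`; stability (poles strictly inside the unit circle)
and a normalized denominator are enforced at construction. Filtering is
applied per channel to the whole continuous block *before* segmentation.

## Segmentation and baseline

Trial boundaries are half-open sample intervals
$[\text{onset}_i, \text{onset}_{i+1})$ of the start trigger; the final
trial runs to the end of the recording and samples before the first start
trigger belong to no trial. Trials missing an expected stimulus or
response event are kept and flagged `complete=False`; exclusion is always
an explicit analyst predicate (`exclude_rows`), never implicit. Condition
resolution is a pure lookup from trigger code to label; unmapped codes get
the explicit label `"unknown"`.

Baseline correction subtracts, per channel, the mean over a closed
interval $[a, b]$ ms after the baseline-trigger onset from the entire
trial. Endpoints are inclusive at sample resolution: the default
$[0, 215]$ ms at 1000 Hz averages exactly 216 samples, the bulk of the
fixation interval. When the baseline and start trigger share a code (128
by default) the baseline anchors at the trial's own start onset. The
alternative of truncating the window to each trial's actual fixation run
is expressible by changing `baseline_interval_ms`; the fixed window is the
default because it makes trials strictly comparable. Correction is
idempotent up to float noise, and a missing baseline trigger leaves the
channel untouched with the trial flagged.

## Time-locked bin statistics

Bins are half-open ms intervals $[s, e)$ relative to the lock-event
onset; sample $i$ belongs to the bin iff
$s \le (i - \text{anchor}) \cdot 1000 / f_s < e$, so each sample is
counted exactly once and $t = 0$ falls in the bin containing 0. At
1000 Hz a 150-ms bin holds exactly 150 samples. Every listed boundary
must lie on the bin-width grid through the anchor (e.g. boundaries
(−150, 150) with width 100 are rejected), which keeps bins aligned with
the event they are locked to. The first matching lock event wins
(configurable to last, for multi-subtask trials). Statistics are pure
functions of the raw slice — defaults: mean, sample standard deviation
(ddof = 1), range (max − min) — registered by name and user-extensible;
adding one never perturbs existing columns. Bins truncated by trial edges
use the available samples and set a flag; trials without a lock event
carry missing values, never silent zeros.

## Tables

Behavioral files are DSV with a header row; subject/block identity is
parsed from filenames (`subj<digits>`, optional `block<digits>`, first
match wins, case-sensitive — the matching convention is ours since only
positive examples exist). Trials are numbered by row order within
(subject, block) when no trial column exists, which makes alignment with
the force-plate trials *positional*; `combine_data` therefore refuses
partial key overlaps (it joins only identical key sets and stacks only
disjoint ones), so row loss is impossible to miss. Decimal separator is
`.` only; locale exports must be converted beforehand.

## Synthetic generator

The generator emulates the statistical structure of a standing
Simon-task study — not biomechanics. Defaults: 10 blocks × 80 trials at
1000 Hz; fixation durations 216/217 ms with 5 % tails uniform in
[214, 250] ms; balanced stimulus codes {1, 2, 4, 8} (each 20× per
block); response times log-normal (median 450 ms, σ_log = 0.25,
truncated at 150 ms); 10 % incorrect responses; response code held
150 ms; inter-trial interval uniform 800–1200 ms; 500 ms lead-in before
the first trial. Channels: Mx and My are sums of two sub-hertz sinusoids
(0.3 and 0.7 Hz, amplitudes 0.5 and 0.3 N·m, random phases per block)
plus white noise (sd 0.05 N·m) and an optional 50-Hz line component; Fz
is a constant 800 N standing load plus noise. A planted effect multiplies
the white noise inside a chosen window around the response (default
[−150, 0) ms) for a chosen stimulus subset.

Randomness is one seed with explicit per-block stream splitting
(`SeedSequence.spawn`), so a corpus is byte-identical across runs and
adding blocks never changes earlier blocks. The schedule is the ground
truth and is written beside the raw files; tests compare pipeline output
against it, never against quantities re-derived from the signal.

What passing tests show — and do not. The generator's triggers are
noise-free and exactly level-held, its sway is stationary and sinusoidal,
and its planted effects are sharp-edged; real recordings have pin-switch
transients (`suppress_glitches` exists for these, default off), drift,
non-stationary sway and soft effects. Ground-truth recovery therefore
validates the pipeline's bookkeeping and numerics, not the physiology of
any real dataset.

The planted-effect recovery experiment (a 0.5 noise-sd multiplier in the
pre-response window for stimulus codes {1, 2}, 400 trials per condition)
is run with the sway sinusoids off and the low-pass filter disabled: the
recovered A/B ratio of mean bin-sd estimates the multiplier only when the
bin-sd is noise-dominated, and the filter's ~100-ms impulse response
would blur the planted window's edges. Both choices isolate the quantity
the experiment measures; the filter's own behavior is validated
separately on analytic signals.

## Numerical choices and sizes

- Filter passes use zero initial conditions (the pad absorbs the
  transient); gains are evaluated on the unit circle via
  `scipy.signal.freqz`.
- Stats tables round-trip through CSV at full float `repr` precision, so
  write→read is exact; keys (subject, block, trial) are nullable integers
  (block may be absent).
- Tests and the acceptance script run the default 10 × 80 corpus in
  memory for ground-truth checks and a 2 × 10 corpus for on-disk
  byte-identity checks; the end-to-end shape check writes the full corpus
  to disk once. These sizes keep the full verification run in well under
  a minute per stage while preserving the study's trial counts where they
  matter (800 trials, 400 per condition).

## Known limitations

- No vendor binary formats; text export only.
- No artifact-based trial rejection, spectral/nonlinear sway measures, or
  downstream inference — those are the analyst's layer.
- The glitch suppressor merges short runs into their predecessor; a
  hardware stack with longer switching transients needs the threshold
  raised, and genuinely short experimental events would be eaten by an
  overly large threshold (hence default 0 = off).
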