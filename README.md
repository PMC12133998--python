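# fpevent — event-related processing of force-plate time series

Force plates measure ground-reaction forces (Fx, Fy, Fz, in N) and moments
(Mx, My, Mz, in N·m) continuously, typically at 1000 Hz. Posturography has
traditionally summarized such recordings over whole blocks of seconds to
minutes, which masks the fast, trial-locked interplay between cognition and
balance. The *event-related* approach instead summarizes short time bins
locked to recurring experimental events (stimulus onset, the response),
yielding one or more scalar sway measures per trial — analogous to
event-related designs in EEG or fMRI. `fpevent` implements that approach as
a tested Python library with a thin command-line front end, for researchers
running cognitive experiments (e.g. conflict tasks) on a force plate.

## The processing model

Given a raw recording with a level-held integer trigger stream (a parallel
port with $N$ pins encodes $2^N$ codes; each code is held until the next
event), the pipeline applies, in order:

1. **Filtering.** A 4th-order low-pass Butterworth at 10 Hz, run forward
   and backward so the net phase shift is zero and the effective magnitude
   response is $|H(f)|^2$. Each pass first prepends the series' initial
   $n = 2000$ samples in reverse order and drops them afterwards, absorbing
   the start-up transient.
2. **Segmentation.** Trial $i$ spans $[\mathrm{onset}_i, \mathrm{onset}_{i+1})$
   of the start trigger (the fixation cross, code 128); within-trial events
   and condition labels (stimulus ∈ {1, 2, 4, 8}, correctness ∈ {32, 64})
   are attached.
3. **Baseline correction.** Per channel, the mean over the fixation
   interval $[0, 215]$ ms after the baseline-trigger onset — exactly 216
   samples at 1000 Hz — is subtracted from the whole trial.
4. **Time-locked bin statistics.** Each trial is anchored at its response
   onset and summarized over half-open bins $[-150, 0)$ and $[0, 150)$ ms
   with mean, sample standard deviation ($n-1$) and range
   ($\max - \min$) per channel (Mx, My by default) — statistics and bins
   are user-extensible.
5. **Table merging.** The per-trial statistics join behavioral tables on
   (subject, block, trial); identity comes from filenames containing
   `subj<digits>` and optionally `block<digits>`.

A seeded synthetic-recording generator emulates the whole study structure
(10 blocks × 80 trials, level-held trigger schedule, sway + noise channel
model, plantable condition effects) with a ground-truth schedule, so every
stage is verifiable end to end without any external data.

## Worked example

```python
from fpevent import (PipelineConfig, SyntheticConfig, corpus_format_spec,
                     run_pipeline, write_corpus)

syn = SyntheticConfig(n_blocks=2, n_trials_per_block=10)
write_corpus(syn, seed=1, outdir="corpus")
config = PipelineConfig(format=corpus_format_spec(syn),
                        input_glob="corpus/fp_subj*.txt",
                        behavioral_glob="corpus/exp_subj*.csv",
                        output_dir="out")
stats = run_pipeline(config)
print(stats[["subject", "block", "trial", "rt_ms", "Mx_[-150,0)_sd"]].head(3))
```

prints

```
 subject  block  trial   rt_ms  Mx_[-150,0)_sd
       1      1      1 360.557        0.029407
       1      1      2 309.946        0.070190
       1      1      3 489.761        0.060888
```

— one row per trial: the behavioral response time alongside the filtered,
baseline-corrected mediolateral sway variability in the 150 ms before the
response. `out/` also receives the effective config (re-running from it
reproduces the outputs bit-for-bit) and a run log. The `examples/`
directory walks through each stage separately, and the same pipeline is
available from the shell:

```sh
fpevent generate --seed 1 --out corpus
fpevent process config.yaml
```

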