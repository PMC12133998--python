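"""Compute response-locked bin statistics, one scalar row per trial.

The default analysis mirrors a Simon-task posturography design: lock each
trial at its response onset (codes 32/64) and summarize the plate moments
Mx and My over the bins [-150, 0) and [0, 150) ms with mean, sd and range.
"""

from fpevent import (BinSpec, SegmentationSpec, SyntheticConfig,
                     baseline_correct, compute_bin_stats, extract_events,
                     generate_corpus, resolve_bins, segment_recording)

config = SyntheticConfig(n_blocks=1, n_trials_per_block=10)
(rec,), _ = generate_corpus(config, seed=1)
spec = SegmentationSpec()
segments = [baseline_correct(s, spec, ["Mx", "My"])
            for s in segment_recording(
                rec, extract_events(rec.trigger_codes, rec.sampling_rate),
                spec)]

bin_spec = BinSpec()
print("bins relative to the response onset:", resolve_bins(bin_spec))

stats = compute_bin_stats(segments, bin_spec)
cols = ["trial", "cond_stimulus", "Mx_[-150,0)_mean", "Mx_[-150,0)_sd",
        "Mx_[0,150)_sd"]
print(stats[cols].head(5).to_string(index=False))
# each row condenses one trial's pre- and post-response sway into scalars
# ready for a mixed-effects analysis
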