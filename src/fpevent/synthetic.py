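"""Synthetic force-plate recordings with known ground truth.

The generator emulates the structure of a standing Simon-task experiment:
10 blocks of 80 trials sampled at 1000 Hz, each trial a level-held trigger
sequence fixation (128) → stimulus (one of {1, 2, 4, 8}) → response (32
correct / 64 incorrect) → inter-trial interval (0).  Fixation durations
concentrate on 216/217 ms with rare tails in [214, 250] ms; response times
are log-normal.  Channels are a sum of slow sway sinusoids (< 1 Hz), white
noise, and an optional 50-Hz line-noise component, plus a constant-load
Fz; a *planted effect* can multiply the noise sd inside a chosen window
around the response for a chosen stimulus subset, giving downstream
statistics a known condition difference to recover.

Randomness is a single seed with explicit per-block stream splitting, so
the corpus is byte-identical across runs and adding blocks never changes
earlier blocks' data.  The per-trial schedule — the ground truth — is
always available (and written beside the raw files); tests never re-derive
truth from the signal.  The generator targets the statistical structure of
such recordings, not biomechanical fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fileio import RawRecording, RecordingFormatSpec, SubjectBlockID
from .triggers import encode_pin_levels

__all__ = ["SyntheticConfig", "generate_schedule", "synthesize_recording",
           "generate_corpus", "write_corpus", "corpus_format_spec"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design, channel model and planted effect for one corpus.

    Durations are in ms.  ``effect_noise_multiplier`` scales the white
    noise inside ``effect_window_ms`` (relative to response onset) for
    trials whose stimulus code is in ``effect_codes``; 1.0 disables the
    effect.  With the default balanced stimulus assignment, codes (1, 2)
    versus (4, 8) split the corpus into two equal condition groups.
    """

    sampling_rate: float = 1000.0
    n_blocks: int = 10
    n_trials_per_block: int = 80
    subject: int = 1

    fixation_code: int = 128
    stimulus_codes: tuple[int, ...] = (1, 2, 4, 8)
    response_codes: tuple[int, int] = (32, 64)  # (correct, incorrect)
    iti_code: int = 0

    fixation_main_ms: tuple[int, int] = (216, 217)
    fixation_tail_range_ms: tuple[int, int] = (214, 250)
    fixation_tail_prob: float = 0.05
    rt_meanlog: float = float(np.log(450.0))
    rt_sdlog: float = 0.25
    rt_min_ms: float = 150.0
    response_hold_ms: float = 150.0
    iti_range_ms: tuple[float, float] = (800.0, 1200.0)
    lead_in_ms: float = 500.0
    p_incorrect: float = 0.1

    sway_freqs_hz: tuple[float, ...] = (0.3, 0.7)
    sway_amps: tuple[float, ...] = (0.5, 0.3)
    noise_sd: float = 0.05
    line_noise_amp: float = 0.0
    line_noise_hz: float = 50.0
    fz_newton: float = 800.0

    effect_codes: tuple[int, ...] = ()
    effect_window_ms: tuple[float, float] = (-150.0, 0.0)
    effect_noise_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.n_blocks < 1 or self.n_trials_per_block < 1:
            raise ValueError("need at least one block and one trial")
        if not (0 <= self.fixation_tail_prob <= 1):
            raise ValueError("fixation_tail_prob must be a probability")
        if self.effect_noise_multiplier < 0:
            raise ValueError("effect_noise_multiplier must be >= 0")
        if len(self.sway_freqs_hz) != len(self.sway_amps):
            raise ValueError("sway_freqs_hz and sway_amps lengths differ")


def _block_seeds(seed: int, n_blocks: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n_blocks)


def _ms_to_samples(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


def _block_schedule(config: SyntheticConfig, rng: np.random.Generator,
                    block: int) -> pd.DataFrame:
    """One block's ground-truth schedule; onsets in samples from block start."""
    n = config.n_trials_per_block
    fs = config.sampling_rate

    # balanced stimulus assignment: each code equally often, then shuffled
    reps = -(-n // len(config.stimulus_codes))
    stimuli = np.tile(config.stimulus_codes, reps)[:n]
    rng.shuffle(stimuli)

    fix_dur = np.where(
        rng.random(n) < config.fixation_tail_prob,
        rng.integers(config.fixation_tail_range_ms[0],
                     config.fixation_tail_range_ms[1] + 1, n),
        rng.choice(config.fixation_main_ms, n),
    ).astype(float)
    rt = np.maximum(rng.lognormal(config.rt_meanlog, config.rt_sdlog, n),
                    config.rt_min_ms)
    correct = rng.random(n) >= config.p_incorrect
    resp_code = np.where(correct, config.response_codes[0],
                         config.response_codes[1])
    iti = rng.uniform(*config.iti_range_ms, n)

    rows = []
    cursor = _ms_to_samples(config.lead_in_ms, fs)
    for i in range(n):
        fix_on = cursor
        stim_on = fix_on + _ms_to_samples(fix_dur[i], fs)
        resp_on = stim_on + _ms_to_samples(rt[i], fs)
        resp_off = resp_on + _ms_to_samples(config.response_hold_ms, fs)
        iti_end = resp_off + _ms_to_samples(iti[i], fs)
        if not (fix_on < stim_on < resp_on < resp_off < iti_end):
            raise ValueError(
                f"block {block} trial {i + 1}: durations imply overlapping "
                "events")
        rows.append({
            "subject": config.subject, "block": block, "trial": i + 1,
            "fixation_onset": fix_on, "fixation_duration_ms": fix_dur[i],
            "stimulus_code": int(stimuli[i]), "stimulus_onset": stim_on,
            "rt_ms": rt[i], "response_code": int(resp_code[i]),
            "response_onset": resp_on, "response_offset": resp_off,
            "iti_duration_ms": iti[i],
        })
        cursor = iti_end
    return pd.DataFrame(rows)


def generate_schedule(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Ground-truth schedule for the whole corpus, one row per trial.

    Onset columns are 0-based sample indices within each trial's block.
    Deterministic: the same seed and config always yield the same
    schedule.
    """
    frames = []
    for b, ss in enumerate(_block_seeds(seed, config.n_blocks), start=1):
        sched_rng = np.random.Generator(np.random.PCG64(ss.spawn(2)[0]))
        frames.append(_block_schedule(config, sched_rng, b))
    return pd.concat(frames, ignore_index=True)


def _level_held_codes(schedule: pd.DataFrame, config: SyntheticConfig,
                      n_samples: int) -> np.ndarray:
    codes = np.full(n_samples, config.iti_code, dtype=np.int64)
    for row in schedule.itertuples():
        codes[row.fixation_onset:row.stimulus_onset] = config.fixation_code
        codes[row.stimulus_onset:row.response_onset] = row.stimulus_code
        codes[row.response_onset:row.response_offset] = row.response_code
    return codes


def synthesize_recording(schedule: pd.DataFrame, config: SyntheticConfig,
                         seed_seq: np.random.SeedSequence | int,
                         block: int) -> RawRecording:
    """Render one block's schedule into a continuous recording.

    Channels: Mx and My carry sway sinusoids + white noise (+ optional
    line noise + planted effect); Fz is the constant standing load plus
    noise.  Trigger codes are the level-held schedule.
    """
    if isinstance(seed_seq, int):
        seed_seq = np.random.SeedSequence(seed_seq)
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    fs = config.sampling_rate
    tail_ms = config.iti_range_ms[1]
    n = int(schedule["response_offset"].max()) + _ms_to_samples(tail_ms, fs)
    t = np.arange(n) / fs

    def sway_channel() -> np.ndarray:
        phases = rng.uniform(0, 2 * np.pi, len(config.sway_freqs_hz))
        out = np.zeros(n)
        for f, a, ph in zip(config.sway_freqs_hz, config.sway_amps, phases):
            out += a * np.sin(2 * np.pi * f * t + ph)
        noise = rng.normal(0.0, config.noise_sd, n)
        if config.effect_noise_multiplier != 1.0 and config.effect_codes:
            w0, w1 = config.effect_window_ms
            for row in schedule.itertuples():
                if row.stimulus_code in config.effect_codes:
                    lo = row.response_onset + _ms_to_samples(w0, fs)
                    hi = row.response_onset + _ms_to_samples(w1, fs)
                    noise[max(lo, 0):max(hi, 0)] *= config.effect_noise_multiplier
        out += noise
        if config.line_noise_amp:
            out += config.line_noise_amp * np.sin(
                2 * np.pi * config.line_noise_hz * t)
        return out

    channels = {
        "Mx": sway_channel(),
        "My": sway_channel(),
        "Fz": config.fz_newton + rng.normal(0.0, config.noise_sd, n),
    }
    return RawRecording(
        id=SubjectBlockID(subject=config.subject, block=block),
        sampling_rate=fs,
        time=np.arange(n, dtype=float) / fs * 1000.0,
        channels=channels,
        trigger_codes=_level_held_codes(schedule, config, n),
    )


def generate_corpus(config: SyntheticConfig, seed: int
                    ) -> tuple[list[RawRecording], pd.DataFrame]:
    """All blocks' recordings plus the full ground-truth schedule."""
    schedule = generate_schedule(config, seed)
    recordings = []
    for b, ss in enumerate(_block_seeds(seed, config.n_blocks), start=1):
        block_sched = schedule[schedule["block"] == b]
        recordings.append(
            synthesize_recording(block_sched, config, ss.spawn(2)[1], b))
    return recordings, schedule


#: Header lines written atop every synthetic raw file, exercising skipping.
_HEADER = ["# synthetic force-plate export", "# channels: time Mx My Fz pins0-7"]


def corpus_format_spec(config: SyntheticConfig) -> RecordingFormatSpec:
    """Format spec matching the files :func:`write_corpus` emits."""
    return RecordingFormatSpec(
        sampling_rate=config.sampling_rate,
        delimiter="\t",
        header_lines=len(_HEADER),
        channel_columns={"Mx": 1, "My": 2, "Fz": 3},
        pin_columns=list(range(4, 12)),
        time_column=0,
    )


def write_corpus(config: SyntheticConfig, seed: int, outdir: str | Path
                 ) -> dict[str, list[Path]]:
    """Write the corpus to disk: raw DSVs, behavioral DSVs, ground truth.

    Raw files are tab-delimited ``fp_subj<S>_block<B>.txt`` with two
    comment header lines and pin-level voltage columns; behavioral files
    are ``exp_subj<S>_block<B>.csv`` with RT/accuracy/condition columns;
    the schedule lands in ``ground_truth_subj<S>.csv``.  Identical seed
    and config give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recordings, schedule = generate_corpus(config, seed)
    paths: dict[str, list[Path]] = {"raw": [], "behavioral": [], "truth": []}

    for rec in recordings:
        b = rec.id.block
        raw_path = outdir / f"fp_subj{config.subject:03d}_block{b:03d}.txt"
        pins = encode_pin_levels(rec.trigger_codes, n_pins=8).astype(np.int64)
        body = pd.DataFrame({"time": rec.time, "Mx": rec.channels["Mx"],
                             "My": rec.channels["My"],
                             "Fz": rec.channels["Fz"]})
        for p in range(pins.shape[1]):
            body[f"pin{p}"] = pins[:, p]
        with open(raw_path, "w") as fh:
            fh.write("\n".join(_HEADER) + "\n")
            body.to_csv(fh, sep="\t", header=False, index=False,
                        float_format="%.17g")
        paths["raw"].append(raw_path)

        block_sched = schedule[schedule["block"] == b]
        beh = pd.DataFrame({
            "rt_ms": block_sched["rt_ms"].round(3).values,
            "accuracy": (block_sched["response_code"]
                         == config.response_codes[0]).astype(int).values,
            "stimulus_code": block_sched["stimulus_code"].values,
        })
        beh_path = outdir / f"exp_subj{config.subject:03d}_block{b:03d}.csv"
        beh.to_csv(beh_path, index=False)
        paths["behavioral"].append(beh_path)

    truth_path = outdir / f"ground_truth_subj{config.subject:03d}.csv"
    schedule.to_csv(truth_path, index=False)
    paths["truth"].append(truth_path)
    return paths
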