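"""Class-conditioned synthetic lead-II ECG generator with known R-peaks.

Each cardiac cycle is a sum of five Gaussian deflections (P, Q, R, S, T)
on a baseline, plus a class-dependent ST-segment shelf between the S and
T waves.  Severity is encoded the way heart-failure ECGs are described
clinically: grade I has normal QRS-dominated beats with amplitudes inside
[0, 1], grades II-IV show progressively larger ST deviation (here:
deepening ST depression, with T-wave inversion at grade IV) and wider
amplitude dispersion.  The generator therefore provides (a) exact
ground-truth R-peak positions for detector validation and (b) a
controllable class effect for classifier recovery studies — while making
no claim of physiological fidelity (see the package methods note).

Records are built by overlap-adding per-beat deflections at jittered RR
intervals onto the full-length sample grid, so beats blend smoothly and
R ground truth is simply the rounded R-deflection centers.  The final
waveform is clipped to the class amplitude envelope, which makes the
envelope a hard guarantee; at the default noise level the clip almost
never engages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .io_ecg import ECGRecord

__all__ = [
    "BeatMorphology",
    "SynthConfig",
    "synth_beat",
    "synth_record",
    "synth_dataset",
    "iter_records",
    "cohort_proportions",
]

WAVE_NAMES = ("P", "Q", "R", "S", "T")


@dataclass
class BeatMorphology:
    """One class's beat shape: Gaussian deflection parameters + ST shelf.

    ``amps`` are signal-unit amplitudes of P/Q/R/S/T, ``centers`` their
    time offsets from the R-peak in seconds, ``widths`` the Gaussian
    sigmas in seconds.  ``st_offset`` shifts the ST window (an ST shelf
    from ~50 to ~160 ms after R); ``amp_jitter`` is the relative s.d. of
    the per-beat amplitude multiplier (truncated at 2 s.d.), modelling
    beat-to-beat dispersion.  ``envelope`` is the (min, max) amplitude
    range the class's samples must stay inside.
    """

    amps: tuple = (0.12, -0.18, 0.60, -0.22, 0.25)
    centers: tuple = (-0.20, -0.04, 0.0, 0.04, 0.24)
    widths: tuple = (0.028, 0.012, 0.013, 0.013, 0.045)
    baseline: float = 0.28
    st_offset: float = 0.0
    amp_jitter: float = 0.04
    envelope: tuple = (0.0, 1.0)

    def template(self, fs: float, pre_s: float = 0.30, post_s: float = 0.45) -> np.ndarray:
        """Noiseless single-cycle waveform sampled at fs (jitter multiplier 1)."""
        t = np.arange(-pre_s, post_s, 1.0 / fs)
        return self.baseline + _deflections(t, self, 1.0)

    def validate(self) -> None:
        lo, hi = self.envelope
        tpl = self.template(fs=500.0)  # fine grid for extreme checking
        if tpl.min() < lo - 1e-9 or tpl.max() > hi - 0.0:
            raise ValueError(
                f"morphology violates its amplitude envelope {self.envelope}: "
                f"template range [{tpl.min():.3f}, {tpl.max():.3f}]"
            )


def _st_shelf(t: np.ndarray) -> np.ndarray:
    """Smooth plateau over the ST window (~0.05-0.16 s after the R-peak)."""
    return 1.0 / (1.0 + np.exp(-(t - 0.05) / 0.012)) / (1.0 + np.exp((t - 0.16) / 0.018))


def _deflections(t: np.ndarray, m: BeatMorphology, mult: float) -> np.ndarray:
    y = np.zeros_like(t, dtype=float)
    for a, c, w in zip(m.amps, m.centers, m.widths):
        y += mult * a * np.exp(-0.5 * ((t - c) / w) ** 2)
    y += mult * m.st_offset * _st_shelf(t)
    return y


def _default_morphologies() -> dict:
    return {
        1: BeatMorphology(),
        2: BeatMorphology(
            amps=(0.15, -0.30, 1.10, -0.50, 0.35), baseline=0.20,
            st_offset=-0.18, amp_jitter=0.12, envelope=(-2.0, 2.0),
        ),
        3: BeatMorphology(
            amps=(0.15, -0.40, 1.60, -0.70, 0.45), baseline=0.20,
            st_offset=-0.35, amp_jitter=0.15, envelope=(-2.0, 2.8),
        ),
        4: BeatMorphology(
            amps=(0.15, -0.50, 1.30, -1.10, -0.40), baseline=0.15,
            st_offset=-0.55, amp_jitter=0.15, envelope=(-2.8, 2.2),
        ),
    }


@dataclass
class SynthConfig:
    """Generator settings: cohort mix, rate, morphology, noise, seed.

    Defaults emulate the study conditions: 30-minute lead-II records at
    125 Hz, patient counts 8/47/115/98 for NYHA I-IV, heart rate ~75 bpm
    with RR jitter, and the per-class amplitude envelopes [0,1], [-2,2],
    [-2,2.8], [-2.8,2.2].
    """

    fs: float = 125.0
    record_seconds: int = 1800
    n_records_per_class: tuple = (8, 47, 115, 98)
    hr_mean: float = 75.0
    hr_sd: float = 5.0
    rr_jitter_sd: float = 0.04
    noise_sd: float = 0.02
    morphologies: dict = field(default_factory=_default_morphologies)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.record_seconds <= 0:
            raise ValueError("fs and record_seconds must be positive")
        offs = [abs(self.morphologies[c].st_offset) for c in (1, 2, 3, 4)]
        if not all(a <= b + 1e-12 for a, b in zip(offs, offs[1:])):
            raise ValueError(
                "|st_offset| must be monotone non-decreasing from class I to IV, "
                f"got {offs}"
            )

    @classmethod
    def null_effect(cls, **kwargs) -> "SynthConfig":
        """All four classes share one morphology: no class signal at all."""
        shared = BeatMorphology(
            amps=(0.15, -0.30, 1.10, -0.50, 0.35), baseline=0.20,
            st_offset=0.0, amp_jitter=0.12, envelope=(-2.0, 2.0),
        )
        return cls(morphologies={c: replace(shared) for c in (1, 2, 3, 4)}, **kwargs)

    @classmethod
    def reduced_study(cls, n_records: int = 10, record_seconds: int = 240,
                      **kwargs) -> "SynthConfig":
        """Balanced desk-scale conditions: n_records per class, short records."""
        return cls(
            record_seconds=record_seconds,
            n_records_per_class=(n_records,) * 4,
            **kwargs,
        )


def synth_beat(
    nyha_class: int,
    morphology: Optional[BeatMorphology] = None,
    rng: Optional[np.random.Generator] = None,
    fs: float = 125.0,
    rr_s: float = 0.8,
) -> tuple[np.ndarray, int]:
    """One noiseless cardiac cycle and the index of its R-peak.

    The beat spans from 0.30 s before the R deflection to ``rr_s - 0.30`` s
    after it; the reported R index is the argmax of the waveform.
    """
    if morphology is None:
        morphology = _default_morphologies()[nyha_class]
    morphology.validate()
    rng = rng or np.random.default_rng()
    mult = 1.0 + float(np.clip(rng.normal(0.0, morphology.amp_jitter),
                               -2 * morphology.amp_jitter, 2 * morphology.amp_jitter))
    pre_s = 0.30
    t = np.arange(-pre_s, rr_s - pre_s, 1.0 / fs)
    beat = morphology.baseline + _deflections(t, morphology, mult)
    return beat, int(np.argmax(beat))


def synth_record(
    cfg: SynthConfig,
    nyha_class: int,
    rng: np.random.Generator,
    subject_id: str = "synth",
) -> tuple[ECGRecord, np.ndarray]:
    """One record of ``cfg.record_seconds`` at ``cfg.fs`` plus true R indices.

    RR intervals are Normal(60/hr, rr_jitter_sd) truncated positive; the
    heart rate itself is drawn per record from Normal(hr_mean, hr_sd).
    Ground-truth R positions are the rounded R-deflection centers that fall
    at least 100 ms inside the record.
    """
    m = cfg.morphologies[nyha_class]
    m.validate()
    n = int(round(cfg.record_seconds * cfg.fs))
    hr = float(np.clip(rng.normal(cfg.hr_mean, cfg.hr_sd), 40.0, 140.0))
    rr_base = 60.0 / hr
    n_beats_est = int(np.ceil(cfg.record_seconds / rr_base)) + 4
    if cfg.record_seconds < 2 * rr_base:
        raise ValueError(
            f"record of {cfg.record_seconds}s holds fewer than 2 beats at {hr:.0f} bpm"
        )
    rr = rr_base + rng.normal(0.0, cfg.rr_jitter_sd, size=n_beats_est)
    rr = np.clip(rr, 0.35, None)
    r_times = 0.4 + np.concatenate([[0.0], np.cumsum(rr)])
    r_times = r_times[r_times < cfg.record_seconds + 0.5]

    signal = np.full(n, m.baseline, dtype=float)
    half_span_s = 0.45  # covers every deflection center +- 4 sigma
    half_span = int(half_span_s * cfg.fs) + 1
    mults = 1.0 + np.clip(rng.normal(0.0, m.amp_jitter, size=len(r_times)),
                          -2 * m.amp_jitter, 2 * m.amp_jitter)
    for r_time, mult in zip(r_times, mults):
        center = int(round(r_time * cfg.fs))
        lo = max(0, center - half_span)
        hi = min(n, center + half_span)
        if lo >= hi:
            continue
        t_local = (np.arange(lo, hi) - r_time * cfg.fs) / cfg.fs
        signal[lo:hi] += _deflections(t_local, m, mult)
    if cfg.noise_sd > 0:
        signal += rng.normal(0.0, cfg.noise_sd, size=n)
    np.clip(signal, m.envelope[0], m.envelope[1], out=signal)

    margin = 0.1
    keep = (r_times >= margin) & (r_times <= cfg.record_seconds - margin)
    r_indices = np.round(r_times[keep] * cfg.fs).astype(int)
    record = ECGRecord(
        subject_id=subject_id, lead="II", fs=cfg.fs,
        samples=signal.astype(np.float32), label=nyha_class,
    )
    return record, r_indices


def iter_records(cfg: SynthConfig) -> Iterator[tuple[ECGRecord, np.ndarray]]:
    """Yield (record, true R indices) pairs for the whole configured cohort.

    Records stream one at a time (a full-scale cohort is large); each
    record's randomness derives deterministically from ``cfg.seed`` and its
    position, so iteration order never changes the waveforms.
    """
    idx = 0
    for class_idx, n_rec in enumerate(cfg.n_records_per_class):
        nyha = class_idx + 1
        for k in range(n_rec):
            rng = np.random.default_rng([cfg.seed, idx])
            yield synth_record(cfg, nyha, rng, subject_id=f"S{nyha}-{k:03d}")
            idx += 1


def synth_dataset(cfg: SynthConfig):
    """Materialize the cohort: (records, r_truth list, manifest DataFrame)."""
    records, truths, rows = [], [], []
    idx = 0
    for class_idx, n_rec in enumerate(cfg.n_records_per_class):
        nyha = class_idx + 1
        for k in range(n_rec):
            rng = np.random.default_rng([cfg.seed, idx])
            rec, r_idx = synth_record(cfg, nyha, rng, subject_id=f"S{nyha}-{k:03d}")
            records.append(rec)
            truths.append(r_idx)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "label": nyha,
                    "fs": cfg.fs,
                    "record_seconds": cfg.record_seconds,
                    "n_r_peaks": len(r_idx),
                    "seed": cfg.seed,
                    "record_index": idx,
                }
            )
            idx += 1
    return records, truths, pd.DataFrame(rows)


def cohort_proportions(counts) -> np.ndarray:
    """Class proportions in percent, rounded to two decimals."""
    counts = np.asarray(counts, dtype=float)
    return np.round(100.0 * counts / counts.sum(), 2)
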