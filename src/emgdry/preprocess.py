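"""Denoising, offset removal and indicator-driven splicing.

The processing chain applied to each trial before feature extraction is
wavelet shrinkage denoising, per-channel offset (mean) removal, and splicing
into labelled rest/contraction segments by run-length parsing of the binary
movement indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pywt

from .errors import ConfigurationError, ValidationError
from .simulate import RecordingTrial, trial_with_samples


class SegmentSource(NamedTuple):
    """Provenance of a spliced segment."""

    subject_id: str
    electrode: str
    movement: str
    trial_index: int
    run_index: int  # 0-based position of the indicator run within the trial


@dataclass
class Segment:
    """A contiguous single-state run of samples, all channels retained.

    ``label`` is ``"rest"`` for indicator-0 runs and the trial's movement for
    indicator-1 runs.
    """

    samples: np.ndarray  # (n, n_channels)
    label: str
    source: SegmentSource

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


def parse_transitions(indicator) -> list[tuple[int, int, int]]:
    """Run-length encode a binary indicator into ``(start, end, state)``.

    Intervals are 0-based and half-open; the runs partition ``[0, n)`` exactly
    and states alternate.
    """
    ind = np.asarray(indicator)
    if ind.size == 0:
        raise ValidationError("indicator is empty")
    if not np.isin(ind, (0, 1)).all():
        bad = ind[~np.isin(ind, (0, 1))][0]
        raise ValidationError(f"indicator contains non-binary value {bad!r}")
    boundaries = np.flatnonzero(np.diff(ind) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [ind.shape[0]]))
    return [(int(s), int(e), int(ind[s])) for s, e in zip(starts, ends)]


def default_level(sample_rate: float, n_samples: int, wavelet: str = "db1") -> int:
    """Decomposition depth: deep enough that the approximation band sits below
    the EMG energy band (fs / 2^(L+1) <= ~15 Hz at 2000 S/s), capped at 6 and
    by the maximal depth the signal length supports."""
    level = min(6, int(math.floor(math.log2(sample_rate / 20.0))))
    max_level = pywt.dwt_max_level(n_samples, pywt.Wavelet(wavelet).dec_len)
    return max(1, min(level, max_level))


def denoise_signal(
    x: np.ndarray,
    sample_rate: float,
    wavelet: str = "db1",
    level: int | None = None,
    threshold_rule: str = "universal",
    mode: str = "soft",
) -> np.ndarray:
    """Wavelet shrinkage of a 1-D signal.

    Multi-level DWT with the chosen wavelet (Haar/db1 by default); the noise
    scale sigma is estimated from the median absolute deviation of the
    finest-level detail coefficients (MAD / 0.6745) and every detail level is
    soft-thresholded at the universal threshold ``sigma * sqrt(2 ln N)``
    before reconstruction.  The approximation coefficients are untouched.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if level is None:
        level = default_level(sample_rate, n, wavelet)
    elif 2**level > n:
        raise ConfigurationError(
            f"decomposition level {level} too deep for signal length {n}"
        )
    if threshold_rule != "universal":
        raise ConfigurationError(f"unknown threshold rule {threshold_rule!r}")
    coeffs = pywt.wavedec(x, wavelet, level=level)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745
    thr = sigma * math.sqrt(2.0 * math.log(max(n, 2)))
    if thr > 0:
        coeffs = [coeffs[0]] + [
            pywt.threshold(c, thr, mode=mode) for c in coeffs[1:]
        ]
    return pywt.waverec(coeffs, wavelet)[:n]


def denoise(
    trial: RecordingTrial,
    wavelet: str = "db1",
    level: int | None = None,
    threshold_rule: str = "universal",
    mode: str = "soft",
) -> RecordingTrial:
    """Apply :func:`denoise_signal` channel-wise; shape and metadata preserved."""
    out = np.column_stack(
        [
            denoise_signal(
                trial.samples[:, c],
                trial.sample_rate,
                wavelet=wavelet,
                level=level,
                threshold_rule=threshold_rule,
                mode=mode,
            )
            for c in range(trial.n_channels)
        ]
    )
    return trial_with_samples(trial, out)


def remove_offset(trial: RecordingTrial) -> RecordingTrial:
    """Subtract the per-channel mean over the whole trial."""
    if trial.n_samples == 0:
        raise ValidationError("cannot remove offset from an empty trial")
    return trial_with_samples(trial, trial.samples - trial.samples.mean(axis=0))


def splice(trial: RecordingTrial, trim: float = 0.0) -> list[Segment]:
    """Cut a trial into one labelled segment per indicator run.

    ``trim`` (seconds) removes a symmetric margin at both ends of every run,
    standing in for manual splice adjustment; 0 keeps the exact indicator
    boundaries.
    """
    runs = parse_transitions(trial.movement_indicator)
    t = int(round(trim * trial.sample_rate))
    if t < 0:
        raise ConfigurationError("trim must be >= 0")
    segments = []
    for run_index, (start, end, state) in enumerate(runs):
        s, e = start + t, end - t
        if e <= s:
            raise ConfigurationError(
                f"trim {trim}s leaves no samples in run [{start}, {end})"
            )
        segments.append(
            Segment(
                samples=trial.samples[s:e],
                label=trial.movement if state == 1 else "rest",
                source=SegmentSource(
                    trial.subject_id,
                    trial.electrode,
                    trial.movement,
                    trial.trial_index,
                    run_index,
                ),
            )
        )
    return segments
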