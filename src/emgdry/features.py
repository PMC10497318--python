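"""Time-domain sEMG features, the contraction/rest SNR statistic, and
per-movement summary tables.

The five features are the classic time-domain EMG descriptors computed per
segment per channel:

    RMS = sqrt( (1/N)     * sum x_n^2 )
    SD  = sqrt( (1/(N-1)) * sum x_n^2 )
    VAR =        (1/(N-1)) * sum x_n^2
    MAV =        (1/N)     * sum |x_n|
    WL  = sum |x_{n+1} - x_n|

SD and VAR are defined about zero rather than about the sample mean: the
signals have had their offset removed trial-wise beforehand, so the segment
mean is already ~0 and the zero-centred forms keep the exact identities
``VAR = SD**2`` and ``SD = RMS * sqrt(N/(N-1))``.  Pass ``center=True`` for
the conventional mean-centred SD/VAR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedSNRError
from .preprocess import Segment
from .protocol import CLASS_ORDER

FEATURE_NAMES: tuple[str, ...] = ("RMS", "SD", "VAR", "MAV", "WL")

_PROVENANCE_COLS = ("label", "subject", "electrode", "movement", "trial", "cycle")


def _as1d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("feature functions expect a 1-D sample sequence")
    return x


def rms(x) -> float:
    """Root mean square, ``sqrt(mean(x**2))``."""
    x = _as1d(x)
    if x.size < 1:
        raise ValueError("rms requires at least 1 sample")
    return float(np.sqrt(np.mean(x**2)))


def sd(x, center: bool = False) -> float:
    """Standard deviation about zero, ``sqrt(sum(x**2) / (N - 1))``."""
    x = _as1d(x)
    if x.size < 2:
        raise ValueError("sd requires at least 2 samples")
    if center:
        x = x - x.mean()
    return float(np.sqrt(np.sum(x**2) / (x.size - 1)))


def var(x, center: bool = False) -> float:
    """Variance about zero, ``sum(x**2) / (N - 1)``; equals ``sd(x)**2``."""
    x = _as1d(x)
    if x.size < 2:
        raise ValueError("var requires at least 2 samples")
    if center:
        x = x - x.mean()
    return float(np.sum(x**2) / (x.size - 1))


def mav(x) -> float:
    """Mean absolute value."""
    x = _as1d(x)
    if x.size < 1:
        raise ValueError("mav requires at least 1 sample")
    return float(np.mean(np.abs(x)))


def wl(x) -> float:
    """Waveform length: cumulative absolute successive difference."""
    x = _as1d(x)
    if x.size < 2:
        raise ValueError("wl requires at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


_FEATURE_FUNCS = {"RMS": rms, "SD": sd, "VAR": var, "MAV": mav, "WL": wl}
_MIN_SAMPLES = {"RMS": 1, "SD": 2, "VAR": 2, "MAV": 1, "WL": 2}


@dataclass
class FeatureDataset:
    """Per-segment feature matrix with labels and provenance.

    ``df`` holds one row per segment: the feature columns (named
    ``<FEATURE>_ch<k>``, features outer, channels inner) plus ``label`` and
    provenance columns. ``channels`` are 1-based channel numbers.
    """

    df: pd.DataFrame
    feature_names: tuple[str, ...]
    channels: tuple[int, ...]

    @property
    def feature_columns(self) -> list[str]:
        return [f"{f}_ch{c}" for f in self.feature_names for c in self.channels]

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def matrix(self) -> np.ndarray:
        return self.df[self.feature_columns].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    def select(
        self,
        features: Sequence[str] | None = None,
        channels: Sequence[int] | None = None,
    ) -> "FeatureDataset":
        """Restrict (and reorder) to a feature/channel subset."""
        features = tuple(features) if features is not None else self.feature_names
        channels = tuple(channels) if channels is not None else self.channels
        missing = [f for f in features if f not in self.feature_names]
        missing += [str(c) for c in channels if c not in self.channels]
        if missing:
            raise KeyError(f"dataset lacks requested features/channels: {missing}")
        cols = [f"{f}_ch{c}" for f in features for c in channels]
        keep = [c for c in _PROVENANCE_COLS if c in self.df.columns]
        return FeatureDataset(
            df=self.df[cols + keep].copy(),
            feature_names=features,
            channels=channels,
        )

    def subset_rows(self, mask) -> "FeatureDataset":
        return FeatureDataset(
            df=self.df.loc[mask].reset_index(drop=True),
            feature_names=self.feature_names,
            channels=self.channels,
        )

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.df.to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path) -> "FeatureDataset":
        df = pd.read_csv(path)
        feats, chans = [], []
        for col in df.columns:
            if "_ch" in col:
                f, _, c = col.rpartition("_ch")
                if f in FEATURE_NAMES and c.isdigit():
                    if f not in feats:
                        feats.append(f)
                    if int(c) not in chans:
                        chans.append(int(c))
        if not feats:
            raise ValueError(f"{path}: no feature columns found")
        return cls(df=df, feature_names=tuple(feats), channels=tuple(chans))


def extract(
    segments: Iterable[Segment],
    feature_subset: Sequence[str] | None = None,
    channel_subset: Sequence[int] | None = None,
    center: bool = False,
) -> FeatureDataset:
    """One feature vector per segment.

    Column order is deterministic: features outer, channels inner, e.g.
    ``RMS_ch1..RMS_ch4, MAV_ch1..``.  Channels are 1-based.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no segments to extract features from")
    features = tuple(feature_subset) if feature_subset else FEATURE_NAMES
    unknown = [f for f in features if f not in _FEATURE_FUNCS]
    if unknown:
        raise ValueError(f"unknown features: {unknown}; known: {FEATURE_NAMES}")
    n_ch = segments[0].samples.shape[1]
    channels = tuple(channel_subset) if channel_subset else tuple(range(1, n_ch + 1))
    bad = [c for c in channels if not 1 <= c <= n_ch]
    if bad:
        raise ValueError(f"channel indices out of range 1..{n_ch}: {bad}")
    min_len = max(_MIN_SAMPLES[f] for f in features)

    rows = []
    for seg in segments:
        if seg.n_samples < min_len:
            raise ValueError(
                f"segment {seg.source} has {seg.n_samples} sample(s); "
                f"features {features} need >= {min_len}"
            )
        row: dict = {}
        for f in features:
            func = _FEATURE_FUNCS[f]
            for c in channels:
                x = seg.samples[:, c - 1]
                row[f"{f}_ch{c}"] = (
                    func(x, center=center) if f in ("SD", "VAR") else func(x)
                )
        row["label"] = seg.label
        row["subject"] = seg.source.subject_id
        row["electrode"] = seg.source.electrode
        row["movement"] = seg.source.movement
        row["trial"] = seg.source.trial_index
        row["cycle"] = seg.source.run_index
        rows.append(row)
    return FeatureDataset(
        df=pd.DataFrame(rows), feature_names=features, channels=channels
    )


@dataclass(frozen=True)
class SNRReport:
    """Contraction-over-rest power ratio of a recording session."""

    snr_db: float
    mean_contraction_power: float  # mV^2
    mean_rest_power: float  # mV^2
    n_contraction: int
    n_rest: int


def compute_snr(segments: Iterable[Segment]) -> SNRReport:
    """Session SNR: mean per-segment power of contraction segments over mean
    per-segment power of rest segments, in dB (10*log10, power quantities).

    Per-segment power is the mean squared amplitude over samples and
    channels; segment powers are averaged unweighted.
    """
    contraction, rest = [], []
    for seg in segments:
        power = float(np.mean(seg.samples**2))
        (rest if seg.label == "rest" else contraction).append(power)
    if not contraction or not rest:
        raise UndefinedSNRError(
            f"SNR undefined: {len(contraction)} contraction and "
            f"{len(rest)} rest segment(s)"
        )
    pc = float(np.mean(contraction))
    pr = float(np.mean(rest))
    return SNRReport(
        snr_db=10.0 * np.log10(pc / pr),
        mean_contraction_power=pc,
        mean_rest_power=pr,
        n_contraction=len(contraction),
        n_rest=len(rest),
    )


def summarize(dataset: FeatureDataset, channel: int = 1) -> pd.DataFrame:
    """Mean +/- SD of every feature per class label for one channel.

    Returns a tidy frame with columns ``label, feature, mean, sd`` (population
    SD, so a single segment per class yields sd 0 rather than NaN); labels
    ordered canonically (rest last classes first per CLASS_ORDER) then any
    extras alphabetically.
    """
    if dataset.n == 0:
        raise ValueError("empty dataset")
    order = [c for c in CLASS_ORDER if c in set(dataset.labels)]
    order += sorted(set(dataset.labels) - set(order))
    records = []
    for label in order:
        sub = dataset.df[dataset.df["label"] == label]
        for f in dataset.feature_names:
            col = f"{f}_ch{channel}"
            if col not in dataset.df.columns:
                raise KeyError(f"channel {channel} not in dataset")
            vals = sub[col].to_numpy(dtype=float)
            records.append(
                {
                    "label": label,
                    "feature": f,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=0)),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(records)
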