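"""CSV persistence for trial recordings and spliced segments.

Dialect: a comment header of ``# key: value`` metadata lines followed by a
standard CSV table ``time,ch1..chN,movement`` (time in seconds, channels in
mV, movement the binary MVC indicator).
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .simulate import RecordingTrial

_META_KEYS = ("subject_id", "electrode", "movement", "trial_index", "sample_rate")


def trial_filename(trial: RecordingTrial) -> str:
    return (
        f"{trial.subject_id}_{trial.electrode}_{trial.movement}"
        f"_trial{trial.trial_index}.csv"
    )


def write_trial_csv(trial: RecordingTrial, path) -> Path:
    path = Path(path)
    n, n_ch = trial.samples.shape
    df = pd.DataFrame(
        {"time": np.arange(n) / trial.sample_rate}
        | {f"ch{c + 1}": trial.samples[:, c] for c in range(n_ch)}
        | {"movement": trial.movement_indicator.astype(int)}
    )
    with open(path, "w") as fh:
        fh.write("# emgdry trial\n")
        fh.write(f"# subject_id: {trial.subject_id}\n")
        fh.write(f"# electrode: {trial.electrode}\n")
        fh.write(f"# movement: {trial.movement}\n")
        fh.write(f"# trial_index: {trial.trial_index}\n")
        fh.write(f"# sample_rate: {trial.sample_rate}\n")
        df.to_csv(fh, index=False, float_format="%.6f")
    return path


def write_session_csv(trials, directory) -> list[Path]:
    """Write one CSV per trial into ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [write_trial_csv(t, directory / trial_filename(t)) for t in trials]


def _read_meta_and_table(path) -> tuple[dict, pd.DataFrame]:
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    if not body_lines:
        raise ParseError(f"{path}: empty file (no CSV table)")
    try:
        df = pd.read_csv(io.StringIO("".join(body_lines)))
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: malformed CSV ({exc})") from exc
    if df.empty:
        raise ParseError(f"{path}: CSV table has no rows")
    return meta, df


def _validate_indicator(df: pd.DataFrame, path) -> np.ndarray:
    if "movement" not in df.columns:
        raise ParseError(f"{path}: missing required column 'movement'")
    ind = df["movement"].to_numpy()
    bad = ~np.isin(ind, (0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ParseError(
            f"{path}: column 'movement' row {row} has non-binary value {ind[row]!r}"
        )
    return ind.astype(np.int8)


def read_trial_csv(path) -> RecordingTrial:
    """Read one trial CSV, validating the movement indicator and metadata."""
    meta, df = _read_meta_and_table(path)
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise ParseError(f"{path}: missing metadata lines for {missing}")
    indicator = _validate_indicator(df, path)
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    if not ch_cols:
        raise ParseError(f"{path}: no channel columns (ch1..chN) found")
    ch_cols = sorted(ch_cols, key=lambda c: int(c[2:]))
    samples = df[ch_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(samples)):
        raise ParseError(f"{path}: non-finite sample values")
    return RecordingTrial(
        samples=samples,
        movement_indicator=indicator,
        sample_rate=float(meta["sample_rate"]),
        subject_id=meta["subject_id"],
        electrode=meta["electrode"],
        movement=meta["movement"],
        trial_index=int(meta["trial_index"]),
    )


# synonym matching the generator vocabulary
read_session_csv = read_trial_csv


def write_segment_csv(segment, path) -> Path:
    """Persist one spliced segment; same dialect as trials plus a label line."""
    path = Path(path)
    n, n_ch = segment.samples.shape
    df = pd.DataFrame(
        {f"ch{c + 1}": segment.samples[:, c] for c in range(n_ch)}
    )
    subject, electrode, movement, trial, run = segment.source
    with open(path, "w") as fh:
        fh.write("# emgdry segment\n")
        fh.write(f"# label: {segment.label}\n")
        fh.write(f"# subject_id: {subject}\n")
        fh.write(f"# electrode: {electrode}\n")
        fh.write(f"# movement: {movement}\n")
        fh.write(f"# trial_index: {trial}\n")
        fh.write(f"# run_index: {run}\n")
        df.to_csv(fh, index=False, float_format="%.6f")
    return path


def read_segment_csv(path):
    from .preprocess import Segment, SegmentSource

    meta, df = _read_meta_and_table(path)
    needed = ("label", "subject_id", "electrode", "movement", "trial_index", "run_index")
    missing = [k for k in needed if k not in meta]
    if missing:
        raise ParseError(f"{path}: missing metadata lines for {missing}")
    ch_cols = sorted(
        (c for c in df.columns if c.startswith("ch")), key=lambda c: int(c[2:])
    )
    if not ch_cols:
        raise ParseError(f"{path}: no channel columns found")
    return Segment(
        samples=df[ch_cols].to_numpy(dtype=float),
        label=meta["label"],
        source=SegmentSource(
            meta["subject_id"],
            meta["electrode"],
            meta["movement"],
            int(meta["trial_index"]),
            int(meta["run_index"]),
        ),
    )
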