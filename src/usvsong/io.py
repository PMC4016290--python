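"""Pixel-trace CSV and ground-truth manifest input/output.

The pixel CSV dialect is one file per recording channel with header
``element_id,time_ms,freq_khz,amp_db``: the frequency-time-amplitude values of
every tracked spectrogram pixel, times strictly increasing within an element.
UTF-8, '.' decimal separator.
"""

from __future__ import annotations

import pandas as pd

from .core import PixelTrace

__all__ = [
    "PIXEL_COLUMNS",
    "MANIFEST_COLUMNS",
    "read_pixel_csv",
    "write_pixel_csv",
    "read_manifest",
    "write_manifest",
    "PixelCsvError",
]

PIXEL_COLUMNS = ["element_id", "time_ms", "freq_khz", "amp_db"]
MANIFEST_COLUMNS = [
    "element_id", "channel", "individual", "population", "sex",
    "context", "night", "song_id", "type13",
]


class PixelCsvError(ValueError):
    """Malformed pixel CSV; the message carries offending line numbers."""


def read_pixel_csv(path, channel: str = None) -> list:
    """Read one channel's pixel CSV into a list of :class:`PixelTrace`.

    Elements appear in file order.  Missing columns, non-numeric rows and
    non-monotone times within an element raise :class:`PixelCsvError` with
    line numbers (1-based, header = line 1).
    """
    df = pd.read_csv(path, dtype={"element_id": str})
    missing = [c for c in PIXEL_COLUMNS if c not in df.columns]
    if missing:
        raise PixelCsvError(f"{path}: missing columns {missing}")
    if channel is None:
        channel = str(path)
    bad = df[PIXEL_COLUMNS[1:]].isna().any(axis=1) | df["element_id"].isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise PixelCsvError(f"{path}: malformed rows at lines {lines[:20]}")
    traces = []
    for eid, grp in df.groupby("element_id", sort=False):
        t = grp["time_ms"].to_numpy(dtype=float)
        if t.size > 1 and not (t[1:] > t[:-1]).all():
            first_bad = int(grp.index[1:][t[1:] <= t[:-1]][0]) + 2
            raise PixelCsvError(
                f"{path}: non-monotone time in element {eid!r} at line {first_bad}"
            )
        traces.append(
            PixelTrace(
                times_ms=t,
                freqs_khz=grp["freq_khz"].to_numpy(dtype=float),
                amps=grp["amp_db"].to_numpy(dtype=float),
                element_id=str(eid),
                channel=channel,
            )
        )
    return traces


def write_pixel_csv(traces, path) -> None:
    """Write traces in the pixel CSV dialect; round-trips through
    :func:`read_pixel_csv` up to float formatting."""
    rows = []
    for tr in traces:
        for t, f, a in zip(tr.times_ms, tr.freqs_khz, tr.amps):
            rows.append((tr.element_id, t, f, a))
    df = pd.DataFrame(rows, columns=PIXEL_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def write_manifest(df: pd.DataFrame, path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"element_id": str, "song_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    return df
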