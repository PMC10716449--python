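"""Reading and writing of traces, movies and FRAP curves.

Traces travel as long-format CSV with columns ``frame, time_s, channel,
counts`` (channels: ``donor``, ``acceptor``, ``alex``, or a single
``orange`` channel for binding traces).  Movies are multi-frame TIFF
files, one per excitation channel, with a JSON sidecar holding the
per-frame channel tags and metadata.  FRAP curves are CSV with columns
``curve_id, t, bleach_roi, reference_roi``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from smtrace.frap import FrapCurve
from smtrace.fretkit import FretTrace
from smtrace.imaging import ImageStack

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_fret_trace_csv",
    "read_fret_trace_csv",
    "write_stack",
    "read_stack",
    "write_frap_csv",
    "read_frap_csv",
]


def write_trace_csv(path, time_s, counts_by_channel: dict) -> None:
    """Long-format trace CSV; ``counts_by_channel`` maps tag -> array."""
    rows = []
    for channel, counts in counts_by_channel.items():
        counts = np.asarray(counts)
        t = np.asarray(time_s[channel]) if isinstance(time_s, dict) else np.asarray(time_s)
        for i, (ti, c) in enumerate(zip(t, counts)):
            rows.append({"frame": i, "time_s": ti, "channel": channel, "counts": c})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "time_s", "channel", "counts"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace CSV must have columns {sorted(required)}")
    return df


def write_fret_trace_csv(path, trace: FretTrace) -> None:
    channels = {"donor": trace.F_D, "acceptor": trace.F_A}
    times = {"donor": trace.time_s, "acceptor": trace.time_s}
    if trace.alex_A is not None:
        channels["alex"] = trace.alex_A
        times["alex"] = trace.alex_times
    write_trace_csv(path, times, channels)


def read_fret_trace_csv(path, beta: float = 0.071, gamma: float = 0.463) -> FretTrace:
    df = read_trace_csv(path)

    def chan(tag):
        sub = df[df.channel == tag].sort_values("frame")
        return sub.time_s.to_numpy(), sub.counts.to_numpy()

    t_d, fd = chan("donor")
    _, fa = chan("acceptor")
    alex_t, alex = chan("alex")
    return FretTrace(
        time_s=t_d, F_D=fd, F_A=fa,
        alex_A=alex if alex.size else None,
        alex_times=alex_t if alex_t.size else None,
        beta=beta, gamma=gamma,
    )


def write_stack(path, stack: ImageStack) -> None:
    """Multi-frame TIFF plus a JSON sidecar with channel tags."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "channels": list(stack.channels) if stack.channels is not None else None,
        "pixel_size_nm": stack.pixel_size_nm,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_stack(path) -> ImageStack:
    path = Path(path)
    frames = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    channels = pixel = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        channels = meta.get("channels")
        pixel = meta.get("pixel_size_nm")
    return ImageStack(frames=frames, channels=channels, pixel_size_nm=pixel)


def write_frap_csv(path, curves: list) -> None:
    rows = []
    for i, c in enumerate(curves):
        ref = c.reference_roi if c.reference_roi is not None else np.full_like(c.t, np.nan)
        for t, b, r in zip(c.t, c.bleach_roi, ref):
            rows.append({"curve_id": i, "t": t, "bleach_roi": b, "reference_roi": r})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_frap_csv(path) -> list:
    df = pd.read_csv(path)
    curves = []
    for _, sub in df.groupby("curve_id"):
        sub = sub.sort_values("t")
        ref = sub.reference_roi.to_numpy()
        curves.append(FrapCurve(
            t=sub.t.to_numpy(),
            bleach_roi=sub.bleach_roi.to_numpy(),
            reference_roi=None if np.all(np.isnan(ref)) else ref,
        ))
    return curves
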