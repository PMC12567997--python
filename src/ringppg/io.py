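"""Signal CSV reading, report writing and table export.

The interchange format for PPG signals is plain CSV with a header row: the
first column is either time in seconds or an integer sample index, every
further column is one channel (a 4-channel ring exports four).  Reports are
JSON; sweep tables and angle aggregates are CSV grids.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .records import PPGRecord
from .sweep import AngleAggregate, SweepTable

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "write_report",
    "sweep_to_frame",
    "write_sweep_csv",
    "read_sweep_csv",
    "aggregates_to_frame",
]


class SignalFormatError(ValueError):
    pass


def read_signal_csv(path: str | Path, fs: float | None = None) -> list[PPGRecord]:
    """One PPGRecord per channel column.

    The first column is time (s) — fs inferred from the median Δt — or an
    integer sample index (requires ``fs``).  If both an inferred rate and
    ``fs`` are available they must agree within 1%.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SignalFormatError("need a time/index column plus at least one channel")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.argmax((bad | df[col].isna()).to_numpy()))
            raise SignalFormatError(f"non-numeric cell in column '{col}', row {row}")
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(axis)
    if len(dt) == 0 or np.any(dt <= 0):
        raise SignalFormatError("first column must be strictly increasing")

    is_index = np.allclose(axis, np.round(axis)) and np.allclose(dt, 1.0)
    if is_index:
        if fs is None:
            raise SignalFormatError(
                "first column is a sample index; a sampling rate is required"
            )
        rate = float(fs)
    else:
        inferred = 1.0 / float(np.median(dt))
        if fs is not None and abs(inferred - fs) / fs > 0.01:
            raise SignalFormatError(
                f"inferred rate {inferred:.3f} Hz disagrees with the stated "
                f"{fs} Hz by more than 1%"
            )
        rate = float(fs) if fs is not None else inferred

    return [
        PPGRecord(samples=df[col].to_numpy(dtype=float), fs=rate, channel_label=str(col))
        for col in df.columns[1:]
    ]


def write_signal_csv(path: str | Path, records: list[PPGRecord]) -> None:
    """Write channels side by side with a time column in seconds."""
    n = len(records[0].samples)
    if any(len(r.samples) != n for r in records):
        raise ValueError("all channels must share one length")
    data = {"time": records[0].times}
    for r in records:
        data[r.channel_label] = r.samples
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    return obj


def write_report(result, path: str | Path, config: dict | None = None) -> None:
    """JSON report with a config echo for provenance."""
    from . import __version__

    payload = {
        "version": __version__,
        "config": _jsonable(config or {}),
        "result": _jsonable(result),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def sweep_to_frame(table: SweepTable) -> pd.DataFrame:
    """Grid as a DataFrame: rows = LED angle, columns = PD angle."""
    return pd.DataFrame(
        table.fractions,
        index=pd.Index(table.angles, name="led_angle"),
        columns=pd.Index(table.angles, name="pd_angle"),
    )


def write_sweep_csv(table: SweepTable, path: str | Path) -> None:
    sweep_to_frame(table).to_csv(path, float_format="%.10g")


def read_sweep_csv(path: str | Path, wavelength: int = 0) -> SweepTable:
    """Round-trip reader for a sweep grid CSV (counts are not persisted)."""
    df = pd.read_csv(path, index_col=0)
    angles = df.index.to_numpy(dtype=float)
    step = float(angles[1] - angles[0]) if len(angles) > 1 else 360.0
    return SweepTable(
        wavelength=wavelength,
        grid_step=step,
        angles=angles,
        fractions=df.to_numpy(dtype=float),
        detected_counts=np.zeros_like(df.to_numpy(), dtype=np.int64),
        n_photons=0,
        seed=0,
    )


def aggregates_to_frame(aggregates: list[AngleAggregate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "delta": [a.delta for a in aggregates],
            "mean_fraction": [a.mean_fraction for a in aggregates],
            "dispersion": [a.dispersion for a in aggregates],
            "n_valid": [a.n_valid for a in aggregates],
        }
    )


def plot_sweep_heatmap(table: SweepTable, path: str | Path) -> None:
    """Optional heatmap export (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(table.fractions, origin="lower", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(table.angles)), [f"{a:.0f}" for a in table.angles])
    ax.set_yticks(range(len(table.angles)), [f"{a:.0f}" for a in table.angles])
    ax.set_xlabel("PD angle (deg)")
    ax.set_ylabel("LED angle (deg)")
    ax.set_title(f"Microcirculation traversal fraction, {table.wavelength} nm")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
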