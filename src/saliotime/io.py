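"""File formats: trial tables (CSV), time series (HDF5 with CSV fallback),
event tables (CSV)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .core import EventRecord, LayerTimeSeries

TRIAL_CSV_COLUMNS = ["participant", "block", "trial", "scene", "duration_s", "report_s"]


def save_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TRIAL_CSV_COLUMNS if c in trials.columns]
    trials[cols].to_csv(path, index=False)


def load_trial_table(path: str | Path, tr_seconds: float = 0.8) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_CSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df.attrs["tr_seconds"] = tr_seconds
    return df


def _group_path(s: LayerTimeSeries) -> str:
    return f"/p{s.participant:03d}/t{s.trial:04d}/{s.hierarchy}/layer{s.layer}"


def save_timeseries_h5(series: Iterable[LayerTimeSeries], path: str | Path) -> None:
    """Layout: /p<participant>/t<trial>/<hierarchy>/layer<l> -> 2-D array
    with attrs (tr_seconds, scene, duration_s)."""
    with h5py.File(path, "w") as f:
        for s in series:
            d = f.create_dataset(_group_path(s), data=s.values)
            d.attrs["tr_seconds"] = s.tr_seconds
            d.attrs["scene"] = s.scene
            d.attrs["duration_s"] = s.duration_s


def load_timeseries_h5(path: str | Path) -> list[LayerTimeSeries]:
    out: list[LayerTimeSeries] = []
    with h5py.File(path, "r") as f:
        for pk in sorted(f):
            for tk in sorted(f[pk]):
                for hk in sorted(f[pk][tk]):
                    for lk in sorted(f[pk][tk][hk]):
                        d = f[pk][tk][hk][lk]
                        out.append(
                            LayerTimeSeries(
                                values=d[()],
                                tr_seconds=float(d.attrs["tr_seconds"]),
                                hierarchy=hk,
                                layer=int(lk.removeprefix("layer")),
                                participant=int(pk.removeprefix("p")),
                                trial=int(tk.removeprefix("t")),
                                scene=str(d.attrs["scene"]),
                                duration_s=float(d.attrs["duration_s"]),
                            )
                        )
    return out


def save_timeseries_csv(series: Iterable[LayerTimeSeries], directory: str | Path) -> None:
    """CSV-per-trial fallback: one file per (participant, trial, hierarchy,
    layer), metadata in '#'-prefixed header lines."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in series:
        name = f"p{s.participant:03d}_t{s.trial:04d}_{s.hierarchy}_layer{s.layer}.csv"
        with open(directory / name, "w") as fh:
            fh.write(f"# tr_seconds={s.tr_seconds}\n")
            fh.write(f"# scene={s.scene}\n")
            fh.write(f"# duration_s={s.duration_s}\n")
            np.savetxt(fh, s.values, delimiter=",")


def load_timeseries_csv(directory: str | Path) -> list[LayerTimeSeries]:
    out: list[LayerTimeSeries] = []
    for path in sorted(Path(directory).glob("p*_t*_*_layer*.csv")):
        stem = path.stem.split("_")
        participant = int(stem[0][1:])
        trial = int(stem[1][1:])
        hierarchy = "_".join(stem[2:-1])
        layer = int(stem[-1].removeprefix("layer"))
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                k, v = line[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
        values = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        out.append(
            LayerTimeSeries(
                values=values,
                tr_seconds=float(meta["tr_seconds"]),
                hierarchy=hierarchy,
                layer=layer,
                participant=participant,
                trial=trial,
                scene=meta.get("scene", ""),
                duration_s=float(meta["duration_s"]),
            )
        )
    return out


def event_records_table(records: Sequence[EventRecord]) -> pd.DataFrame:
    """Flat per-cell table: participant,trial,layer,n_events,n_excluded,
    n_valid_trs."""
    return pd.DataFrame(
        [
            {
                "participant": r.participant,
                "trial": r.trial,
                "hierarchy": r.hierarchy,
                "layer": r.layer,
                "n_events": r.count,
                "n_excluded": int(r.excluded.sum()),
                "n_valid_trs": int(np.isfinite(r.threshold).sum() + r.excluded.sum()),
            }
            for r in records
        ]
    )
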