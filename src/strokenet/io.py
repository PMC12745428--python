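"""Plain-text I/O: recordings, event side-cars, matrices and tables.

Recordings are stored as CSV matrices — a ``# fs=<Hz>`` comment line, a
header row of channel labels, then one row per channel (channels x
samples) — with cue events in a side-car CSV of (sample_index, task).
Connectivity matrices are labelled square CSVs; every tabular artifact
goes through pandas.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .preprocessing import Recording


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# fs={rec.fs}\n")
        fh.write(",".join(rec.labels) + "\n")
        writer = csv.writer(fh)
        for row in rec.data:
            writer.writerow([repr(float(v)) for v in row])


def write_events_csv(rec: Recording, path: str | Path) -> None:
    pd.DataFrame(rec.events, columns=["sample_index", "task"]).to_csv(path, index=False)


def read_recording_csv(path: str | Path, events_path: str | Path | None = None) -> Recording:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(first.split("=", 1)[1])
        labels = tuple(fh.readline().strip().split(","))
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    events: tuple[tuple[int, str], ...] = ()
    if events_path is not None:
        ev = pd.read_csv(events_path)
        events = tuple((int(r.sample_index), str(r.task)) for r in ev.itertuples())
    return Recording(data=data, fs=fs, labels=labels, events=events)


def write_connectivity_csv(m: ConnectivityMatrix, path: str | Path) -> None:
    pd.DataFrame(m.values, index=m.node_labels, columns=m.node_labels).to_csv(path)


def read_connectivity_csv(path: str | Path, band: str) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(
        band=band, values=df.to_numpy(float), node_labels=tuple(df.columns)
    )


def write_manifest_csv(subjects, path: str | Path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "affected_side": s.affected_side or "",
            "mas_upper": s.mas_upper or "",
            "mas_hand": s.mas_hand or "",
            "seed": s.seed,
        }
        for s in subjects
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"mas_upper": str, "mas_hand": str})
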