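"""Reading and writing of study artifacts.

Signals are stored as raw float32 binary (channels x samples, C order) with a
JSON sidecar carrying channel names, sampling rate and reference tag.
Electrode tables are BIDS-iEEG-style TSV files with columns
``name, x, y, z, hemisphere, subject``.  All tabular stage outputs are TSV so
a test harness in any language can read them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

ELECTRODE_COLUMNS = ["name", "x", "y", "z", "hemisphere", "subject"]


@dataclasses.dataclass
class Recording:
    """Multichannel voltage time series.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_ids : list of str
        One id per data row; ids match the electrode table ``name`` column.
    reference : str
        One of ``raw``, ``bipolar``, ``common_average``.
    sample_mask : ndarray of bool, shape (n_samples,)
        True where the sample is retained for analysis.
    electrodes : DataFrame, optional
        Electrode table restricted to (and aligned with) ``channel_ids``.
    subject : str, optional
    """

    data: np.ndarray
    fs: float
    channel_ids: list
    reference: str = "raw"
    sample_mask: np.ndarray | None = None
    electrodes: pd.DataFrame | None = None
    subject: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids must align with data rows")
        if self.sample_mask is None:
            self.sample_mask = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.sample_mask = np.asarray(self.sample_mask, dtype=bool)
            if self.sample_mask.shape != (self.data.shape[1],):
                raise ValueError("sample_mask must have one entry per sample")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            fs=self.fs,
            channel_ids=list(self.channel_ids),
            reference=self.reference,
            sample_mask=self.sample_mask.copy(),
            electrodes=None if self.electrodes is None else self.electrodes.copy(),
            subject=self.subject,
        )


def validate_electrode_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ELECTRODE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"electrode table missing columns: {missing}")
    coords = table[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("electrode coordinates must be finite")
    if table.groupby("subject")["name"].apply(lambda s: s.duplicated().any()).any():
        raise ValueError("electrode names must be unique within subject")
    bad = set(table["hemisphere"]) - {"left", "right"}
    if bad:
        raise ValueError(f"unknown hemisphere labels: {bad}")
    return table


def write_electrode_table(table: pd.DataFrame, path) -> None:
    validate_electrode_table(table)
    table.loc[:, ELECTRODE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_electrode_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"name": str, "subject": str})
    return validate_electrode_table(table)


def write_recording(rec: Recording, stem) -> None:
    """Write ``<stem>.bin`` (float32) and ``<stem>.json`` sidecar."""
    stem = Path(stem)
    rec.data.astype(np.float32).tofile(stem.with_suffix(".bin"))
    sidecar = {
        "channels": list(map(str, rec.channel_ids)),
        "fs": rec.fs,
        "n_samples": int(rec.n_samples),
        "reference": rec.reference,
        "subject": rec.subject,
        "units": "uV",
        "dtype": "float32",
        "order": "C",
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(stem, electrodes: pd.DataFrame | None = None) -> Recording:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".bin"), dtype=np.float32)
    n_ch = len(sidecar["channels"])
    data = data.reshape(n_ch, sidecar["n_samples"]).astype(float)
    sub = sidecar.get("subject")
    elec = None
    if electrodes is not None:
        elec = electrodes[electrodes["subject"] == sub] if sub is not None else electrodes
        elec = elec.set_index("name").loc[sidecar["channels"]].reset_index()
    return Recording(
        data=data,
        fs=float(sidecar["fs"]),
        channel_ids=list(sidecar["channels"]),
        reference=sidecar.get("reference", "raw"),
        electrodes=elec,
        subject=sub,
    )


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
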