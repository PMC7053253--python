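"""In-memory and on-disk containers shared by the synthesis and extraction
stages.

The on-disk container is a single HDF5 file with two members:
``/rf`` — float32 array of shape (frames, lines, samples) — and ``/meta`` —
a JSON document (stored as a UTF-8 string) holding the full acquisition
metadata.  The JSON round-trips bit-exactly, so provenance survives the
write/read cycle.  Measurement tables travel as plain CSV with the columns
``f0_MHz, output_pct, p_neg_kPa, pressure_mmHg, replicate, sha_dB``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "RFDataset",
    "ROI",
    "SubharmonicMeasurement",
    "save_rf",
    "load_rf",
    "measurements_to_frame",
    "write_measurements",
    "read_measurements",
]

META_SCHEMA_VERSION = 1

MEASUREMENT_COLUMNS = [
    "f0_MHz", "output_pct", "p_neg_kPa", "pressure_mmHg", "replicate",
    "sha_dB", "n_frames", "n_lines",
]


@dataclass
class RFDataset:
    """Frames x lines x samples of RF echoes plus acquisition metadata.

    ``meta`` is a flat JSON-serialisable dict; the keys the pipeline relies
    on are ``fs``, ``f0``, ``c``, ``pressure_mmHg``, ``p_neg_kPa``,
    ``output_pct``, ``replicate``, ``polarity`` (list of +/-1 per line) and
    ``pi_combined``.
    """

    rf: np.ndarray
    meta: dict

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf)
        if self.rf.ndim != 3:
            raise ValueError("rf must be 3-D: (frames, lines, samples)")
        if not np.all(np.isfinite(self.rf)):
            raise ValueError("rf contains non-finite values")
        n_frames, n_lines, n_samples = self.rf.shape
        for key, val in (("n_frames", n_frames), ("n_lines", n_lines),
                         ("n_samples", n_samples)):
            if key in self.meta and int(self.meta[key]) != val:
                raise ValueError(
                    f"meta[{key!r}]={self.meta[key]} does not match rf shape "
                    f"{self.rf.shape}")

    @property
    def n_frames(self) -> int:
        return self.rf.shape[0]

    @property
    def n_lines(self) -> int:
        return self.rf.shape[1]

    @property
    def n_samples(self) -> int:
        return self.rf.shape[2]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest in beam coordinates.

    Depth is along the beam (converted to sample indices through the
    round-trip travel time); the lateral extent selects lines.  The
    phased-array sector ROI is approximated by the same rectangle in beam
    coordinates.
    """

    depth_start_mm: float = 10.0
    depth_end_mm: float = 13.0
    lateral_start_mm: float = 0.0
    lateral_end_mm: float = 15.5

    def __post_init__(self) -> None:
        if not self.depth_end_mm > self.depth_start_mm:
            raise ValueError("depth_end_mm must exceed depth_start_mm")
        if not self.lateral_end_mm > self.lateral_start_mm:
            raise ValueError("lateral_end_mm must exceed lateral_start_mm")

    def sample_slice(self, fs: float, c: float, n_samples: int) -> slice:
        """Sample-index window for the depth band (round-trip time)."""
        s0 = int(round(2 * self.depth_start_mm * 1e-3 / c * fs))
        s1 = int(round(2 * self.depth_end_mm * 1e-3 / c * fs))
        if s0 >= n_samples:
            raise ValueError(
                f"ROI starts at sample {s0}, beyond the {n_samples}-sample line")
        return slice(s0, min(s1, n_samples))


@dataclass(frozen=True)
class SubharmonicMeasurement:
    """One extracted subharmonic amplitude with its acquisition provenance."""

    f0_MHz: float
    output_pct: float
    p_neg_kPa: float
    pressure_mmHg: float
    replicate: int
    sha_dB: float
    n_frames: int
    n_lines: int


def save_rf(dataset: RFDataset, path: str | Path) -> None:
    """Write a dataset to the HDF5 container (/rf float32, /meta JSON)."""
    meta = dict(dataset.meta)
    meta.setdefault("schema_version", META_SCHEMA_VERSION)
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=dataset.rf.astype(np.float32))
        f.create_dataset("meta", data=json.dumps(meta, sort_keys=True))


def load_rf(path: str | Path) -> RFDataset:
    """Read a dataset from the HDF5 container."""
    with h5py.File(path, "r") as f:
        rf = f["rf"][...].astype(np.float64)
        meta = json.loads(f["meta"][()].decode("utf-8"))
    return RFDataset(rf=rf, meta=meta)


def measurements_to_frame(measurements) -> pd.DataFrame:
    """Stack SubharmonicMeasurement records into a tidy DataFrame."""
    return pd.DataFrame([asdict(m) for m in measurements],
                        columns=MEASUREMENT_COLUMNS)


def write_measurements(measurements, path: str | Path) -> None:
    df = (measurements if isinstance(measurements, pd.DataFrame)
          else measurements_to_frame(measurements))
    df.to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    return df
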