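"""The universal I/O unit: a bundle of time-aligned current sweeps.

On disk a bundle is ``<name>.csv`` (column 1 ``time_s``, columns 2…N
``sweep_<level_mV>`` in pA) plus a ``<name>.meta.json`` sidecar carrying the
stimulus protocol, acquisition metadata, and — for synthetic bundles — the
ground-truth event times and preset provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .protocols import StimProtocol

__all__ = ["SweepBundle", "GroundTruth", "write_bundle", "read_bundle"]

#: series resistance above which a recording is flagged for exclusion
SERIES_RESISTANCE_QC_MOHM = 35.0


@dataclass
class GroundTruth:
    """Generative truth stored with synthetic bundles.

    ``event_times_s`` holds one array of IPSC onset times per sweep;
    ``event_conductances_nS`` the matching sampled peak conductances.
    """

    event_times_s: list[np.ndarray] = field(default_factory=list)
    event_conductances_nS: list[np.ndarray] = field(default_factory=list)
    preset_name: Optional[str] = None
    preset: Optional[dict] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "event_times_s": [np.asarray(t).tolist() for t in self.event_times_s],
            "event_conductances_nS": [np.asarray(a).tolist() for a in self.event_conductances_nS],
            "preset_name": self.preset_name,
            "preset": self.preset,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            event_times_s=[np.asarray(t, dtype=float) for t in d.get("event_times_s", [])],
            event_conductances_nS=[np.asarray(a, dtype=float) for a in d.get("event_conductances_nS", [])],
            preset_name=d.get("preset_name"),
            preset=d.get("preset"),
            seed=d.get("seed"),
        )


@dataclass
class SweepBundle:
    """Time-aligned voltage-clamp current sweeps plus protocol and metadata.

    Attributes
    ----------
    time_s : (n_samples,) array
        Shared uniform time base, seconds.
    sweeps_pA : (n_sweeps, n_samples) array
        Recorded (or simulated) membrane currents.
    protocol : StimProtocol
    metadata : dict
        At minimum ``sampling_rate_Hz``; typically also filter settings and
        ``series_resistance_MOhm``.
    ground_truth : GroundTruth, optional
    """

    time_s: np.ndarray
    sweeps_pA: np.ndarray
    protocol: StimProtocol
    metadata: dict = field(default_factory=dict)
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.sweeps_pA = np.atleast_2d(np.asarray(self.sweeps_pA, dtype=float))
        if self.sweeps_pA.shape[1] != self.time_s.shape[0]:
            raise ValueError("sweeps and time base have mismatched lengths")
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time base must be uniformly sampled")

    @property
    def sampling_rate(self) -> float:
        sr = self.metadata.get("sampling_rate_Hz")
        if sr is not None:
            return float(sr)
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    @property
    def n_sweeps(self) -> int:
        return self.sweeps_pA.shape[0]

    @property
    def qc_excluded(self) -> bool:
        """True when series resistance exceeds the 35 MΩ inclusion bound."""
        rs = self.metadata.get("series_resistance_MOhm")
        return rs is not None and float(rs) > SERIES_RESISTANCE_QC_MOHM

    def membrane_potentials(self) -> np.ndarray:
        """Effective membrane potential per sweep sample (mV)."""
        return self.protocol.membrane_waveforms(self.sampling_rate)

    def sweep_labels(self) -> list[str]:
        if self.protocol.step_levels:
            return [f"sweep_{lev:g}" for lev in self.protocol.step_levels]
        return [f"sweep_{i}" for i in range(self.n_sweeps)]


def write_bundle(bundle: SweepBundle, directory: str | Path, name: str) -> tuple[Path, Path]:
    """Write ``<name>.csv`` + ``<name>.meta.json``; returns both paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{name}.csv"
    meta_path = directory / f"{name}.meta.json"

    df = pd.DataFrame({"time_s": bundle.time_s})
    for lbl, sweep in zip(bundle.sweep_labels(), bundle.sweeps_pA):
        df[lbl] = sweep
    df.to_csv(csv_path, index=False, float_format="%.8g")

    meta = {
        "protocol": bundle.protocol.to_dict(),
        "metadata": bundle.metadata,
        "ground_truth": bundle.ground_truth.to_dict() if bundle.ground_truth else None,
    }
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path, meta_path


def read_bundle(directory: str | Path, name: str) -> SweepBundle:
    """Round-trip reader for :func:`write_bundle` output."""
    directory = Path(directory)
    df = pd.read_csv(directory / f"{name}.csv")
    meta = json.loads((directory / f"{name}.meta.json").read_text())
    gt = meta.get("ground_truth")
    return SweepBundle(
        time_s=df["time_s"].to_numpy(),
        sweeps_pA=df.drop(columns="time_s").to_numpy().T,
        protocol=StimProtocol.from_dict(meta["protocol"]),
        metadata=meta.get("metadata", {}),
        ground_truth=GroundTruth.from_dict(gt) if gt else None,
    )
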