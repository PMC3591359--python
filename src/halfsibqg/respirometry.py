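"""Flow-through respirometry: baseline drift correction and rate conversion.

A multiplexed record cycles seven fly chambers past a single CO₂ analyzer,
with an empty chamber read at the beginning, middle and end of the record.
Analyzer drift over the record is taken as linear: a least-squares line
through the baseline (time, ppm) points defines the zero, is subtracted
from every sample, and the mean corrected ppm over each fly's measurement
window is converted to µL CO₂ h⁻¹ at the known flow rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: ppm (µL CO₂ per L air) × flow (mL min⁻¹) × 60 min h⁻¹ × 10⁻³ L mL⁻¹ → µL h⁻¹
PPM_TO_RATE = 1e-6 * 60 * 1000


class RespirometryError(ValueError):
    pass


@dataclass
class RespirometryRecord:
    """One multiplexed respirometry record.

    ``times`` are minutes from record start, ``chambers`` the chamber label
    per sample, ``ppm`` the analyzer reading.  ``fly_assignment`` maps fly
    id -> chamber label; ``baseline_chamber`` names the empty chamber.
    """

    times: np.ndarray
    chambers: np.ndarray
    ppm: np.ndarray
    baseline_chamber: str = "B"
    flow_rate: float = 50.0          # mL min⁻¹
    fly_assignment: dict[str, str] = field(default_factory=dict)
    duration_per_fly: float = 10.0   # minutes
    record_hour: str = ""
    corrected: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.chambers = np.asarray(self.chambers, dtype=object)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.flow_rate <= 0:
            raise RespirometryError("flow_rate must be positive")
        if np.any(np.diff(self.times) < 0):
            raise RespirometryError("sample times must be non-decreasing")

    def baseline_points(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.chambers == self.baseline_chamber
        return self.times[m], self.ppm[m]


def baseline_correct(rec: RespirometryRecord) -> RespirometryRecord:
    """Subtract the least-squares linear baseline from every chamber.

    Requires at least two baseline points at distinct times (three are
    expected: begin, middle, end of the record).
    """
    t, y = rec.baseline_points()
    if len(t) < 2:
        raise RespirometryError(
            f"need >=2 baseline points, got {len(t)} in chamber {rec.baseline_chamber!r}"
        )
    if np.ptp(t) == 0:
        raise RespirometryError("baseline points all at identical times")
    slope, intercept = np.polyfit(t, y, 1)
    corrected = rec.ppm - (intercept + slope * rec.times)
    return replace(rec, ppm=corrected, corrected=True)


def ppm_to_rate(mean_ppm: float, flow_rate: float = 50.0) -> float:
    """Convert a (baseline-corrected) CO₂ excess in ppm to µL CO₂ h⁻¹.

    rate = ppm × 10⁻⁶ × flow[mL min⁻¹] × 60 × 1000; e.g. 10 ppm at
    50 mL min⁻¹ is 30 µL h⁻¹.
    """
    if flow_rate <= 0:
        raise RespirometryError("flow_rate must be positive")
    return float(mean_ppm) * flow_rate * PPM_TO_RATE


def extract_rmr(rec: RespirometryRecord) -> pd.DataFrame:
    """Per-fly routine metabolic rate from a baseline-corrected record.

    Returns a DataFrame (fly id, rmr, chamber, hour); a fly whose chamber
    has no samples yields NaN with a warning.
    """
    if not rec.corrected:
        raise RespirometryError("record must be baseline-corrected first")
    rows = []
    for fly, chamber in rec.fly_assignment.items():
        m = rec.chambers == chamber
        if not m.any():
            warnings.warn(f"no samples for fly {fly!r} in chamber {chamber!r}")
            rmr = np.nan
        else:
            rmr = ppm_to_rate(float(rec.ppm[m].mean()), rec.flow_rate)
        rows.append((fly, rmr, chamber, rec.record_hour))
    return pd.DataFrame(rows, columns=["id", "rmr", "chamber", "hour"])


def process_records(records) -> pd.DataFrame:
    """Baseline-correct and extract RMR for a sequence of records."""
    out = [extract_rmr(baseline_correct(r)) for r in records]
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["id", "rmr", "chamber", "hour"]
    )
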