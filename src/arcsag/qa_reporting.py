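"""Summary statistics and TG-142 style tolerance verdicts for arc metrics.

Implements the statistics used to condense per-angle deformation curves
into machine-level numbers: range (max − min) with the angles of the
extrema, between-replicate reproducibility (per-angle sample SD, summarised
by its maximum), root-mean-square deviation between paired conditions
(clockwise vs counter-clockwise rotation, collimator 0 vs 90), pass/fail
verdicts against configurable mechanical tolerances, and the first-order
dosimetric impact of an SDD change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoverageError, InputError
from .geometry_metrics import METRIC_COLUMNS, ArcMetrics


@dataclass
class ToleranceConfig:
    """Mechanical tolerances (non-stereotactic photon linac defaults)."""

    epid_sag_mm: float = 2.0
    gantry_sag_mm: float = 1.0
    sdd_change_mm: float = 5.0
    mlc_position_mm: float = 1.0
    mlc_systematic_note_mm: float = 0.3  # informational: systematic leaf limit

    def __post_init__(self):
        for name in ("epid_sag_mm", "gantry_sag_mm", "sdd_change_mm", "mlc_position_mm"):
            if getattr(self, name) <= 0:
                raise InputError(f"tolerance {name} must be positive")


@dataclass
class SummaryReport:
    """Per-metric summary statistics plus tolerance verdicts."""

    ranges: pd.DataFrame
    verdicts: pd.DataFrame | None = None
    reproducibility: pd.DataFrame | None = None
    rmsd: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str | Path:
        import json

        payload = {"ranges": self.ranges.to_dict(orient="index"), "meta": self.meta}
        if self.verdicts is not None:
            payload["verdicts"] = self.verdicts.to_dict(orient="index")
        if self.reproducibility is not None:
            payload["reproducibility"] = self.reproducibility.to_dict(orient="index")
        if self.rmsd is not None:
            payload["rmsd"] = self.rmsd.to_dict(orient="index")
        text = json.dumps(payload, indent=2, sort_keys=True, default=float)
        if path is None:
            return text
        path = Path(path)
        path.write_text(text + "\n")
        return path


def range_summary(metrics: ArcMetrics) -> pd.DataFrame:
    """Range (max − min), extrema, their angles, mean and max |value|."""
    rows = {}
    for name in METRIC_COLUMNS:
        series = metrics.series(name)
        if series.size == 0:
            raise InputError("empty metric series")
        imax = int(np.argmax(series))
        imin = int(np.argmin(series))
        rows[name] = {
            "range": float(series[imax] - series[imin]),
            "min": float(series[imin]),
            "max": float(series[imax]),
            "argmin_angle_deg": float(metrics.angles_deg[imin]),
            "argmax_angle_deg": float(metrics.angles_deg[imax]),
            "mean": float(series.mean()),
            "max_abs": float(np.abs(series).max()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _match_angles(reference: np.ndarray, other: np.ndarray, tol_deg: float = 2.0):
    """Indices into ``other`` matching each reference angle within tol."""
    idx = np.array([int(np.argmin(np.abs(other - a))) for a in reference])
    if np.any(np.abs(other[idx] - reference) > tol_deg):
        raise InputError("replicate angle grids differ by more than the 2 deg tolerance")
    return idx


def reproducibility(replicates: list[ArcMetrics]) -> pd.DataFrame:
    """Between-replicate sample SD per angle; summary = max over angles.

    Replicates must follow the same acquisition plan; angles are matched by
    nearest neighbour within 2 degrees.
    """
    if len(replicates) < 2:
        raise InputError(f"need at least 2 replicates, got {len(replicates)}")
    ref_angles = replicates[0].angles_deg
    rows = {}
    for name in METRIC_COLUMNS:
        stack = [replicates[0].series(name)]
        for rep in replicates[1:]:
            idx = _match_angles(ref_angles, rep.angles_deg)
            stack.append(rep.series(name)[idx])
        sd = np.std(np.vstack(stack), axis=0, ddof=1)
        rows[name] = {
            "max_sd": float(sd.max()),
            "mean_sd": float(sd.mean()),
            "argmax_angle_deg": float(ref_angles[int(np.argmax(sd))]),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def rmsd_compare(series1: ArcMetrics, series2: ArcMetrics) -> pd.DataFrame:
    """Root-mean-square deviation between two arcs, per metric.

    Both series are linearly interpolated onto the union of their angle
    grids restricted to the overlapping angular range (so a clockwise and a
    reversed counter-clockwise acquisition pair up even when their sampling
    grids differ).  Requires at least 270 degrees of common coverage.
    """
    a1 = np.sort(series1.angles_deg)
    a2 = np.sort(series2.angles_deg)
    lo, hi = max(a1.min(), a2.min()), min(a1.max(), a2.max())
    if hi - lo < 270.0:
        raise CoverageError(f"common angular coverage {hi - lo:.0f} deg < 270 deg")
    grid = np.union1d(series1.angles_deg, series2.angles_deg)
    grid = grid[(grid >= lo) & (grid <= hi)]

    rows = {}
    for name in METRIC_COLUMNS:
        o1 = np.argsort(series1.angles_deg)
        o2 = np.argsort(series2.angles_deg)
        v1 = np.interp(grid, series1.angles_deg[o1], series1.series(name)[o1])
        v2 = np.interp(grid, series2.angles_deg[o2], series2.series(name)[o2])
        rows[name] = {"rmsd": float(np.sqrt(np.mean((v1 - v2) ** 2)))}
    return pd.DataFrame.from_dict(rows, orient="index")


#: metric -> (summary quantity, tolerance attribute)
_TOLERANCE_MAP = {
    "epid_sag_x_mm": ("max_abs", "epid_sag_mm"),
    "epid_sag_y_mm": ("max_abs", "epid_sag_mm"),
    "gantry_sag_x_mm": ("max_abs", "gantry_sag_mm"),
    "gantry_sag_y_mm": ("max_abs", "gantry_sag_mm"),
    "delta_sdd_mm": ("max_abs", "sdd_change_mm"),
    "mlc_sag_L_mm": ("range", "mlc_position_mm"),
    "mlc_sag_R_mm": ("range", "mlc_position_mm"),
    "mlc_sag_G_mm": ("range", "mlc_position_mm"),
    "mlc_sag_T_mm": ("range", "mlc_position_mm"),
}


def tolerance_check(
    summary: pd.DataFrame, config: ToleranceConfig | None = None
) -> pd.DataFrame:
    """Pass/fail verdicts with margins against the configured tolerances.

    Imager and gantry sag and the SDD change are judged on the maximum
    absolute excursion; carriage sag on the range per direction (a bulk
    carriage drift is a systematic leaf-position error).  Skew and tilt have
    no standard numeric tolerance and are reported without a verdict.
    """
    config = config or ToleranceConfig()
    rows = {}
    for metric, (quantity, attr) in _TOLERANCE_MAP.items():
        value = float(summary.loc[metric, quantity])
        tol = getattr(config, attr)
        rows[metric] = {
            "quantity": quantity,
            "value": value,
            "tolerance": tol,
            "margin": tol - abs(value),
            "pass": bool(abs(value) <= tol),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def magnification_impact(delta_sdd_mm: float, sdd0_mm: float) -> tuple[float, float]:
    """Image magnification (%) and first-order dose change (%) of an SDD shift.

    The projected size of any object scales with SDD, so the magnification
    is ΔSDD/SDD0; the fluence at the detector follows the inverse square
    law, so the dose change is twice that to first order (relevant when the
    imager is used for absolute dosimetry).
    """
    if sdd0_mm <= 0:
        raise InputError("sdd0_mm must be positive")
    magnification_pct = 100.0 * delta_sdd_mm / sdd0_mm
    return magnification_pct, 2.0 * magnification_pct


def plot_metrics(metrics: ArcMetrics, out_path) -> Path:
    """Write a per-metric overview figure (angle vs metric)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 3, figsize=(12, 10), sharex=True)
    order = np.argsort(metrics.angles_deg)
    for ax, name in zip(axes.ravel(), METRIC_COLUMNS):
        ax.plot(metrics.angles_deg[order], metrics.series(name)[order], ".-", ms=3)
        ax.set_title(name, fontsize=9)
        ax.axhline(0.0, color="0.8", lw=0.8)
    for ax in axes[-1]:
        ax.set_xlabel("gantry angle (deg)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
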