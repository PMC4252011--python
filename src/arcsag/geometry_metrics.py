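"""Per-angle mechanical deformation metrics from marker and edge positions.

Given the trajectory of the five ball-bearing shadows and of the four MLC
field edges over a gantry arc, this module computes, per gantry angle θ and
relative to the gantry-zero reference frame:

* ``epid_sag_x/y``  — displacement of the imager panel, from the isocentre
  ball (e), after removing the A·cosθ / B·sinθ signature that a lateral /
  vertical set-up offset of the ball imprints on its projected trajectory;
* ``gantry_sag_x/y`` — displacement of the gantry head: mean displacement of
  the four head balls minus the EPID sag;
* ``delta_sdd``     — change in source-to-detector distance, from the
  magnification of the x-separation of the (a,c) vs (b,d) marker pairs,
  reported at detector scale (not isocentre-scaled);
* ``skew``          — in-plane rotation (yaw) of imager/collimator, from the
  orientation of the (a,b) pair;
* ``tilt_x/y``      — out-of-plane rotation (roll/pitch) of the panel, from
  the differential apparent SDD of marker pairs on opposite sides;
* ``mlc_sag_L/R/G/T`` — bulk displacement of the MLC carriages, from the
  distance between the mean head-marker position and each bank edge.

Every series is re-anchored so that its value at the reference frame is
exactly zero, matching the convention that all machine calibrations are
defined at gantry zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoverageError, GeometryError, ReferenceFrameError
from .imaging_io import PlanePoint, angular_coverage_deg
from .marker_detection import (
    HEAD_MARKERS,
    FieldEdges,
    MarkerSet,
    Pairing,
    PhantomGeometry,
)

METRIC_COLUMNS = (
    "epid_sag_x_mm",
    "epid_sag_y_mm",
    "gantry_sag_x_mm",
    "gantry_sag_y_mm",
    "delta_sdd_mm",
    "skew_deg",
    "tilt_x_deg",
    "tilt_y_deg",
    "mlc_sag_L_mm",
    "mlc_sag_R_mm",
    "mlc_sag_G_mm",
    "mlc_sag_T_mm",
)

MIN_PAIR_SEPARATION_MM = 10.0


@dataclass
class MisalignmentFit:
    """Least-squares amplitudes of the periodic set-up misalignment terms.

    ``A_mm`` multiplies (cosθ − 1) in x (lateral offset of ball e or lasers),
    ``B_mm`` multiplies sinθ in y (vertical offset).  Both vanish for a
    perfectly positioned isocentre ball.
    """

    A_mm: float
    B_mm: float
    residual_rms_mm: float

    def __post_init__(self):
        if abs(self.A_mm) >= 10 or abs(self.B_mm) >= 10:
            raise GeometryError(
                f"implausible misalignment fit A={self.A_mm:.2f}, B={self.B_mm:.2f} mm"
            )


@dataclass
class ArcMetrics:
    """Angle-indexed series of every mechanical metric for one arc."""

    angles_deg: np.ndarray
    epid_sag_x_mm: np.ndarray
    epid_sag_y_mm: np.ndarray
    gantry_sag_x_mm: np.ndarray
    gantry_sag_y_mm: np.ndarray
    delta_sdd_mm: np.ndarray
    skew_deg: np.ndarray
    tilt_x_deg: np.ndarray
    tilt_y_deg: np.ndarray
    mlc_sag_L_mm: np.ndarray
    mlc_sag_R_mm: np.ndarray
    mlc_sag_G_mm: np.ndarray
    mlc_sag_T_mm: np.ndarray
    misalignment: MisalignmentFit | None = None
    reference_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.angles_deg)
        for name in METRIC_COLUMNS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != angles length {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)

    def series(self, name: str) -> np.ndarray:
        if name not in METRIC_COLUMNS:
            raise KeyError(name)
        return getattr(self, name)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"gantry_angle_deg": self.angles_deg}
        data.update({name: getattr(self, name) for name in METRIC_COLUMNS})
        return pd.DataFrame(data)

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ArcMetrics":
        angles = df["gantry_angle_deg"].to_numpy(dtype=float)
        ref = int(np.argmin(np.abs(angles)))
        return cls(
            angles_deg=angles,
            reference_index=ref,
            **{name: df[name].to_numpy(dtype=float) for name in METRIC_COLUMNS},
        )

    @classmethod
    def from_csv(cls, path) -> "ArcMetrics":
        return cls.from_dataframe(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------


def _as_xy(points: list[PlanePoint]) -> np.ndarray:
    return np.array([[p.x_mm, p.y_mm] for p in points])


def _marker_arrays(marker_sets: list[MarkerSet]) -> dict[str, np.ndarray]:
    """name -> (n, 2) array of isocentre-plane positions."""
    return {
        name: np.array([ms.xy(name) for ms in marker_sets])
        for name in ("a", "b", "c", "d", "e")
    }


def _pair_mean(m: dict, pair: tuple, axis: int) -> np.ndarray:
    return 0.5 * (m[pair[0]][:, axis] + m[pair[1]][:, axis])


def _pair_diff(m: dict, pair: tuple, axis: int) -> np.ndarray:
    return m[pair[0]][:, axis] - m[pair[1]][:, axis]


def _rezero(series: np.ndarray, ref_index: int) -> np.ndarray:
    return series - series[ref_index]


def reference_index(angles_deg: np.ndarray, tolerance_deg: float = 2.0) -> int:
    angles = np.asarray(angles_deg, dtype=float)
    ref = int(np.argmin(np.abs(angles)))
    if abs(angles[ref]) > tolerance_deg:
        raise ReferenceFrameError(
            f"no frame within {tolerance_deg} deg of gantry zero "
            f"(closest: {angles[ref]:.2f} deg)"
        )
    return ref


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def fit_misalignment(
    angles_deg: np.ndarray,
    e_positions: list[PlanePoint] | np.ndarray,
    ref_index: int | None = None,
) -> MisalignmentFit:
    """Fit the set-up misalignment amplitudes A (x) and B (y).

    A lateral offset of the isocentre ball projects onto the rotating panel
    as an A·cosθ term in x, a vertical offset as a B·sinθ term in y.  Both
    are estimated by ordinary least squares of the e-ball displacement from
    its reference position against the bases {cosθ − 1} (x) and {sinθ} (y);
    the bases vanish at gantry zero, so the fit never moves the reference.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 8:
        raise CoverageError(f"need at least 8 angles for the fit, got {angles.size}")
    if angular_coverage_deg(angles) < 270.0:
        raise CoverageError(
            f"angular span {angular_coverage_deg(angles):.0f} deg < 270 deg"
        )
    if ref_index is None:
        ref_index = reference_index(angles)
    e = e_positions if isinstance(e_positions, np.ndarray) else _as_xy(list(e_positions))

    theta = np.radians(angles)
    dx = e[:, 0] - e[ref_index, 0]
    dy = e[:, 1] - e[ref_index, 1]
    fx = np.cos(theta) - 1.0
    fy = np.sin(theta)
    A = float(fx @ dx / (fx @ fx))
    B = float(fy @ dy / (fy @ fy))
    resid = np.concatenate([dx - A * fx, dy - B * fy])
    return MisalignmentFit(A_mm=A, B_mm=B, residual_rms_mm=float(np.sqrt(np.mean(resid**2))))


def epid_sag(
    angles_deg: np.ndarray,
    e_positions: list[PlanePoint] | np.ndarray,
    fit: MisalignmentFit,
    ref_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """EPID sag in x and y: e-ball displacement minus the misalignment terms.

    Re-anchored so that the reference frame reads exactly zero.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if ref_index is None:
        ref_index = reference_index(angles)
    e = e_positions if isinstance(e_positions, np.ndarray) else _as_xy(list(e_positions))
    theta = np.radians(angles)
    sag_x = (e[:, 0] - fit.A_mm * (np.cos(theta) - 1.0)) - e[ref_index, 0]
    sag_y = (e[:, 1] - fit.B_mm * np.sin(theta)) - e[ref_index, 1]
    return _rezero(sag_x, ref_index), _rezero(sag_y, ref_index)


def gantry_sag(
    marker_sets: list[MarkerSet],
    epid_sag_xy: tuple[np.ndarray, np.ndarray],
    ref_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Gantry sag: mean head-ball displacement minus the EPID sag."""
    m = _marker_arrays(marker_sets)
    mean_x = np.mean([m[n][:, 0] for n in HEAD_MARKERS], axis=0)
    mean_y = np.mean([m[n][:, 1] for n in HEAD_MARKERS], axis=0)
    sag_x = _rezero(mean_x, ref_index) - epid_sag_xy[0]
    sag_y = _rezero(mean_y, ref_index) - epid_sag_xy[1]
    return sag_x, sag_y


def sdd_change(
    marker_sets: list[MarkerSet],
    sdd0_mm: float,
    ref_index: int,
    pairing: Pairing | None = None,
) -> np.ndarray:
    """Change in SDD from the magnification of opposite marker-pair means.

    Positive values mean the detector moved farther from the source; the
    result is a physical distance at the detector, not isocentre-scaled.
    """
    pairing = pairing or Pairing()
    m = _marker_arrays(marker_sets)
    left, right = pairing.sdd
    sep = _pair_mean(m, left, 0) - _pair_mean(m, right, 0)
    if abs(sep[ref_index]) < MIN_PAIR_SEPARATION_MM:
        raise GeometryError(
            f"reference pair separation {sep[ref_index]:.2f} mm too small for the "
            "SDD estimate"
        )
    return sdd0_mm * (sep / sep[ref_index] - 1.0)


def skewness(
    marker_sets: list[MarkerSet],
    ref_index: int,
    pair: tuple[str, str] = ("a", "b"),
) -> np.ndarray:
    """Imager/collimator yaw from the orientation of one head-marker pair.

    Clockwise rotations (viewed in the beam's-eye view) are positive.
    """
    m = _marker_arrays(marker_sets)
    dx = m[pair[1]][:, 0] - m[pair[0]][:, 0]
    dy = m[pair[1]][:, 1] - m[pair[0]][:, 1]
    if abs(dx[ref_index]) < MIN_PAIR_SEPARATION_MM:
        raise GeometryError(
            f"pair {pair} x-separation {dx[ref_index]:.2f} mm too small for skew"
        )
    psi = np.degrees(np.arctan(dy / dx))
    return _rezero(psi, ref_index)


def epid_tilt(
    marker_sets: list[MarkerSet],
    sdd0_mm: float,
    ref_index: int,
    pairing: Pairing | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Panel roll (about y: tilt_x) and pitch (about x: tilt_y) in degrees.

    Each marker pair yields an independent apparent-SDD estimate from the
    scaling of its separation; a tilted panel magnifies opposite sides
    differently, so the arctangent of the difference over the distance
    between the pair midpoints measures the tilt.  A common-mode SDD change
    cancels exactly.
    """
    pairing = pairing or Pairing()
    m = _marker_arrays(marker_sets)

    # pitch (tilt about the cross-plane axis): gun vs target x-separations
    gun, target = pairing.tilt_pitch
    sep_g = _pair_diff(m, gun, 0)
    sep_t = _pair_diff(m, target, 0)
    dy_mid = _pair_mean(m, gun, 1) - _pair_mean(m, target, 1)
    if min(abs(sep_g[ref_index]), abs(sep_t[ref_index]), abs(dy_mid[ref_index])) < MIN_PAIR_SEPARATION_MM:
        raise GeometryError("degenerate pair geometry for the pitch estimate")
    num = sdd0_mm * (sep_g / sep_g[ref_index] - 1.0) - sdd0_mm * (
        sep_t / sep_t[ref_index] - 1.0
    )
    tilt_y = np.degrees(np.arctan(num / dy_mid))

    # roll (tilt about the in-plane axis): left vs right y-separations
    left, right = pairing.tilt_roll
    sep_l = _pair_diff(m, left, 1)
    sep_r = _pair_diff(m, right, 1)
    dx_mid = _pair_mean(m, left, 0) - _pair_mean(m, right, 0)
    if min(abs(sep_l[ref_index]), abs(sep_r[ref_index]), abs(dx_mid[ref_index])) < MIN_PAIR_SEPARATION_MM:
        raise GeometryError("degenerate pair geometry for the roll estimate")
    num = sdd0_mm * (sep_l / sep_l[ref_index] - 1.0) - sdd0_mm * (
        sep_r / sep_r[ref_index] - 1.0
    )
    tilt_x = np.degrees(np.arctan(num / dx_mid))

    return _rezero(tilt_x, ref_index), _rezero(tilt_y, ref_index)


def mlc_carriage_sag(
    marker_sets: list[MarkerSet],
    field_edges: list[FieldEdges],
    ref_index: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Carriage sag per direction: head-marker mean minus bank edge.

    The raw marker-to-edge distances (~half the aperture) are re-referenced
    to the gantry-zero frame, so each series reports the gravity-driven
    drift of the carriage relative to the head.  A rigid common shift of
    markers and edges cancels exactly.
    """
    m = _marker_arrays(marker_sets)
    mean_x = np.mean([m[n][:, 0] for n in HEAD_MARKERS], axis=0)
    mean_y = np.mean([m[n][:, 1] for n in HEAD_MARKERS], axis=0)
    L = np.array([fe.L_edge_mm for fe in field_edges])
    R = np.array([fe.R_edge_mm for fe in field_edges])
    G = np.array([fe.G_edge_mm for fe in field_edges])
    T = np.array([fe.T_edge_mm for fe in field_edges])
    sag_L = mean_x - L
    sag_R = R - mean_x
    sag_G = mean_y - G
    sag_T = T - mean_y
    return tuple(_rezero(s, ref_index) for s in (sag_L, sag_R, sag_G, sag_T))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def compute_arc_metrics(
    angles_deg: np.ndarray,
    marker_sets: list[MarkerSet],
    field_edges: list[FieldEdges],
    sdd0_mm: float,
    geometry: PhantomGeometry | None = None,
    *,
    ref_index: int | None = None,
) -> ArcMetrics:
    """Compute every per-angle metric for one arc series."""
    angles = np.asarray(angles_deg, dtype=float)
    if not (len(angles) == len(marker_sets) == len(field_edges)):
        raise ValueError("angles, marker sets and field edges must align")
    pairing = geometry.pairing if geometry is not None else Pairing()
    if ref_index is None:
        ref_index = reference_index(angles)

    e_xy = np.array([ms.xy("e") for ms in marker_sets])
    fit = fit_misalignment(angles, e_xy, ref_index)
    sag = epid_sag(angles, e_xy, fit, ref_index)
    gsag = gantry_sag(marker_sets, sag, ref_index)
    dsdd = sdd_change(marker_sets, sdd0_mm, ref_index, pairing)
    psi = skewness(marker_sets, ref_index, pairing.skew[0])
    tilt_x, tilt_y = epid_tilt(marker_sets, sdd0_mm, ref_index, pairing)
    sag_L, sag_R, sag_G, sag_T = mlc_carriage_sag(marker_sets, field_edges, ref_index)

    return ArcMetrics(
        angles_deg=angles,
        epid_sag_x_mm=sag[0],
        epid_sag_y_mm=sag[1],
        gantry_sag_x_mm=gsag[0],
        gantry_sag_y_mm=gsag[1],
        delta_sdd_mm=dsdd,
        skew_deg=psi,
        tilt_x_deg=tilt_x,
        tilt_y_deg=tilt_y,
        mlc_sag_L_mm=sag_L,
        mlc_sag_R_mm=sag_R,
        mlc_sag_G_mm=sag_G,
        mlc_sag_T_mm=sag_T,
        misalignment=fit,
        reference_index=ref_index,
    )
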