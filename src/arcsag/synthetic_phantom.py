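"""Forward simulation of arc acquisitions of the five-ball phantom.

A :class:`MachineModel` describes the gravity-driven deformations of a linac
during gantry rotation as smooth low-order harmonic functions of the gantry
angle: imager (EPID) sag, gantry-head sag, source-to-detector distance
variation, imager yaw (skew), imager tilt (pitch/roll), bulk drifts of the
two MLC carriages, and a static set-up offset of the isocentre ball that
imprints the characteristic cosθ / sinθ signature on its projected track.

:func:`project_markers` maps the model to the apparent marker and field-edge
positions at one gantry angle.  The construction is exact by design: the
analysis equations applied to the noiseless projections return the injected
curves to machine precision, which makes the simulator the ground-truth
oracle for the whole pipeline.  :func:`render_image` rasterises a projection
into a realistic portal image (open-field plateau, linear penumbra, disc
shadows, Gaussian and salt noise) and :func:`simulate_arc` produces a full
arc as DICOM files plus a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError, RenderError
from .imaging_io import SAD_MM, BeamImage, PlanePoint, write_beam_image
from .marker_detection import FieldEdges, MarkerSet, PhantomGeometry

# ---------------------------------------------------------------------------
# Harmonic deformation curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicCurve:
    """Low-order Fourier series in the gantry angle, re-zeroed at zero.

    ``f(θ) = Σ_k cos_k·cos(kθ) + sin_k·sin(kθ) − f(0)``, orders up to 3.
    The subtraction anchors every deformation to the gantry-zero reference
    state.  ``step_at_zero`` adds an optional antisymmetric discontinuity of
    the given total height across θ = 0, emulating the backlash jump seen on
    real machines when the gantry passes through vertical.
    """

    cos: tuple = (0.0, 0.0, 0.0)
    sin: tuple = (0.0, 0.0, 0.0)
    step_at_zero: float = 0.0

    def __post_init__(self):
        if len(self.cos) > 3 or len(self.sin) > 3:
            raise InputError("harmonic curves support orders 1..3 only")

    def __call__(self, theta_deg):
        theta = np.radians(np.asarray(theta_deg, dtype=float))
        out = np.zeros_like(theta)
        for k, c in enumerate(self.cos, start=1):
            out = out + c * (np.cos(k * theta) - 1.0)
        for k, s in enumerate(self.sin, start=1):
            out = out + s * np.sin(k * theta)
        if self.step_at_zero:
            out = out + 0.5 * self.step_at_zero * np.sign(np.sin(theta))
        return out if out.ndim else float(out)

    def amplitude(self) -> float:
        return float(sum(map(abs, self.cos)) * 2 + sum(map(abs, self.sin)) + abs(self.step_at_zero))


ZERO = HarmonicCurve()


@dataclass
class NoiseModel:
    """Additive detector noise: Gaussian read-out noise plus salt spikes."""

    gaussian_sd: float = 3.0  # intensity units on a ~900-unit contrast
    salt_fraction: float = 0.001


@dataclass
class PanelSpec:
    """Imaging panel geometry (detector plane)."""

    rows: int = 768
    cols: int = 1024
    pixel_spacing_mm: float = 0.392

    @classmethod
    def as500(cls) -> "PanelSpec":
        return cls(rows=384, cols=512, pixel_spacing_mm=0.784)


@dataclass
class MachineModel:
    """Parametric deformation model: the recovery target of the pipeline.

    Default curves reproduce the per-component deformation magnitudes that
    typical in-service C-arm linacs exhibit: sub-millimetre cross-plane and
    about 1 mm in-plane imager sag, below 1 mm gantry sag, millimetre-level
    SDD variation, skew below 0.2 degrees, tilt around a tenth of a degree
    and carriage drifts that peak at the lateral gantry positions where
    gravity acts along the leaf-travel direction.
    """

    sdd0_mm: float = 1500.0
    epid_sag_x: HarmonicCurve = field(default_factory=lambda: HarmonicCurve(sin=(0.0, 0.1)))
    epid_sag_y: HarmonicCurve = field(default_factory=lambda: HarmonicCurve(cos=(0.0, 0.5)))
    gantry_sag_x: HarmonicCurve = field(default_factory=lambda: HarmonicCurve(sin=(0.2,)))
    gantry_sag_y: HarmonicCurve = field(default_factory=lambda: HarmonicCurve(cos=(0.0, 0.35)))
    sdd_variation: HarmonicCurve = field(default_factory=lambda: HarmonicCurve(sin=(1.7,)))
    skew: HarmonicCurve = field(default_factory=lambda: HarmonicCurve(sin=(0.15,)))
    tilt_x: HarmonicCurve = field(default_factory=lambda: HarmonicCurve(sin=(0.04,)))
    tilt_y: HarmonicCurve = field(default_factory=lambda: HarmonicCurve(sin=(0.1,)))
    carriage_offset_L: HarmonicCurve = field(default_factory=lambda: HarmonicCurve(sin=(-0.41,)))
    carriage_offset_R: HarmonicCurve = field(default_factory=lambda: HarmonicCurve(sin=(0.49,)))
    carriage_offset_G: HarmonicCurve = field(default_factory=lambda: HarmonicCurve(cos=(0.0, 0.17)))
    carriage_offset_T: HarmonicCurve = field(default_factory=lambda: HarmonicCurve(cos=(0.0, -0.16)))
    e_marker_offset: tuple[float, float] = (0.8, -0.5)  # (lateral A, vertical B) mm
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    _MM_CURVES = (
        "epid_sag_x", "epid_sag_y", "gantry_sag_x", "gantry_sag_y",
        "sdd_variation", "carriage_offset_L", "carriage_offset_R",
        "carriage_offset_G", "carriage_offset_T",
    )
    _DEG_CURVES = ("skew", "tilt_x", "tilt_y")

    def __post_init__(self):
        for name in self._MM_CURVES:
            if getattr(self, name).amplitude() > 10.0:
                raise InputError(f"{name} amplitude exceeds the physical 10 mm range")
        for name in self._DEG_CURVES:
            if getattr(self, name).amplitude() > 1.0:
                raise InputError(f"{name} amplitude exceeds the physical 1 degree range")
        if max(map(abs, self.e_marker_offset)) > 10.0:
            raise InputError("e-marker offset exceeds the physical 10 mm range")

    @classmethod
    def null(cls, sdd0_mm: float = 1500.0, **kwargs) -> "MachineModel":
        """A perfect machine: every deformation curve identically zero."""
        zeros = {name: ZERO for name in cls._MM_CURVES + cls._DEG_CURVES}
        zeros["e_marker_offset"] = (0.0, 0.0)
        zeros.update(kwargs)
        return cls(sdd0_mm=sdd0_mm, **zeros)

    @classmethod
    def from_yaml(cls, path) -> "MachineModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if key in cls._MM_CURVES + cls._DEG_CURVES:
                kwargs[key] = HarmonicCurve(
                    cos=tuple(value.get("cos", ())),
                    sin=tuple(value.get("sin", ())),
                    step_at_zero=float(value.get("step_at_zero", 0.0)),
                )
            elif key == "noise":
                kwargs[key] = NoiseModel(**value)
            elif key == "e_marker_offset":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class AcquisitionPlan:
    """Gantry angles, rotation direction and collimator setting of one arc."""

    mode: str = "cine"  # {"cine", "integrated"}
    start_deg: float = 0.0
    stop_deg: float = 360.0
    step_deg: float = 4.0  # cine: ~4 deg between averaged images
    direction: str = "CW"
    collimator_deg: float = 0.0
    angles_deg: tuple | None = None  # explicit override
    replicate_seeds: tuple = (1, 2, 3)

    def __post_init__(self):
        if self.mode not in ("cine", "integrated"):
            raise InputError(f"unknown acquisition mode {self.mode!r}")
        if self.direction not in ("CW", "CCW"):
            raise InputError(f"direction must be CW or CCW, got {self.direction!r}")

    @classmethod
    def integrated(cls, step_deg: float = 10.0, **kwargs) -> "AcquisitionPlan":
        return cls(mode="integrated", step_deg=step_deg, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionPlan":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "angles_deg" in raw and raw["angles_deg"] is not None:
            raw["angles_deg"] = tuple(raw["angles_deg"])
        if "replicate_seeds" in raw:
            raw["replicate_seeds"] = tuple(raw["replicate_seeds"])
        return cls(**raw)


def acquisition_schedule(plan: AcquisitionPlan) -> np.ndarray:
    """Delivery gantry angles of a plan, in acquisition order.

    Both rotation endpoints are included (a 10-degree integrated plan over a
    full rotation yields 37 images); CCW plans traverse the same angles in
    reverse.
    """
    if plan.angles_deg is not None:
        angles = np.asarray(plan.angles_deg, dtype=float)
    else:
        if plan.step_deg <= 0:
            raise InputError(f"step_deg must be positive, got {plan.step_deg}")
        n = int(round((plan.stop_deg - plan.start_deg) / plan.step_deg))
        angles = plan.start_deg + plan.step_deg * np.arange(n + 1)
    if plan.direction == "CCW":
        angles = angles[::-1]
    if angles.size > 0 and np.ptp(angles) > 360.0:
        raise InputError("acquisition angles exceed a single full rotation")
    return angles


# ---------------------------------------------------------------------------
# Exact geometric projection
# ---------------------------------------------------------------------------


def project_markers(
    model: MachineModel, theta_deg: float, geometry: PhantomGeometry
) -> tuple[MarkerSet, FieldEdges]:
    """Apparent marker and edge positions (isocentre-plane mm) at one angle.

    The head markers carry the combined imager + gantry displacement, the
    pair separations encode the SDD change and the two tilts, the pair
    orientations encode the skew, and the isocentre ball carries the imager
    displacement plus the set-up offset signature.  The construction solves
    the analysis equations in reverse, so the noiseless round trip through
    the metric computation is exact to numerical precision.
    """
    th = float(theta_deg)
    rad = np.radians(th)

    s_x = float(model.epid_sag_x(th))
    s_y = float(model.epid_sag_y(th))
    u_x = s_x + float(model.gantry_sag_x(th))
    u_y = s_y + float(model.gantry_sag_y(th))
    m = 1.0 + float(model.sdd_variation(th)) / model.sdd0_mm
    psi = np.radians(float(model.skew(th)))
    phi_x = np.radians(float(model.tilt_x(th)))
    phi_y = np.radians(float(model.tilt_y(th)))

    a0 = geometry.layout_xy("a")
    b0 = geometry.layout_xy("b")
    c0 = geometry.layout_xy("c")
    d0 = geometry.layout_xy("d")
    W0 = a0[0] - b0[0]  # gun-pair x-separation (== target pair for the square)
    H0 = a0[1] - c0[1]  # left-pair y-separation
    cx0 = 0.25 * (a0[0] + b0[0] + c0[0] + d0[0])
    cy0 = 0.25 * (a0[1] + b0[1] + c0[1] + d0[1])

    D_y = H0 * m  # in-plane distance between gun and target pair midpoints
    D_x = W0 * m  # cross-plane distance between left and right pair midpoints
    p_minus_q = np.tan(phi_y) * D_y * W0 / model.sdd0_mm
    p = W0 * m + 0.5 * p_minus_q  # gun-pair x-separation
    q = W0 * m - 0.5 * p_minus_q  # target-pair x-separation
    r_minus_s = np.tan(phi_x) * D_x * H0 / model.sdd0_mm  # left minus right y-sep
    tpsi = np.tan(psi)
    cd_ydiff = p * tpsi - r_minus_s  # c_Y - d_Y

    a = PlanePoint(cx0 + u_x + 0.5 * p, cy0 + u_y + 0.5 * D_y + 0.5 * p * tpsi)
    b = PlanePoint(cx0 + u_x - 0.5 * p, cy0 + u_y + 0.5 * D_y - 0.5 * p * tpsi)
    c = PlanePoint(cx0 + u_x + 0.5 * q, cy0 + u_y - 0.5 * D_y + 0.5 * cd_ydiff)
    d = PlanePoint(cx0 + u_x - 0.5 * q, cy0 + u_y - 0.5 * D_y - 0.5 * cd_ydiff)

    A, B = model.e_marker_offset
    e = PlanePoint(
        s_x + A * (np.cos(rad) - 1.0),
        s_y + B * np.sin(rad),
    )

    w, h = geometry.field_size_mm
    edges = FieldEdges(
        L_edge_mm=-0.5 * w + u_x - float(model.carriage_offset_L(th)),
        R_edge_mm=0.5 * w + u_x + float(model.carriage_offset_R(th)),
        G_edge_mm=0.5 * h + u_y - float(model.carriage_offset_G(th)),
        T_edge_mm=-0.5 * h + u_y + float(model.carriage_offset_T(th)),
    )
    markers = MarkerSet(a=a, b=b, c=c, d=d, e=e)
    return markers, edges


TRUTH_COLUMNS = (
    "epid_sag_x_mm", "epid_sag_y_mm", "gantry_sag_x_mm", "gantry_sag_y_mm",
    "delta_sdd_mm", "skew_deg", "tilt_x_deg", "tilt_y_deg",
    "mlc_sag_L_mm", "mlc_sag_R_mm", "mlc_sag_G_mm", "mlc_sag_T_mm",
)


def truth_table(model: MachineModel, angles_deg) -> pd.DataFrame:
    """Injected metric curves per angle — what a perfect analysis recovers."""
    angles = np.asarray(angles_deg, dtype=float)
    return pd.DataFrame(
        {
            "gantry_angle_deg": angles,
            "epid_sag_x_mm": model.epid_sag_x(angles),
            "epid_sag_y_mm": model.epid_sag_y(angles),
            "gantry_sag_x_mm": model.gantry_sag_x(angles),
            "gantry_sag_y_mm": model.gantry_sag_y(angles),
            "delta_sdd_mm": model.sdd_variation(angles),
            "skew_deg": model.skew(angles),
            "tilt_x_deg": model.tilt_x(angles),
            "tilt_y_deg": model.tilt_y(angles),
            "mlc_sag_L_mm": model.carriage_offset_L(angles),
            "mlc_sag_R_mm": model.carriage_offset_R(angles),
            "mlc_sag_G_mm": model.carriage_offset_G(angles),
            "mlc_sag_T_mm": model.carriage_offset_T(angles),
        }
    )


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

BASELINE = 100.0  # blocked-region intensity
PLATEAU = 1000.0  # open-field intensity
BB_ATTENUATION = 0.40  # fractional intensity loss under a ball shadow
PENUMBRA_MM = 3.0  # linear penumbra width at the detector plane


def _ramp(x: np.ndarray, edge: float, width: float, rising: bool) -> np.ndarray:
    t = (x - (edge - 0.5 * width)) / width
    t = np.clip(t, 0.0, 1.0)
    return t if rising else 1.0 - t


def render_image(
    markers: MarkerSet,
    edges: FieldEdges,
    *,
    geometry: PhantomGeometry,
    panel: PanelSpec | None = None,
    sdd_mm: float = 1500.0,
    gantry_angle_deg: float = 0.0,
    collimator_angle_deg: float = 0.0,
    acquisition_mode: str = "cine",
    frame_index: int = 0,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> BeamImage:
    """Rasterise one projection into a portal image.

    Open-field plateau with linear penumbra at the four aperture edges and
    disc-shaped attenuation shadows for the five balls (2x2 supersampled,
    smooth one-pixel coverage edge), plus Gaussian read-out noise and salt
    spikes.  Deterministic for a given ``rng`` state.
    """
    panel = panel or PanelSpec()
    noise = noise or NoiseModel()
    mag = sdd_mm / SAD_MM
    dr = dc = panel.pixel_spacing_mm
    x0 = -(panel.cols - 1) / 2.0 * dc
    y0 = (panel.rows - 1) / 2.0 * dr
    x = x0 + np.arange(panel.cols) * dc  # detector mm per column
    y = y0 - np.arange(panel.rows) * dr  # detector mm per row

    half_x = 0.5 * panel.cols * dc
    half_y = 0.5 * panel.rows * dr
    for name in ("a", "b", "c", "d", "e"):
        mx, my = markers.xy(name) * mag
        if abs(mx) > half_x - 5 or abs(my) > half_y - 5:
            raise RenderError(f"marker {name} at ({mx:.0f}, {my:.0f}) mm leaves the panel")

    fx = _ramp(x, edges.L_edge_mm * mag, PENUMBRA_MM, rising=True) * _ramp(
        x, edges.R_edge_mm * mag, PENUMBRA_MM, rising=False
    )
    fy = _ramp(y, edges.T_edge_mm * mag, PENUMBRA_MM, rising=True) * _ramp(
        y, edges.G_edge_mm * mag, PENUMBRA_MM, rising=False
    )
    pixels = BASELINE + (PLATEAU - BASELINE) * np.outer(fy, fx)

    # ball shadows: local patches, 2x2 supersampling, smooth 1 px coverage
    sub = (np.arange(2) - 0.5) / 2.0
    for name in ("a", "b", "c", "d", "e"):
        mx, my = markers.xy(name) * mag
        r_px = geometry.projected_radius_mm(name, sdd_mm) / dc
        row_c = (y0 - my) / dr
        col_c = (mx - x0) / dc
        half = int(np.ceil(r_px)) + 3
        r0, r1 = int(round(row_c)) - half, int(round(row_c)) + half + 1
        c0, c1 = int(round(col_c)) - half, int(round(col_c)) + half + 1
        r0, r1 = max(r0, 0), min(r1, panel.rows)
        c0, c1 = max(c0, 0), min(c1, panel.cols)
        rr, cc = np.mgrid[r0:r1, c0:c1].astype(float)
        cov = np.zeros(rr.shape)
        for sr in sub:
            for sc in sub:
                dist = np.hypot(rr + sr - row_c, cc + sc - col_c)
                cov += np.clip(0.5 + (r_px - dist), 0.0, 1.0)
        cov /= sub.size ** 2
        pixels[r0:r1, c0:c1] *= 1.0 - BB_ATTENUATION * cov

    if rng is not None:
        if noise.gaussian_sd > 0:
            pixels = pixels + rng.normal(0.0, noise.gaussian_sd, size=pixels.shape)
        if noise.salt_fraction > 0:
            salt = rng.random(pixels.shape) < noise.salt_fraction
            pixels[salt] = 1.25 * PLATEAU

    return BeamImage(
        pixels=pixels,
        gantry_angle_deg=gantry_angle_deg,
        collimator_angle_deg=collimator_angle_deg,
        sdd_mm=sdd_mm,
        pixel_spacing_mm=(dr, dc),
        acquisition_mode=acquisition_mode,
        frame_index=frame_index,
    )


# ---------------------------------------------------------------------------
# Full-arc simulation
# ---------------------------------------------------------------------------


def simulate_arc(
    model: MachineModel,
    plan: AcquisitionPlan,
    geometry: PhantomGeometry | None = None,
    *,
    panel: PanelSpec | None = None,
    out_dir=None,
    seed: int | None = None,
) -> tuple[list, pd.DataFrame]:
    """Simulate one arc delivery.

    Returns ``(images, truth)`` where ``images`` is a list of
    :class:`BeamImage` (or of file paths when ``out_dir`` is given, in which
    case DICOM files and ``truth.csv`` are written there) and ``truth`` is
    the injected metric table, one row per scheduled angle.
    """
    geometry = geometry or PhantomGeometry()
    panel = panel or PanelSpec()
    rng = np.random.default_rng(model.seed if seed is None else seed)
    angles = acquisition_schedule(plan)
    truth = truth_table(model, angles)
    truth.insert(1, "iec_angle_deg", np.where(
        np.mod(angles, 360.0) > 180.0, np.mod(angles, 360.0) - 360.0, np.mod(angles, 360.0)
    ))

    images = []
    for i, ang in enumerate(angles):
        markers, edges = project_markers(model, ang, geometry)
        img = render_image(
            markers,
            edges,
            geometry=geometry,
            panel=panel,
            sdd_mm=model.sdd0_mm,
            gantry_angle_deg=ang,
            collimator_angle_deg=plan.collimator_deg,
            acquisition_mode=plan.mode,
            frame_index=i + 1,
            noise=model.noise,
            rng=rng,
        )
        images.append(img)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, img in enumerate(images):
            paths.append(write_beam_image(img, out_dir / f"arc_{i:04d}.dcm"))
        truth.to_csv(out_dir / "truth.csv", index=False)
        return paths, truth
    return images, truth
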