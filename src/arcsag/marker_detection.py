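"""Sub-pixel localisation of the five ball-bearing shadows and MLC edges.

The phantom carries five 4.8 mm tungsten-carbide ball bearings: four
(a, b, c, d) rigidly mounted on the gantry head around the beam axis and one
(e) fixed at the nominal isocentre on a couch-mounted rod.  Their shadows,
together with the four edges of the 18 x 18 cm2 MLC-defined aperture, are
the raw observables of every mechanical metric in this package.

Detection strategy
------------------
1. Preprocessing: conservative smoothing (clamp every pixel into the
   [min, max] of its 8-neighbourhood) removes impulse noise without blurring
   edges, followed by a 2x2 rank-4 (maximum) filter that suppresses dark
   single-pixel dropouts.  The rank filter resamples onto the half-pixel
   offset grid of the window centres; the image origin metadata is shifted
   accordingly so that geometry is preserved.
2. Ball bearings: matched filtering of the background-subtracted, inverted
   image with a disc kernel of the projected ball diameter; candidates are
   local maxima of the match score inside the field aperture; roles a-e are
   assigned by nearest-neighbour matching to the nominal layout after a
   global translation fit; sub-pixel centres are iteratively re-centred
   intensity-weighted centroids.
3. Field edges: 50%-of-contrast crossings of band-averaged profiles, one
   crossing per 5 mm leaf row for the left/right banks (bank edge = mean of
   per-leaf crossings) and a central-third average profile for the gun and
   target edges.  Marker footprints are masked out of the profiles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.signal import fftconvolve

from .errors import AssignmentError, DetectionError, EdgeError, GeometryError
from .imaging_io import SAD_MM, BeamImage, PlanePoint, to_isocentre_mm

MARKER_NAMES = ("a", "b", "c", "d", "e")
HEAD_MARKERS = ("a", "b", "c", "d")


@dataclass(frozen=True)
class Pairing:
    """Which marker pairs feed which equation (configurable; see docs)."""

    sdd: tuple = (("a", "c"), ("b", "d"))  # left pair vs right pair, x
    skew: tuple = (("a", "b"), ("c", "d"))  # gun pair and target pair
    tilt_pitch: tuple = (("a", "b"), ("c", "d"))  # gun vs target, x-separations
    tilt_roll: tuple = (("a", "c"), ("b", "d"))  # left vs right, y-separations


@dataclass
class PhantomGeometry:
    """Nominal phantom layout and detection parameters.

    ``marker_layout`` holds the nominal isocentre-plane (x, y) of each
    marker.  Head markers sit on a square centred on the beam axis; marker
    ``e`` is at the origin.  ``marker_source_distance_mm`` sets each ball's
    distance from the source, which fixes the projected shadow size on the
    panel (the balls themselves are all ``bb_diameter_mm`` across).
    """

    bb_diameter_mm: float = 4.8
    marker_layout: dict = field(
        default_factory=lambda: {
            "a": (60.0, 60.0),  # gun-left
            "b": (-60.0, 60.0),  # gun-right
            "c": (60.0, -60.0),  # target-left
            "d": (-60.0, -60.0),  # target-right
            "e": (0.0, 0.0),  # isocentre
        }
    )
    field_size_mm: tuple[float, float] = (180.0, 180.0)  # (x width, y height)
    marker_source_distance_mm: dict = field(
        default_factory=lambda: {"a": 550.0, "b": 550.0, "c": 550.0, "d": 550.0, "e": SAD_MM}
    )
    pairing: Pairing = field(default_factory=Pairing)
    leaf_width_mm: float = 5.0  # inner-leaf width at isocentre
    rank: int = 4  # 2x2 rank filter order (4 = max, 1 = min)

    def __post_init__(self):
        pts = {k: np.asarray(v, dtype=float) for k, v in self.marker_layout.items()}
        for name in MARKER_NAMES:
            if name not in pts:
                raise GeometryError(f"marker_layout missing marker {name!r}")
        for m, n in itertools.combinations(HEAD_MARKERS, 2):
            if np.linalg.norm(pts[m] - pts[n]) < 1e-6:
                raise GeometryError(f"markers {m!r} and {n!r} coincide")
        for pair_a, pair_b in (self.pairing.sdd, self.pairing.tilt_roll):
            sep = abs(
                (pts[pair_a[0]][0] + pts[pair_a[1]][0]) / 2
                - (pts[pair_b[0]][0] + pts[pair_b[1]][0]) / 2
            )
        if not np.allclose(pts["e"], 0.0):
            raise GeometryError("marker e nominal position must be the origin")

    # -- helpers ---------------------------------------------------------
    def layout_xy(self, name: str) -> np.ndarray:
        return np.asarray(self.marker_layout[name], dtype=float)

    def projected_radius_mm(self, name: str, sdd_mm: float) -> float:
        """Detector-plane radius of the ball shadow for a given SDD."""
        dist = self.marker_source_distance_mm[name]
        return 0.5 * self.bb_diameter_mm * sdd_mm / dist

    def min_pair_separation_mm(self) -> float:
        pts = [self.layout_xy(n) for n in MARKER_NAMES]
        return min(
            float(np.linalg.norm(p - q)) for p, q in itertools.combinations(pts, 2)
        )

    @classmethod
    def from_yaml(cls, path) -> "PhantomGeometry":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pairing" in raw:
            raw["pairing"] = Pairing(
                **{k: tuple(tuple(p) for p in v) for k, v in raw["pairing"].items()}
            )
        if "marker_layout" in raw:
            raw["marker_layout"] = {k: tuple(v) for k, v in raw["marker_layout"].items()}
        if "field_size_mm" in raw:
            raw["field_size_mm"] = tuple(raw["field_size_mm"])
        return cls(**raw)


@dataclass
class MarkerSet:
    """Sub-pixel marker positions (isocentre-plane mm) for one image."""

    a: PlanePoint
    b: PlanePoint
    c: PlanePoint
    d: PlanePoint
    e: PlanePoint
    detection_score: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> PlanePoint:
        return getattr(self, name)

    def xy(self, name: str) -> np.ndarray:
        return self[name].as_array()

    def validate(self, geometry: PhantomGeometry, tol_frac: float = 0.25) -> None:
        """Check pairwise separations against the nominal layout and that
        marker e lies inside the head-marker quadrilateral."""
        for m, n in itertools.combinations(MARKER_NAMES, 2):
            nominal = np.linalg.norm(geometry.layout_xy(m) - geometry.layout_xy(n))
            actual = np.linalg.norm(self.xy(m) - self.xy(n))
            if abs(actual - nominal) > tol_frac * nominal:
                raise AssignmentError(
                    f"separation {m}-{n} = {actual:.1f} mm deviates more than "
                    f"{tol_frac:.0%} from nominal {nominal:.1f} mm"
                )
        xs = [self.xy(n)[0] for n in HEAD_MARKERS]
        ys = [self.xy(n)[1] for n in HEAD_MARKERS]
        ex, ey = self.xy("e")
        if not (min(xs) < ex < max(xs) and min(ys) < ey < max(ys)):
            raise AssignmentError("marker e does not lie inside the a-d quadrilateral")


@dataclass
class FieldEdges:
    """MLC aperture edge positions (isocentre-plane mm) for one image."""

    L_edge_mm: float
    R_edge_mm: float
    G_edge_mm: float
    T_edge_mm: float
    per_leaf_crossings: dict = field(default_factory=lambda: {"L": [], "R": []})

    def validate(self, geometry: PhantomGeometry, tol_frac: float = 0.10) -> None:
        if not self.R_edge_mm > self.L_edge_mm:
            raise EdgeError("right edge does not lie right of left edge")
        if self.T_edge_mm == self.G_edge_mm:
            raise EdgeError("gun and target edges coincide")
        w_nom, h_nom = geometry.field_size_mm
        width = self.R_edge_mm - self.L_edge_mm
        height = abs(self.G_edge_mm - self.T_edge_mm)
        if abs(width - w_nom) > tol_frac * w_nom:
            raise EdgeError(f"aperture width {width:.1f} mm far from nominal {w_nom}")
        if abs(height - h_nom) > tol_frac * h_nom:
            raise EdgeError(f"aperture height {height:.1f} mm far from nominal {h_nom}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

_NEIGHBOURHOOD = np.ones((3, 3), dtype=bool)
_NEIGHBOURHOOD[1, 1] = False


def conservative_smooth(image: BeamImage) -> BeamImage:
    """Clamp each pixel into the [min, max] range of its 8 neighbours.

    Removes isolated noise spikes without degrading high-spatial-frequency
    detail; pixels already inside their neighbourhood range are untouched.
    """
    p = image.pixels
    lo = ndimage.minimum_filter(p, footprint=_NEIGHBOURHOOD, mode="nearest")
    hi = ndimage.maximum_filter(p, footprint=_NEIGHBOURHOOD, mode="nearest")
    return replace(image, pixels=np.clip(p, lo, hi))


def rank_filter_2x2(image: BeamImage, rank: int = 4) -> BeamImage:
    """Apply a 2x2 rank filter (rank 4 = maximum, rank 1 = minimum).

    Each output pixel is the rank-th order statistic of the 2x2 window with
    the output sample placed at the window centre: the pixel grid keeps its
    size (edge padding) and ``origin_mm`` is shifted by half a pixel so that
    symmetric structures keep their measured positions.
    """
    if rank not in (1, 2, 3, 4):
        raise ValueError("rank of a 2x2 window must be in 1..4")
    p = np.pad(image.pixels, ((0, 1), (0, 1)), mode="edge")
    windows = np.stack([p[:-1, :-1], p[1:, :-1], p[:-1, 1:], p[1:, 1:]])
    if rank == 4:
        out = windows.max(axis=0)
    elif rank == 1:
        out = windows.min(axis=0)
    else:
        out = np.sort(windows, axis=0)[rank - 1]
    x0, y0 = image.origin_mm
    dr, dc = image.pixel_spacing_mm
    return replace(image, pixels=out, origin_mm=(x0 + 0.5 * dc, y0 - 0.5 * dr))


def preprocess(image: BeamImage, rank: int = 4) -> BeamImage:
    """Conservative smoothing followed by the 2x2 rank filter."""
    return rank_filter_2x2(conservative_smooth(image), rank=rank)


# ---------------------------------------------------------------------------
# Intensity statistics
# ---------------------------------------------------------------------------


def _field_levels(pixels: np.ndarray) -> tuple[float, float]:
    """Estimate (baseline, plateau): blocked-region and open-field medians."""
    finite = pixels[np.isfinite(pixels)]
    thr = 0.5 * (np.min(finite) + np.max(finite))
    inside = finite[finite > thr]
    outside = finite[finite <= thr]
    if inside.size == 0 or outside.size == 0:
        raise EdgeError("image shows no open-field / blocked-region contrast")
    return float(np.median(outside)), float(np.median(inside))


def _aperture_mask(pixels: np.ndarray, baseline: float, plateau: float) -> np.ndarray:
    thr = baseline + 0.5 * (plateau - baseline)
    mask = pixels > thr
    return ndimage.binary_fill_holes(mask)


# ---------------------------------------------------------------------------
# Ball-bearing detection
# ---------------------------------------------------------------------------


def _disc_kernel(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disc = (xx**2 + yy**2 <= radius_px**2).astype(float)
    return disc / disc.sum()


def _refine_centroid(
    pixels: np.ndarray,
    row: float,
    col: float,
    radius_px: float,
    n_iter: int = 4,
    noise_clip_sigma: float = 2.0,
) -> tuple[float, float]:
    """Iteratively re-centred intensity-weighted centroid of a dark blob.

    The window of radius 1.5 projected radii is recentred on the running
    estimate so that the (near-zero) signal in the outer annulus cancels the
    window-truncation bias of a fixed integer window.  The local background
    and its noise level are estimated from the surrounding annulus (median
    and MAD); weights below ``noise_clip_sigma`` times the noise are zeroed,
    which suppresses the rectified-noise contribution of the empty annulus
    without biasing the symmetric blob.
    """
    R = 1.5 * radius_px
    half = int(np.ceil(R)) + 2
    for _ in range(n_iter):
        r0 = int(round(row))
        c0 = int(round(col))
        rs = slice(max(r0 - half, 0), min(r0 + half + 1, pixels.shape[0]))
        cs = slice(max(c0 - half, 0), min(c0 + half + 1, pixels.shape[1]))
        patch = pixels[rs, cs]
        rr, cc = np.mgrid[rs, cs]
        dist = np.hypot(rr - row, cc - col)
        ring = (dist > R) & (dist <= R + 2)
        if not ring.any():
            break
        background = np.median(patch[ring])
        noise = 1.4826 * np.median(np.abs(patch[ring] - background))
        weights = np.clip(background - patch - noise_clip_sigma * noise, 0.0, None)
        weights[dist > R] = 0.0
        total = weights.sum()
        if total <= 0:
            break
        row = float((weights * rr).sum() / total)
        col = float((weights * cc).sum() / total)
    return row, col


def _fit_disc_model(
    pixels: np.ndarray, row: float, col: float, radius_px: float
) -> tuple[float, float] | None:
    """Least-squares fit of a soft-edged disc shadow to a local patch.

    The model is a uniform attenuation disc whose pixel values integrate
    the disc coverage over each pixel footprint (2-point Gauss quadrature
    per axis — detector pixels are area integrators), with free centre,
    radius, depth, background and edge width.  This concentrates the
    statistical weight at the shadow rim, where the positional information
    lives, and roughly halves the localisation noise of the plain centroid.
    A soft-L1 loss scaled to the local noise level bounds the influence of
    residual impulse noise (adjacent spike pairs survive conservative
    smoothing and would otherwise drag the fit by several micrometres).
    Returns None when the fit fails or wanders, so the caller can keep the
    centroid estimate.
    """
    from scipy.optimize import least_squares

    R = 1.5 * radius_px
    half = int(np.ceil(R)) + 2
    r0, c0 = int(round(row)), int(round(col))
    rs = slice(max(r0 - half, 0), min(r0 + half + 1, pixels.shape[0]))
    cs = slice(max(c0 - half, 0), min(c0 + half + 1, pixels.shape[1]))
    patch = pixels[rs, cs].ravel()
    rr, cc = np.mgrid[rs, cs]
    rr = rr.ravel().astype(float)
    cc = cc.ravel().astype(float)
    dist0 = np.hypot(rr - row, cc - col)
    outside = dist0 > R
    if not outside.any():
        return None
    bg0 = float(np.median(patch[outside]))
    noise = 1.4826 * float(np.median(np.abs(patch[outside] - bg0)))
    depth0 = bg0 - float(patch.min())
    if depth0 <= 0:
        return None
    quad = np.array([-0.25, 0.25])

    def residual(params):
        r_, c_, rad, depth, bg, s = params
        cov = np.zeros_like(patch)
        for sr in quad:
            for sc in quad:
                d = np.hypot(rr + sr - r_, cc + sc - c_)
                cov += np.clip(0.5 + (rad - d) / s, 0.0, 1.0)
        return bg - depth * (cov / 4.0) - patch

    try:
        sol = least_squares(
            residual,
            [row, col, radius_px, depth0, bg0, 1.0],
            method="trf",
            loss="soft_l1",
            f_scale=max(3.0 * noise, 1e-3),
            max_nfev=200,
        )
    except Exception:
        return None
    fit_row, fit_col = float(sol.x[0]), float(sol.x[1])
    if not sol.success or np.hypot(fit_row - row, fit_col - col) > 1.0:
        return None
    return fit_row, fit_col


def detect_markers(image: BeamImage, geometry: PhantomGeometry) -> MarkerSet:
    """Locate the five ball-bearing shadows with sub-pixel precision.

    The candidate search runs on a 2x2 rank-filtered copy of the input
    (single-pixel dropouts cannot seed or split blobs there): matched
    filtering with a disc kernel yields candidate blobs as connected
    regions of high match score, and a global translation fit followed by
    optimal nearest-neighbour assignment maps candidates onto roles a-e.
    Sub-pixel centres are then refined on the *input* intensities by an
    iterative intensity-weighted centroid followed by a soft-edged disc
    model fit, which keeps the localisation noise of the estimator at the
    level set by the detector noise alone.

    Pass a conservatively smoothed image (see :func:`conservative_smooth`);
    a fully rank-filtered image also works, at slightly higher noise.

    Raises :class:`DetectionError` (with the candidate count) when five
    blobs cannot be found, and :class:`AssignmentError` when roles cannot
    be assigned unambiguously.
    """
    p = image.pixels
    baseline, plateau = _field_levels(p)
    contrast = plateau - baseline
    aperture = _aperture_mask(p, baseline, plateau)

    dr, dc = image.pixel_spacing_mm
    radius_px = {
        name: geometry.projected_radius_mm(name, image.sdd_mm) / dc
        for name in MARKER_NAMES
    }
    kernel = _disc_kernel(min(radius_px.values()))

    search = rank_filter_2x2(image, rank=geometry.rank)
    inverted = np.clip(plateau - search.pixels, 0.0, None)
    response = fftconvolve(inverted, kernel, mode="same")
    # keep responses away from the penumbra ring
    interior = ndimage.distance_transform_edt(aperture) > max(radius_px.values()) + 4
    response = np.where(interior, response, 0.0)

    # candidate blobs: connected regions of high match score (the score
    # plateaus inside shadows larger than the kernel, so component centroids
    # are more stable than single peak pixels)
    strong = response > 0.15 * contrast
    labels, n_blobs = ndimage.label(strong)
    weight = np.where(strong, response, 0.0)
    centres = ndimage.center_of_mass(weight, labels, range(1, n_blobs + 1))
    peak_vals = ndimage.maximum(response, labels, range(1, n_blobs + 1))
    order = np.argsort(np.atleast_1d(peak_vals))[::-1]
    candidates = np.array(centres, dtype=float).reshape(-1, 2)[order]
    candidates += 0.5  # rank-filter grid sits at the 2x2 window centres

    if len(candidates) < 5:
        raise DetectionError(
            f"found only {len(candidates)} ball-bearing candidates (need 5)",
            count=len(candidates),
        )
    candidates = candidates[:5]

    nominal_px = np.array(
        [image.pixel_from_iso(*geometry.layout_xy(n)) for n in MARKER_NAMES]
    )
    shift = candidates.mean(axis=0) - nominal_px.mean(axis=0)
    expected = nominal_px + shift
    cost = np.linalg.norm(candidates[:, None, :] - expected[None, :, :], axis=2)
    rows_idx, cols_idx = linear_sum_assignment(cost)
    max_ok_px = 0.25 * geometry.min_pair_separation_mm() * image.magnification / dc
    assigned: dict[str, np.ndarray] = {}
    for ci, ni in zip(rows_idx, cols_idx):
        if cost[ci, ni] > max_ok_px:
            raise AssignmentError(
                f"candidate at {candidates[ci]} is {cost[ci, ni]:.1f} px from its "
                f"best role {MARKER_NAMES[ni]!r}; assignment ambiguous"
            )
        assigned[MARKER_NAMES[ni]] = candidates[ci]

    points: dict[str, PlanePoint] = {}
    scores: dict[str, float] = {}
    for name, (row, col) in assigned.items():
        row, col = _refine_centroid(p, row, col, radius_px[name])
        refined = _fit_disc_model(p, row, col, radius_px[name])
        if refined is not None:
            row, col = refined
        points[name] = to_isocentre_mm(row, col, image)
        peak = response[int(round(assigned[name][0])), int(round(assigned[name][1]))]
        scores[name] = float(np.clip(peak / contrast, 0.0, 1.0))

    markers = MarkerSet(**points, detection_score=scores)
    markers.validate(geometry)
    return markers


# ---------------------------------------------------------------------------
# Field-edge detection
# ---------------------------------------------------------------------------


def _cross_at_half(
    coords: np.ndarray, profile: np.ndarray, threshold: float, near: float, side: str
) -> float:
    """50% crossing of a profile by linear interpolation near ``near``.

    ``coords`` must be sorted ascending.  The crossing searched for is the
    one bracketing ``threshold`` inside a +-15 mm window around the expected
    position; a symmetric linear penumbra yields the geometric edge midpoint
    independent of the penumbra width.
    """
    window = np.abs(coords - near) <= 15.0
    if not window.any():
        raise EdgeError(f"no profile samples near expected {side} edge", side=side)
    idx = np.nonzero(window)[0]
    c = coords[idx]
    v = profile[idx]
    if np.any(~np.isfinite(v)):
        raise EdgeError(f"profile near {side} edge is masked", side=side)
    diff = v - threshold
    sign_change = np.nonzero(diff[:-1] * diff[1:] <= 0)[0]
    sign_change = sign_change[diff[sign_change] != diff[sign_change + 1]]
    if sign_change.size == 0:
        raise EdgeError(f"no 50% crossing found for {side} edge", side=side)
    # crossing closest to the expected position
    best = None
    for i in sign_change:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        pos = c[i] + frac * (c[i + 1] - c[i])
        if best is None or abs(pos - near) < abs(best - near):
            best = float(pos)
    return best


def detect_field_edges(
    image: BeamImage,
    geometry: PhantomGeometry,
    markers: MarkerSet | None = None,
) -> FieldEdges:
    """Locate the four MLC aperture edges (isocentre-plane mm).

    Left/right bank edges: one 50% crossing per leaf row, averaged per bank.
    Gun/target edges: 50% crossings of the in-plane profile averaged over
    the central third of the aperture width.  Marker shadows (radius twice
    the projected ball radius) are masked out of all profiles.
    """
    p = image.pixels.astype(float).copy()
    nrows, ncols = p.shape

    if markers is not None:
        rr, cc = np.mgrid[0:nrows, 0:ncols]
        for name in MARKER_NAMES:
            row, col = image.pixel_from_iso(*markers.xy(name))
            r_px = (
                2.0
                * geometry.projected_radius_mm(name, image.sdd_mm)
                / image.pixel_spacing_mm[1]
            )
            p[(rr - row) ** 2 + (cc - col) ** 2 <= r_px**2] = np.nan

    baseline, plateau = _field_levels(p)
    threshold = baseline + 0.5 * (plateau - baseline)

    scale = SAD_MM / image.sdd_mm  # detector mm -> isocentre mm
    x_mm = image.detector_xy(0, np.arange(ncols))[0] * scale
    y_mm = image.detector_xy(np.arange(nrows), 0)[1] * scale
    w_nom, h_nom = geometry.field_size_mm

    # --- gun / target edges: central third of the aperture width ----------
    central = np.abs(x_mm) <= w_nom / 6.0
    prof_y = np.nanmean(p[:, central], axis=1)
    y_order = np.argsort(y_mm)
    g_edge = _cross_at_half(y_mm[y_order], prof_y[y_order], threshold, h_nom / 2, "G")
    t_edge = _cross_at_half(y_mm[y_order], prof_y[y_order], threshold, -h_nom / 2, "T")

    # --- left / right bank edges: one crossing per leaf row ----------------
    leaf = geometry.leaf_width_mm
    margin = leaf  # stay clear of the gun/target penumbras
    lo, hi = t_edge + margin, g_edge - margin
    n_bands = int(np.floor((hi - lo) / leaf))
    left_cross, right_cross = [], []
    for k in range(n_bands):
        band = (y_mm >= lo + k * leaf) & (y_mm < lo + (k + 1) * leaf)
        if not band.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            prof_x = np.nanmean(p[band, :], axis=0)
        try:
            l_val = _cross_at_half(x_mm, prof_x, threshold, -w_nom / 2, "L")
            r_val = _cross_at_half(x_mm, prof_x, threshold, w_nom / 2, "R")
        except EdgeError:
            continue  # leaf row contaminated by a masked marker footprint
        left_cross.append(l_val)
        right_cross.append(r_val)
    if not left_cross:
        raise EdgeError("no usable leaf rows for the left/right bank edges", side="L")

    edges = FieldEdges(
        L_edge_mm=float(np.mean(left_cross)),
        R_edge_mm=float(np.mean(right_cross)),
        G_edge_mm=g_edge,
        T_edge_mm=t_edge,
        per_leaf_crossings={"L": left_cross, "R": right_cross},
    )
    edges.validate(geometry)
    return edges
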