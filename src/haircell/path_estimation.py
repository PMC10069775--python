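"""Automated cochlear-path estimation.

The organ of Corti is a coiled ribbon; a cell's tonotopic identity depends
on its fractional position along that ribbon, so the ribbon's centerline
must be recovered from the image. The procedure:

1. threshold the cell-body (e.g. anti-MYO7A) channel to a binary mask;
2. downsample the mask by local averaging (factor 10) for speed;
3. binary hole closing, then erosion, to bridge gaps and shed nonspecific
   staining;
4. center the foreground on its centroid and convert every foreground
   pixel to polar (angle, radius) coordinates;
5. unwrap the angles into a continuous single-valued domain — a largest-gap
   period shift for coils subtending less than one turn, plus a
   radius-guided turn unwrapping that handles multi-turn spirals (radius
   grows monotonically along the coil, so sorting by radius orders points
   along the spiral and each angle can be lifted by the 2π multiple nearest
   a running median of its predecessors);
6. fit a Gaussian-process regression of radius on unwrapped angle
   (squared-exponential kernel plus white noise), predict on a dense angle
   grid, convert back to cartesian and rescale to full resolution;
7. designate the end with the tighter curl (larger mean discrete curvature
   over the terminal window) as the apex and parameterize the polyline by
   arc length from it.

Cells are then projected onto the polyline to obtain percent distance from
apex and perpendicular distance from the path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path as _Path

import numpy as np
from scipy.ndimage import binary_closing, binary_erosion
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .errors import ConfigurationError, InputError, PathEstimationError

DEFAULT_DOWNSAMPLE = 10
DEFAULT_OCCUPANCY = 0.05
DEFAULT_CLOSE_RADIUS = 2
DEFAULT_ERODE_RADIUS = 1
DEFAULT_GAP_THRESHOLD_RAD = np.deg2rad(20.0)
DEFAULT_GRID_POINTS = 2000
DEFAULT_MAX_GP_POINTS = 500
APEX_WINDOW_FRACTION = 0.10
APEX_TIE_TOLERANCE = 0.05  # relative curvature difference below which ends tie


@dataclass
class PolarPointSet:
    """Foreground pixels in polar coordinates about a fixed center.

    theta is in radians (continuous after unwrapping); radius in pixels of
    the frame the mask lives in; center is the (row, col) used for the
    shift.
    """

    theta: np.ndarray
    radius: np.ndarray
    center: tuple

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        if self.theta.shape != self.radius.shape:
            raise InputError("theta and radius must have equal length")
        if np.any(self.radius < 0):
            raise InputError("radii must be non-negative")

    def __len__(self) -> int:
        return self.theta.size

    def to_cartesian(self) -> np.ndarray:
        """(N, 2) rows/cols reconstructed from (theta, radius, center)."""
        rows = self.center[0] + self.radius * np.sin(self.theta)
        cols = self.center[1] + self.radius * np.cos(self.theta)
        return np.column_stack([rows, cols])


@dataclass
class CochlearPath:
    """Ordered centerline polyline, apex first.

    points are (row, col) full-resolution pixels; cumulative_um is the
    arc length from the apex (cumulative_um[0] == 0). apex_tie_flag marks
    paths whose apex inference was ambiguous (manual review advised).
    """

    points: np.ndarray
    pixel_size_nm: float
    apex_index: int = 0
    cumulative_um: np.ndarray = field(default=None)
    apex_tie_flag: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise InputError("path needs >= 2 (row, col) points")
        if self.pixel_size_nm <= 0:
            raise InputError("pixel_size_nm must be positive")
        if self.apex_index not in (0, len(self.points) - 1):
            raise InputError("apex must be one of the two polyline ends")
        if self.apex_index != 0:  # normalize to apex-first storage
            self.points = self.points[::-1].copy()
            self.apex_index = 0
        if self.cumulative_um is None:
            self.cumulative_um = self._arc_length_um()
        else:
            self.cumulative_um = np.asarray(self.cumulative_um, dtype=np.float64)
        if self.cumulative_um[0] != 0 or np.any(np.diff(self.cumulative_um) < 0):
            raise InputError("cumulative_um must start at 0 and be non-decreasing")
        if self.total_length_um <= 0:
            raise InputError("path must have positive total length")

    def _arc_length_um(self) -> np.ndarray:
        um_per_px = self.pixel_size_nm / 1000.0
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1) * um_per_px
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length_um(self) -> float:
        return float(self.cumulative_um[-1])

    @property
    def apex_point(self) -> np.ndarray:
        return self.points[0]

    @property
    def base_point(self) -> np.ndarray:
        return self.points[-1]


def rasterize_mask(img, channel: int | None = None, threshold: float | None = None) -> np.ndarray:
    """Binary mask of supra-threshold cell-body fluorescence.

    *channel* defaults to the channel tagged ``cell_body`` (else 0);
    *threshold* defaults to Otsu's threshold on that channel — the
    threshold is deliberately exposed because a poor setting is the known
    failure mode of automated path estimation.
    """
    if channel is None:
        channel = img.channel_with_role("cell_body", default=0)
    if not (0 <= channel < img.n_channels):
        raise InputError(f"channel {channel} out of range")
    plane = img.pixels[channel]
    if threshold is None:
        if plane.max() <= plane.min():
            raise PathEstimationError(
                "cell-body channel is constant; adjust the threshold or supply a manual path"
            )
        threshold = float(threshold_otsu(plane))
    elif not (0.0 <= threshold <= 1.0):
        raise InputError("threshold must lie in [0, 1]")
    return plane > threshold


def downsample_binary(mask: np.ndarray, factor: int = DEFAULT_DOWNSAMPLE, occupancy: float = DEFAULT_OCCUPANCY) -> np.ndarray:
    """Local-average downsampling of a binary mask.

    Non-overlapping factor x factor blocks are averaged; a block is
    foreground iff its mean occupancy exceeds *occupancy*. Output dims are
    ceil(dim / factor).
    """
    if factor < 1:
        raise InputError("factor must be >= 1")
    if factor == 1:
        return mask.astype(bool).copy()
    mask = np.asarray(mask, dtype=np.float64)
    h, w = mask.shape
    hh, ww = int(np.ceil(h / factor)), int(np.ceil(w / factor))
    padded = np.zeros((hh * factor, ww * factor))
    padded[:h, :w] = mask
    block_mean = padded.reshape(hh, factor, ww, factor).mean(axis=(1, 3))
    return block_mean > occupancy


def morph_clean(mask: np.ndarray, close_radius: int = DEFAULT_CLOSE_RADIUS, erode_radius: int = DEFAULT_ERODE_RADIUS) -> np.ndarray:
    """Binary hole closing then erosion with disk structuring elements."""
    if close_radius < 0 or erode_radius < 0:
        raise InputError("radii must be >= 0")
    out = np.asarray(mask, dtype=bool)
    if close_radius > 0:
        out = binary_closing(out, structure=disk(close_radius))
    if erode_radius > 0:
        out = binary_erosion(out, structure=disk(erode_radius))
    return out


def to_polar(mask: np.ndarray) -> PolarPointSet:
    """Foreground pixels about their centroid as (angle, radius) pairs.

    Angles are atan2-based, measured from the +col axis toward the +row
    axis, raw range (-pi, pi].
    """
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    if rows.size < 10:
        raise PathEstimationError(
            f"only {rows.size} foreground pixels; lower the threshold or supply a manual path"
        )
    center = (float(rows.mean()), float(cols.mean()))
    # The centroid of a spiral ribbon is biased toward its outer turns; an
    # off-center conversion makes the per-turn radius wobble and breaks
    # turn unwrapping. When the coil wraps the full circle, seed the center
    # from the spiral's inner hole and refine it so the radius-vs-angle
    # relation sheds its once-per-turn sinusoid (see _refine_spiral_center).
    raw_theta = np.arctan2(rows - center[0], cols - center[1])
    occupancy, _ = np.histogram(raw_theta, bins=24, range=(-np.pi, np.pi))
    if np.all(occupancy > 0):
        center = _refine_spiral_center(np.asarray(mask, dtype=bool), rows, cols, center)
    dr = rows - center[0]
    dc = cols - center[1]
    return PolarPointSet(
        theta=np.arctan2(dr, dc),
        radius=np.hypot(dr, dc),
        center=center,
    )


def _refine_spiral_center(mask: np.ndarray, rows: np.ndarray, cols: np.ndarray, fallback: tuple) -> tuple:
    """Locate the center of a coiled ribbon that wraps the full circle.

    Seed: the deepest background pixel (euclidean distance transform) in
    the interior of the foreground bounding box that sees foreground in
    every direction — i.e. the spiral's inner hole. Refine: convert to
    polar about the current estimate, unwrap turns, regress radius on
    ``[1, theta, sin(theta_raw), cos(theta_raw)]`` — for a center offset
    (drow, dcol) the radius picks up the sinusoid drow*sin + dcol*cos, so
    the sinusoid coefficients are the remaining offset. A handful of
    damped iterations converges to sub-pixel accuracy.
    """
    from scipy.ndimage import distance_transform_edt

    dt = distance_transform_edt(~mask)
    rmin, rmax = rows.min(), rows.max()
    cmin, cmax = cols.min(), cols.max()
    h, w = rmax - rmin, cmax - cmin
    interior = np.zeros_like(dt, dtype=bool)
    interior[rmin + h // 4 : rmax - h // 4, cmin + w // 4 : cmax - w // 4] = True
    candidates = np.argsort(np.where(interior, dt, -1.0), axis=None)[::-1]
    W = mask.shape[1]
    seed = None
    for k in candidates[: min(3000, candidates.size)]:
        r0, c0 = divmod(int(k), W)
        if dt[r0, c0] <= 0:
            break
        th = np.arctan2(rows - r0, cols - c0)
        occ, _ = np.histogram(th, bins=24, range=(-np.pi, np.pi))
        if np.all(occ > 0):
            seed = np.array([float(r0), float(c0)])
            break
    if seed is None:
        return fallback

    center = seed
    best = (np.inf, tuple(center))
    for _ in range(8):
        dr = rows - center[0]
        dc = cols - center[1]
        raw = np.arctan2(dr, dc)
        p = unwrap_turns(PolarPointSet(theta=raw, radius=np.hypot(dr, dc), center=tuple(center)))
        # sin/cos use the raw (periodic) angle; the linear term the unwrapped one
        design = np.column_stack(
            [np.ones_like(p.theta), p.theta, np.sin(p.theta), np.cos(p.theta)]
        )
        coef, *_ = np.linalg.lstsq(design, p.radius, rcond=None)
        resid_sd = float(np.std(p.radius - design @ coef))
        if resid_sd < best[0]:
            best = (resid_sd, (float(center[0]), float(center[1])))
        step = 0.8 * np.array([coef[2], coef[3]])
        if np.linalg.norm(step) < 1e-3:
            break
        center = center + step
    return best[1]


def unwrap_gap(p: PolarPointSet, gap_threshold_rad: float = DEFAULT_GAP_THRESHOLD_RAD) -> PolarPointSet:
    """Single-period shift across the largest angular gap.

    A coil subtending less than a full turn leaves an empty angular sector;
    if the largest circular gap between consecutive sorted angles exceeds
    the threshold (and is interior, i.e. not the wrap-around between the
    maximum and minimum+2π), every angle at or below the gap's lower edge
    is lifted by one period, yielding a continuous angular domain.
    """
    if len(p) == 0:
        return p
    theta = np.mod(p.theta + np.pi, 2 * np.pi) - np.pi  # canonical (-pi, pi]
    order = np.argsort(theta)
    s = theta[order]
    internal_gaps = np.diff(s)
    wrap_gap = (s[0] + 2 * np.pi) - s[-1]
    if internal_gaps.size == 0 or internal_gaps.max() <= max(wrap_gap, gap_threshold_rad):
        return PolarPointSet(theta=theta, radius=p.radius.copy(), center=p.center)
    i = int(np.argmax(internal_gaps))
    lower_edge = s[i]
    shifted = np.where(theta <= lower_edge, theta + 2 * np.pi, theta)
    return PolarPointSet(theta=shifted, radius=p.radius.copy(), center=p.center)


def unwrap_turns(p: PolarPointSet, window: int = 25) -> PolarPointSet:
    """Radius-guided unwrapping for multi-turn coils.

    Along an outward-coiling ribbon the radius grows monotonically with the
    continuous angle, so sorting points by radius orders them along the
    spiral. Each raw angle is then lifted by the integer multiple of 2π
    that brings it nearest the running median of the preceding *window*
    continuous angles. Output points are sorted by radius.
    """
    if len(p) == 0:
        return p
    order = np.argsort(p.radius, kind="stable")
    theta = np.mod(p.theta[order] + np.pi, 2 * np.pi) - np.pi
    radius = p.radius[order]
    cont = np.empty_like(theta)
    cont[0] = theta[0]
    two_pi = 2 * np.pi
    for i in range(1, theta.size):
        ref = np.median(cont[max(0, i - window) : i])
        k = np.round((ref - theta[i]) / two_pi)
        cont[i] = theta[i] + k * two_pi
    return PolarPointSet(theta=cont, radius=radius, center=p.center)


def _gp_kernel():
    return ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
        length_scale=1.0, length_scale_bounds=(0.05, 20.0)
    ) + WhiteKernel(noise_level=0.05, noise_level_bounds=(1e-6, 1.0))


def fit_path(
    p: PolarPointSet,
    seed: int = 0,
    pixel_size_nm: float = 288.0,
    scale_factor: int = DEFAULT_DOWNSAMPLE,
    n_grid: int = DEFAULT_GRID_POINTS,
    max_gp_points: int = DEFAULT_MAX_GP_POINTS,
) -> CochlearPath:
    """Gaussian-process fit of radius on unwrapped angle.

    The GP (squared-exponential kernel plus white noise, hyperparameters by
    marginal-likelihood optimization) is fit to at most *max_gp_points*
    points (seeded subsample) and predicted on a dense uniform angle grid
    spanning the observed range. Predictions convert back to cartesian and
    are rescaled by *scale_factor* to full-resolution pixels; block centers
    of the downsampled frame map to ``factor*coord + (factor-1)/2``.
    """
    if len(p) < 10:
        raise PathEstimationError("need >= 10 polar points to fit a path")
    theta, radius = p.theta, p.radius
    if theta.size > max_gp_points:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(theta.size, size=max_gp_points, replace=False))
        theta, radius = theta[idx], radius[idx]
    gp = GaussianProcessRegressor(
        kernel=_gp_kernel(), normalize_y=True, n_restarts_optimizer=0, random_state=seed
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(theta[:, None], radius)
        grid = np.linspace(p.theta.min(), p.theta.max(), n_grid)
        r_pred = gp.predict(grid[:, None])
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise PathEstimationError(
            f"Gaussian-process fit failed ({exc}); supply a manual path"
        ) from exc
    if np.any(~np.isfinite(r_pred)) or np.any(r_pred <= 0):
        raise PathEstimationError("Gaussian-process fit produced invalid radii; supply a manual path")
    rows = p.center[0] + r_pred * np.sin(grid)
    cols = p.center[1] + r_pred * np.cos(grid)
    points = np.column_stack([rows, cols]) * scale_factor + (scale_factor - 1) / 2.0
    return CochlearPath(points=points, pixel_size_nm=pixel_size_nm)


def _discrete_curvature(points: np.ndarray) -> np.ndarray:
    """Three-point (circumradius) curvature at interior vertices."""
    a = points[:-2]
    b = points[1:-1]
    c = points[2:]
    ab = np.linalg.norm(b - a, axis=1)
    bc = np.linalg.norm(c - b, axis=1)
    ca = np.linalg.norm(c - a, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    area2 = np.abs(cross)
    denom = ab * bc * ca
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * area2 / denom, 0.0)
    return kappa


def infer_apex(path: CochlearPath) -> CochlearPath:
    """Designate the end with the tighter curl as the apex.

    Discrete three-point curvature is averaged over the terminal 10% of
    vertices at each end; the end with the larger mean magnitude becomes
    the apex (the coiled organ of Corti curls most tightly at its apical,
    low-frequency end). Near-equal curvature raises a tie flag, defaults
    the apex to the first point, and marks the path for manual review.
    """
    n = len(path.points)
    if n < 20:
        raise InputError("apex inference needs >= 20 path points")
    kappa = _discrete_curvature(path.points)
    k = max(3, int(round(APEX_WINDOW_FRACTION * n)))
    head = float(np.mean(kappa[:k]))
    tail = float(np.mean(kappa[-k:]))
    scale = max(head, tail)
    if scale <= 0 or abs(head - tail) / scale < APEX_TIE_TOLERANCE:
        warnings.warn(
            "apex inference tie: terminal curvatures are indistinguishable; "
            "defaulting apex to the first point — review manually",
            stacklevel=2,
        )
        return CochlearPath(
            points=path.points.copy(),
            pixel_size_nm=path.pixel_size_nm,
            apex_tie_flag=True,
        )
    apex_end = 0 if head > tail else n - 1
    return CochlearPath(
        points=path.points.copy(),
        pixel_size_nm=path.pixel_size_nm,
        apex_index=apex_end,
    )


def swap_apex(path: CochlearPath) -> CochlearPath:
    """Flip the apex/base designation (involution)."""
    return CochlearPath(
        points=path.points[::-1].copy(),
        pixel_size_nm=path.pixel_size_nm,
        apex_tie_flag=path.apex_tie_flag,
    )


def load_manual_path(file, pixel_size_nm: float) -> CochlearPath:
    """Read a manually annotated path (CSV of x,y pixels, base→apex order).

    The ImageJ point-export convention traces base to apex, so the apex is
    the final point of the file; the returned path is apex-first.
    """
    file = _Path(file)
    if not file.exists():
        raise InputError(f"manual path file not found: {file}")
    points = []
    with open(file, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.replace("\t", ",").split(",") if p.strip()]
            if lineno == 1 and parts and not _is_number(parts[0]):
                continue  # header row
            if len(parts) < 2 or not all(_is_number(v) for v in parts[:2]):
                raise InputError(f"{file}:{lineno}: expected 'x,y' numeric row; got {line!r}")
            x, y = float(parts[0]), float(parts[1])
            points.append((y, x))  # file stores x=col, y=row
    if len(points) < 2:
        raise InputError(f"{file}: a manual path needs >= 2 points")
    pts = np.asarray(points, dtype=np.float64)
    return CochlearPath(points=pts, pixel_size_nm=pixel_size_nm, apex_index=len(pts) - 1)


def save_manual_path(path: CochlearPath, file) -> None:
    """Write a path back out in the manual x,y base→apex dialect."""
    pts = path.points[::-1]  # apex-first storage -> base-first file
    with open(file, "w", encoding="utf-8") as fh:
        fh.write("x,y\n")
        for row, col in pts:
            fh.write(f"{col},{row}\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def project_cells(dets: list, path: CochlearPath) -> list:
    """Project detection centroids onto the path polyline.

    Returns ``(detection, percent_from_apex, distance_um)`` triples:
    the arc-length fraction (0 at the apex, 100 at the base) of the nearest
    point on the polyline, and the perpendicular distance to it in microns.
    """
    if not dets:
        return []
    um_per_px = path.pixel_size_nm / 1000.0
    pts = path.points
    seg_start = pts[:-1]
    seg_vec = pts[1:] - pts[:-1]
    seg_len2 = (seg_vec ** 2).sum(axis=1)
    seg_len2 = np.where(seg_len2 > 0, seg_len2, 1e-12)
    cum_um = path.cumulative_um
    total = path.total_length_um
    centroids = np.asarray([d.centroid for d in dets], dtype=np.float64)
    out = []
    chunk = 512
    for start in range(0, len(dets), chunk):
        block = centroids[start : start + chunk]  # (B, 2)
        diff = block[:, None, :] - seg_start[None, :, :]  # (B, S, 2)
        t = np.clip((diff * seg_vec[None]).sum(-1) / seg_len2[None], 0.0, 1.0)
        foot = seg_start[None] + t[..., None] * seg_vec[None]
        d2 = ((block[:, None, :] - foot) ** 2).sum(-1)
        best = np.argmin(d2, axis=1)
        rows = np.arange(block.shape[0])
        dist_um = np.sqrt(d2[rows, best]) * um_per_px
        seg_um = np.diff(cum_um)
        arc_um = cum_um[best] + t[rows, best] * seg_um[best]
        percent = np.clip(arc_um / total * 100.0, 0.0, 100.0)
        for j in range(block.shape[0]):
            out.append((dets[start + j], float(percent[j]), float(dist_um[j])))
    return out


def estimate_path(
    img,
    channel: int | None = None,
    threshold: float | None = None,
    seed: int = 0,
    downsample_factor: int = DEFAULT_DOWNSAMPLE,
    occupancy: float = DEFAULT_OCCUPANCY,
    close_radius: int = DEFAULT_CLOSE_RADIUS,
    erode_radius: int = DEFAULT_ERODE_RADIUS,
    n_grid: int = DEFAULT_GRID_POINTS,
    max_gp_points: int = DEFAULT_MAX_GP_POINTS,
) -> CochlearPath:
    """End-to-end automated path estimation on a whole-coil image."""
    mask = rasterize_mask(img, channel=channel, threshold=threshold)
    if not mask.any():
        raise PathEstimationError(
            "no supra-threshold cell-body pixels; adjust the threshold or supply a manual path"
        )
    small = downsample_binary(mask, factor=downsample_factor, occupancy=occupancy)
    small = morph_clean(small, close_radius=close_radius, erode_radius=erode_radius)
    polar = to_polar(small)
    polar = unwrap_turns(unwrap_gap(polar))
    path = fit_path(
        polar,
        seed=seed,
        pixel_size_nm=img.pixel_size_nm,
        scale_factor=downsample_factor,
        n_grid=n_grid,
        max_gp_points=max_gp_points,
    )
    return infer_apex(path)
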