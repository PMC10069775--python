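"""Synthetic whole-cochlea generator with exact ground truth.

Emulates a flat-mounted neonatal cochlea: the organ of Corti is modelled as
an Archimedean spiral ribbon (r = a + b*theta) carrying one row of inner
hair cells on its inner side and three rows of outer hair cells on its
outer side. Two fluorescence channels are rendered — a cell-body channel
(contiguous ribbon of overlapping soma blobs, IHC somata larger and
brighter) and a stereocilia-bundle channel (separated per-cell blobs, IHC
blobs larger than OHC) — plus Gaussian noise and optional off-path
background blobs. Every cell records its exact arc-length position
(percent from apex, apex = inner terminus, where an Archimedean spiral
curls tightest) and its ground-truth Greenwood best frequency.

Default geometry reproduces a whole coil at desk scale: 2.25 turns,
~5 mm total arc length, rendered at a working pixel size of 1152 nm/px
(288 nm/px imagery downscaled 4x), giving ~1120 px square images with
realistic inter-cell spacings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import Detection, IHC, OHC
from .errors import GeneratorError
from .frequency import GreenwoodParams, get_params, greenwood_frequency
from .image_io import MultiChannelImage
from .path_estimation import CochlearPath

# Study-condition defaults.
DEFAULT_TURNS = 2.25
DEFAULT_PIXEL_SIZE_NM = 1152.0  # 288 nm/px imagery, downscaled 4x
DEFAULT_A_PX = 100.0  # inner radius of the spiral, px
DEFAULT_B_PX = 29.0  # radial growth per radian, px
DEFAULT_IHC_SPACING_UM = 9.0
DEFAULT_OHC_SPACING_UM = 8.0
#: Signed perpendicular offsets (µm): negative = inner (modiolar) side.
DEFAULT_ROW_OFFSETS_UM = {"IHC": (-10.0,), "OHC": (6.0, 14.0, 22.0)}
DEFAULT_NOISE_SD = 0.05
DEFAULT_SOMA_SIGMA_UM = {"IHC": 3.2, "OHC": 2.0}
DEFAULT_BUNDLE_SIGMA_UM = {"IHC": 2.0, "OHC": 1.4}
DEFAULT_SOMA_AMPLITUDE = {"IHC": 1.0, "OHC": 0.7}
DEFAULT_BUNDLE_AMPLITUDE = {"IHC": 0.9, "OHC": 0.9}
DEFAULT_JITTER_UM = 0.4


@dataclass
class GroundTruthCell:
    """One generated hair cell with exact tonotopic bookkeeping."""

    label: str
    centroid: tuple  # (row, col) px
    arc_um: float
    percent_from_apex: float
    frequency_khz: float
    row_index: int  # 0 for IHC; 0..2 for the three OHC rows
    dropped: bool = False


@dataclass
class SyntheticCochlea:
    """A rendered synthetic cochlea plus its complete ground truth."""

    image: MultiChannelImage
    cells: list  # ground-truth Detection boxes for surviving cells
    truth: list  # GroundTruthCell for surviving cells (same order as cells)
    dropped: list  # GroundTruthCell removed by simulated hair-cell loss
    background: list  # ground-truth Detection boxes of off-path distractors
    centerline: CochlearPath  # analytic spiral polyline, apex first
    analytic_length_um: float  # closed-form spiral arc length
    params: dict = field(default_factory=dict)


def archimedean_arc_length(a: float, b: float, theta: float) -> float:
    """Closed-form arc length of r = a + b*t from t = 0 to t = theta."""
    if b == 0:
        return a * theta

    def antideriv(u):
        return 0.5 * (u * np.sqrt(1 + u * u) + np.arcsinh(u))

    return b * (antideriv(a / b + theta) - antideriv(a / b))


def make_spiral(
    turns: float = DEFAULT_TURNS,
    a: float = DEFAULT_A_PX,
    b: float = DEFAULT_B_PX,
    n_points: int = 4000,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    center: tuple | None = None,
    ribbon_halfwidth_um: float = 30.0,
) -> CochlearPath:
    """Archimedean spiral centerline with exact arc length attached.

    The spiral is sampled uniformly in theta over [0, 2*pi*turns]; the
    inner terminus (theta = 0) is the apex. Parameters whose turn-to-turn
    radial spacing (2*pi*b) is smaller than the rendered ribbon width would
    self-intersect and are rejected.
    """
    if turns <= 0.25:
        raise GeneratorError("turns must exceed 0.25")
    if b < 0:
        raise GeneratorError("b must be >= 0")
    um_per_px = pixel_size_nm / 1000.0
    if turns > 1 and b > 0 and 2 * np.pi * b * um_per_px < 2 * ribbon_halfwidth_um:
        raise GeneratorError(
            "spiral turns closer than the ribbon width would self-intersect; increase b"
        )
    if turns > 1 and b == 0:
        raise GeneratorError("a multi-turn circle (b = 0) self-intersects")
    theta_max = 2 * np.pi * turns
    theta = np.linspace(0.0, theta_max, n_points)
    r = a + b * theta
    if center is None:
        extent = r.max() + ribbon_halfwidth_um / um_per_px + 20
        center = (extent, extent)
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    return CochlearPath(points=np.column_stack([rows, cols]), pixel_size_nm=pixel_size_nm)


def _spiral_geometry(turns, a, b, n_dense=20000):
    """Dense theta grid with exact cumulative arc length (px)."""
    theta = np.linspace(0.0, 2 * np.pi * turns, n_dense)
    s = np.array([archimedean_arc_length(a, b, t) for t in theta[:: n_dense // 200 + 1]])
    # interpolate the closed form onto the full grid (it is smooth and monotone)
    theta_coarse = theta[:: n_dense // 200 + 1]
    s_dense = np.interp(theta, theta_coarse, s)
    return theta, s_dense


def place_cells(
    turns: float = DEFAULT_TURNS,
    a: float = DEFAULT_A_PX,
    b: float = DEFAULT_B_PX,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    center: tuple = (560.0, 560.0),
    ihc_spacing_um: float = DEFAULT_IHC_SPACING_UM,
    ohc_spacing_um: float = DEFAULT_OHC_SPACING_UM,
    row_offsets_um: dict = None,
    dropout_fraction: float = 0.0,
    jitter_um: float = DEFAULT_JITTER_UM,
    greenwood: GreenwoodParams | None = None,
    seed: int = 0,
) -> tuple:
    """Place IHC/OHC rows along the spiral at regular arc-length intervals.

    Returns ``(survivors, dropped)`` lists of :class:`GroundTruthCell`.
    Cell arc positions carry jitter but the recorded percent/frequency come
    from the exact (jittered) analytic parameterization. *dropout_fraction*
    simulates hair-cell loss; removed cells are recorded, not discarded.
    """
    if ihc_spacing_um <= 0 or ohc_spacing_um <= 0:
        raise GeneratorError("cell spacings must be positive")
    if not (0 <= dropout_fraction < 1):
        raise GeneratorError("dropout_fraction must lie in [0, 1)")
    row_offsets_um = row_offsets_um or DEFAULT_ROW_OFFSETS_UM
    greenwood = greenwood or get_params()
    rng = np.random.default_rng(seed)
    um_per_px = pixel_size_nm / 1000.0

    theta_grid, s_grid_px = _spiral_geometry(turns, a, b)
    total_um = s_grid_px[-1] * um_per_px

    def theta_at_arc_um(s_um):
        return np.interp(s_um / um_per_px, s_grid_px, theta_grid)

    survivors, dropped = [], []
    specs = [(IHC, ihc_spacing_um, row_offsets_um["IHC"])] + [
        (OHC, ohc_spacing_um, row_offsets_um["OHC"])
    ]
    for label, spacing, offsets in specs:
        for row_idx, offset_um in enumerate(offsets):
            n_cells = int(np.floor(total_um / spacing))
            for i in range(n_cells):
                s_um = (i + 0.5) * spacing + rng.normal(0.0, jitter_um)
                s_um = float(np.clip(s_um, 0.0, total_um))
                th = float(theta_at_arc_um(s_um))
                r = a + b * th
                # unit tangent / outward normal of the spiral at theta
                dr_row = b * np.sin(th) + r * np.cos(th)
                dr_col = b * np.cos(th) - r * np.sin(th)
                norm = np.hypot(dr_row, dr_col)
                t_row, t_col = dr_row / norm, dr_col / norm
                n_row, n_col = -t_col, t_row
                # orient the normal outward (away from the spiral center)
                p_row = r * np.sin(th)
                p_col = r * np.cos(th)
                if n_row * p_row + n_col * p_col < 0:
                    n_row, n_col = -n_row, -n_col
                off_px = (offset_um + rng.normal(0.0, jitter_um)) / um_per_px
                row = center[0] + p_row + off_px * n_row
                col = center[1] + p_col + off_px * n_col
                cell = GroundTruthCell(
                    label=label,
                    centroid=(float(row), float(col)),
                    arc_um=s_um,
                    percent_from_apex=s_um / total_um * 100.0,
                    frequency_khz=greenwood_frequency(s_um / total_um, greenwood),
                    row_index=row_idx,
                )
                if rng.random() < dropout_fraction:
                    cell.dropped = True
                    dropped.append(cell)
                else:
                    survivors.append(cell)
    return survivors, dropped


def _add_blob(plane: np.ndarray, row: float, col: float, sigma_px: float, amplitude: float):
    """Accumulate one Gaussian blob on a local patch (4 sigma support)."""
    h, w = plane.shape
    half = int(np.ceil(4 * sigma_px))
    r0, r1 = max(0, int(row) - half), min(h, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(w, int(col) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    plane[r0:r1, c0:c1] += amplitude * np.exp(-(rr * rr + cc * cc) / (2 * sigma_px * sigma_px))


def render(
    turns: float = DEFAULT_TURNS,
    a: float = DEFAULT_A_PX,
    b: float = DEFAULT_B_PX,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    image_size: int | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    background_blobs: int = 0,
    dropout_fraction: float = 0.0,
    ihc_spacing_um: float = DEFAULT_IHC_SPACING_UM,
    ohc_spacing_um: float = DEFAULT_OHC_SPACING_UM,
    row_offsets_um: dict = None,
    soma_sigma_um: dict = None,
    bundle_sigma_um: dict = None,
    jitter_um: float = DEFAULT_JITTER_UM,
    greenwood: GreenwoodParams | None = None,
    seed: int = 0,
) -> SyntheticCochlea:
    """Render a complete synthetic cochlea (soma + bundle channels).

    Ground-truth boxes are squares of side 4x the class bundle sigma
    centred on each bundle blob. Background blobs (distractors away from
    the coil) are injected into both channels and recorded separately in
    the truth. Fully reproducible from *seed*.
    """
    soma_sigma_um = soma_sigma_um or DEFAULT_SOMA_SIGMA_UM
    bundle_sigma_um = bundle_sigma_um or DEFAULT_BUNDLE_SIGMA_UM
    greenwood = greenwood or get_params()
    um_per_px = pixel_size_nm / 1000.0
    ribbon_halfwidth_um = max(
        abs(v) for offs in (row_offsets_um or DEFAULT_ROW_OFFSETS_UM).values() for v in offs
    ) + 4 * max(soma_sigma_um.values())

    centerline = make_spiral(
        turns=turns, a=a, b=b, pixel_size_nm=pixel_size_nm,
        ribbon_halfwidth_um=ribbon_halfwidth_um,
    )
    # make_spiral centers the spiral so the ribbon fits with a margin
    r_max = a + b * 2 * np.pi * turns
    extent = r_max + ribbon_halfwidth_um / um_per_px + 20
    center = (extent, extent)
    if image_size is None:
        image_size = int(np.ceil(2 * extent))

    survivors, dropped = place_cells(
        turns=turns, a=a, b=b, pixel_size_nm=pixel_size_nm, center=center,
        ihc_spacing_um=ihc_spacing_um, ohc_spacing_um=ohc_spacing_um,
        row_offsets_um=row_offsets_um, dropout_fraction=dropout_fraction,
        jitter_um=jitter_um, greenwood=greenwood, seed=seed,
    )

    soma = np.zeros((image_size, image_size), dtype=np.float64)
    bundle = np.zeros_like(soma)
    for cell in survivors:
        row, col = cell.centroid
        _add_blob(soma, row, col, soma_sigma_um[cell.label] / um_per_px,
                  DEFAULT_SOMA_AMPLITUDE[cell.label])
        _add_blob(bundle, row, col, bundle_sigma_um[cell.label] / um_per_px,
                  DEFAULT_BUNDLE_AMPLITUDE[cell.label])

    rng = np.random.default_rng(seed + 1)
    background = []
    placed = 0
    while placed < background_blobs:
        row = rng.uniform(0, image_size)
        col = rng.uniform(0, image_size)
        rad = np.hypot(row - center[0], col - center[1])
        spiral_r_range = (a - 1.5 * ribbon_halfwidth_um / um_per_px,
                          r_max + 1.5 * ribbon_halfwidth_um / um_per_px)
        # keep distractors clearly off the coil annulus or near its middle gap
        theta_guess = np.clip((rad - a) / b if b > 0 else 0.0, 0, 2 * np.pi * turns)
        nearest_r = a + b * theta_guess
        if spiral_r_range[0] < rad < spiral_r_range[1] and abs(rad - nearest_r) < 2.5 * ribbon_halfwidth_um / um_per_px:
            continue
        sigma_px = bundle_sigma_um[OHC] / um_per_px
        _add_blob(soma, row, col, 2.0 / um_per_px, 0.8)
        _add_blob(bundle, row, col, sigma_px, 0.9)
        half = 2 * sigma_px
        background.append(
            Detection(box=(row - half, col - half, row + half, col + half), label=OHC, score=1.0)
        )
        placed += 1

    if noise_sd > 0:
        soma = soma + rng.normal(0.0, noise_sd, soma.shape)
        bundle = bundle + rng.normal(0.0, noise_sd, bundle.shape)
    soma = np.clip(soma, 0.0, 1.0)
    bundle = np.clip(bundle, 0.0, 1.0)

    boxes = []
    for cell in survivors:
        row, col = cell.centroid
        half = 2 * bundle_sigma_um[cell.label] / um_per_px
        boxes.append(
            Detection(
                box=(
                    max(0.0, row - half), max(0.0, col - half),
                    min(float(image_size), row + half), min(float(image_size), col + half),
                ),
                label=cell.label,
                score=1.0,
            )
        )

    image = MultiChannelImage(
        pixels=np.stack([soma, bundle]),
        pixel_size_nm=pixel_size_nm,
        channel_roles={0: "cell_body", 1: "bundle"},
    )
    analytic_um = archimedean_arc_length(a, b, 2 * np.pi * turns) * um_per_px
    return SyntheticCochlea(
        image=image,
        cells=boxes,
        truth=survivors,
        dropped=dropped,
        background=background,
        centerline=centerline,
        analytic_length_um=analytic_um,
        params=dict(
            turns=turns, a=a, b=b, pixel_size_nm=pixel_size_nm, seed=seed,
            noise_sd=noise_sd, background_blobs=background_blobs,
            dropout_fraction=dropout_fraction, ihc_spacing_um=ihc_spacing_um,
            ohc_spacing_um=ohc_spacing_um, greenwood_species=greenwood.species,
        ),
    )


def spiral_point_cloud(
    turns: float,
    a: float,
    b: float,
    n_points: int = 400,
    radial_noise_frac: float = 0.05,
    seed: int = 0,
) -> tuple:
    """Noisy polar samples of an Archimedean spiral, plus its exact length.

    Points are uniform in theta with multiplicative radial noise (s.d. a
    fraction of the local radius) — a desk-scale stand-in for the
    thresholded cell-body ribbon. Returns ``(points_rowcol, exact_length_px,
    center)`` where the apex (tight inner curl) is the theta = 0 end.
    """
    rng = np.random.default_rng(seed)
    theta = np.sort(rng.uniform(0.0, 2 * np.pi * turns, n_points))
    r = a + b * theta
    r_noisy = r * (1.0 + radial_noise_frac * rng.standard_normal(n_points))
    extent = r.max() * 1.2 + 10
    center = (extent, extent)
    rows = center[0] + r_noisy * np.sin(theta)
    cols = center[1] + r_noisy * np.cos(theta)
    exact = archimedean_arc_length(a, b, 2 * np.pi * turns)
    return np.column_stack([rows, cols]), exact, center
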