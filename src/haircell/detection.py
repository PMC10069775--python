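"""Candidate hair-cell detection.

Every backend satisfies one contract: given a normalized tile, return a
list of :class:`Detection` (box + IHC/OHC label + confidence) in tile-local
pixel coordinates. Downstream stages (merging, path estimation, frequency
assignment) consume only this contract, so backends are interchangeable.

Two backends ship here:

* :func:`reference_detect` — a deterministic blob detector tuned to the
  synthetic generator's rendering (smoothed bundle-channel peaks; the
  IHC/OHC label comes from the soma-channel footprint, inner hair cells
  having larger, brighter somata than outer hair cells).
* :func:`learned_detect` — an adapter for a trained two-stage region-proposal
  detector loaded from user-supplied weights. Training such a detector is
  out of scope here; without a usable weights file the adapter raises a
  configuration error pointing at the reference backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from .errors import ConfigurationError, InputError

IHC = "IHC"
OHC = "OHC"
LABELS = (IHC, OHC)


@dataclass(frozen=True)
class Detection:
    """One candidate cell.

    box is (row0, col0, row1, col1) in float pixels with row0 < row1 and
    col0 < col1; score lies in [0, 1]; tile_index records provenance and
    cell_id is assigned after merging.
    """

    box: tuple
    label: str
    score: float
    tile_index: Optional[int] = None
    cell_id: Optional[int] = None

    def __post_init__(self):
        r0, c0, r1, c1 = self.box
        if not (r1 > r0 and c1 > c0):
            raise InputError(f"degenerate detection box {self.box}")
        if not (0.0 <= self.score <= 1.0):
            raise InputError(f"score must be in [0, 1]; got {self.score}")
        if self.label not in LABELS:
            raise InputError(f"label must be one of {LABELS}; got {self.label!r}")

    @property
    def centroid(self) -> tuple:
        r0, c0, r1, c1 = self.box
        return ((r0 + r1) / 2.0, (c0 + c1) / 2.0)

    @property
    def area(self) -> float:
        r0, c0, r1, c1 = self.box
        return (r1 - r0) * (c1 - c0)


def reference_detect(
    tile_pixels: np.ndarray,
    blob_sigma_px: float = 1.5,
    min_peak: float = 0.2,
    bundle_channel: int = -1,
    soma_channel: int = 0,
    soma_threshold: float = 0.5,
    ihc_area_cutoff_px: float = 20.0,
) -> list:
    """Deterministic reference detector for synthetic fixtures.

    Local maxima of the Gaussian-smoothed bundle channel above *min_peak*
    become detections with a square box of side ``4 * blob_sigma_px``
    centred on the peak and score equal to the smoothed peak height. The
    class label is read from the cell-body channel: the count of
    supra-threshold soma pixels inside the box exceeds *ihc_area_cutoff_px*
    for the larger, brighter IHC somata.
    """
    px = np.asarray(tile_pixels, dtype=np.float64)
    if px.ndim == 2:
        px = px[None]
    bundle = px[bundle_channel]
    soma = px[soma_channel] if px.shape[0] > 1 else bundle
    smoothed = gaussian_filter(bundle, sigma=blob_sigma_px)
    half = 2.0 * blob_sigma_px
    min_distance = max(1, int(round(blob_sigma_px)))
    peaks = peak_local_max(
        smoothed, min_distance=min_distance, threshold_abs=min_peak, exclude_border=False
    )
    h, w = bundle.shape
    soma_supra = soma > soma_threshold
    dets = []
    for r, c in peaks:
        r0, c0 = max(0.0, r - half), max(0.0, c - half)
        r1, c1 = min(float(h), r + half), min(float(w), c + half)
        if r1 <= r0 or c1 <= c0:
            continue
        footprint = soma_supra[int(np.floor(r0)) : int(np.ceil(r1)), int(np.floor(c0)) : int(np.ceil(c1))]
        label = IHC if footprint.sum() > ihc_area_cutoff_px else OHC
        score = float(np.clip(smoothed[r, c], 0.0, 1.0))
        dets.append(Detection(box=(r0, c0, r1, c1), label=label, score=score))
    return dets


@dataclass
class ReferenceDetector:
    """Backend wrapper around :func:`reference_detect` (pure given config)."""

    blob_sigma_px: float = 1.5
    min_peak: float = 0.2
    bundle_channel: int = -1
    soma_channel: int = 0
    soma_threshold: float = 0.5
    ihc_area_cutoff_px: float = 20.0
    name: str = field(default="reference", init=False)

    def detect(self, tile_pixels: np.ndarray) -> list:
        return reference_detect(
            tile_pixels,
            blob_sigma_px=self.blob_sigma_px,
            min_peak=self.min_peak,
            bundle_channel=self.bundle_channel,
            soma_channel=self.soma_channel,
            soma_threshold=self.soma_threshold,
            ihc_area_cutoff_px=self.ihc_area_cutoff_px,
        )


def load_learned_backend(weights_path):
    """Load a trained two-stage detector from a weights file.

    Requires torch/torchvision and a compatible checkpoint; otherwise a
    :class:`ConfigurationError` explains how to fall back to the reference
    detector.
    """
    from pathlib import Path

    if weights_path is None or not Path(weights_path).exists():
        raise ConfigurationError(
            f"weights file not found: {weights_path!r}; "
            "supply trained weights or use the reference detector (--backend reference)"
        )
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise ConfigurationError(
            "the learned backend requires torch/torchvision; "
            "install them or use the reference detector (--backend reference)"
        ) from exc
    try:
        model = torch.load(weights_path, map_location="cpu")
    except Exception as exc:
        raise ConfigurationError(
            f"could not load weights from {weights_path}: {exc}; "
            "use the reference detector (--backend reference)"
        ) from exc
    return LearnedDetector(model=model)


@dataclass
class LearnedDetector:
    """Adapter presenting a trained detector through the backend contract."""

    model: object
    name: str = field(default="learned", init=False)

    def detect(self, tile_pixels: np.ndarray) -> list:
        return learned_detect(tile_pixels, self.model)


def learned_detect(tile_pixels: np.ndarray, model_handle) -> list:
    """Run a loaded two-stage detector on one tile.

    Returns unthresholded boxes/labels/scores in tile-local coordinates;
    confidence rejection and NMS happen later, in the merge stage.
    """
    if model_handle is None:
        raise ConfigurationError(
            "no model loaded; use load_learned_backend() or the reference detector"
        )
    import torch

    px = np.asarray(tile_pixels, dtype=np.float32)
    if px.ndim == 2:
        px = px[None]
    model_handle.eval()
    with torch.no_grad():
        out = model_handle([torch.from_numpy(px)])[0]
    h, w = px.shape[-2:]
    dets = []
    for (x0, y0, x1, y1), lab, sc in zip(
        out["boxes"].numpy(), out["labels"].numpy(), out["scores"].numpy()
    ):
        box = (
            float(np.clip(y0, 0, h)),
            float(np.clip(x0, 0, w)),
            float(np.clip(y1, 0, h)),
            float(np.clip(x1, 0, w)),
        )
        dets.append(
            Detection(box=box, label=OHC if int(lab) == 2 else IHC, score=float(np.clip(sc, 0, 1)))
        )
    return dets
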