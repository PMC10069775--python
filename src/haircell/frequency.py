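"""Tonotopic frequency assignment and cochleograms.

Position along the cochlea maps to best frequency through the Greenwood
function

    F(x) = A * (10**(a*x) - k)   [Hz]

where ``x`` is the fractional distance from the apex (x = 0 apex, lowest
frequency; x = 1 base, highest). The constants are species-specific;
presets carry the standard literature values and every one can be
overridden. Frequencies are reported in kHz.

Cochleograms are per-class histograms of cell counts over percent-length
bins (1% of total cochlear length by default), anchored at the apex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InputError


@dataclass(frozen=True)
class GreenwoodParams:
    """Greenwood constants: F(x) = A * (10**(a*x) - k) Hz, x in [0, 1] from apex."""

    A: float
    a: float
    k: float
    species: str = "custom"

    def __post_init__(self):
        if self.A <= 0 or self.a <= 0:
            raise ConfigurationError("Greenwood A and a must be positive")
        if not (0 <= self.k < 10 ** self.a):
            raise ConfigurationError("Greenwood k must satisfy 0 <= k < 10**a")


#: Species presets (standard literature constants; override freely).
#: mouse: 9.8 kHz scale, a=0.92, k=0.68 — Greenwood-form mouse place map.
#: human: 165.4 Hz, a=2.1, k=0.88 — classic human fit.
#: guinea_pig: 350 Hz, a=2.1, k=0.85.
PRESETS = {
    "mouse": GreenwoodParams(A=9800.0, a=0.92, k=0.68, species="mouse"),
    "human": GreenwoodParams(A=165.4, a=2.1, k=0.88, species="human"),
    "guinea_pig": GreenwoodParams(A=350.0, a=2.1, k=0.85, species="guinea_pig"),
}

DEFAULT_SPECIES = "mouse"
DEFAULT_BIN_SIZE_PERCENT = 1.0


def get_params(species: str = DEFAULT_SPECIES) -> GreenwoodParams:
    try:
        return PRESETS[species]
    except KeyError:
        raise ConfigurationError(
            f"unknown species {species!r}; presets: {sorted(PRESETS)}"
        ) from None


def greenwood_frequency(x_fraction_from_apex, params: GreenwoodParams) -> np.ndarray | float:
    """Best frequency (kHz) at fractional distance x from the apex."""
    x = np.asarray(x_fraction_from_apex, dtype=np.float64)
    if np.any(x < 0) or np.any(x > 1):
        raise InputError("x_fraction_from_apex must lie in [0, 1]")
    f_khz = params.A * (10.0 ** (params.a * x) - params.k) / 1000.0
    return float(f_khz) if np.isscalar(x_fraction_from_apex) else f_khz


def greenwood_position(frequency_khz, params: GreenwoodParams) -> np.ndarray | float:
    """Inverse map: fractional distance from apex for a best frequency (kHz)."""
    f_hz = np.asarray(frequency_khz, dtype=np.float64) * 1000.0
    arg = f_hz / params.A + params.k
    if np.any(arg <= 0):
        raise InputError("frequency outside the Greenwood range")
    x = np.log10(arg) / params.a
    return float(x) if np.isscalar(frequency_khz) else x


def octave_error(f_pred, f_ref) -> np.ndarray | float:
    """|log2(f_pred / f_ref)| — the magnitude frequency error in octaves."""
    fp = np.asarray(f_pred, dtype=np.float64)
    fr = np.asarray(f_ref, dtype=np.float64)
    if np.any(fp <= 0) or np.any(fr <= 0):
        raise InputError("frequencies must be positive")
    err = np.abs(np.log2(fp / fr))
    return float(err) if np.isscalar(f_pred) and np.isscalar(f_ref) else err


@dataclass
class CellRecord:
    """One finalized hair cell with its tonotopic assignment."""

    cell_id: int
    label: str
    centroid: tuple  # (row, col) px
    percent_from_apex: float
    distance_um_from_apex: float
    frequency_khz: float
    score: float
    box: tuple = None
    distance_to_path_um: Optional[float] = None


def assign_frequencies(projections: list, params: GreenwoodParams, total_length_um: float | None = None) -> list:
    """Turn path projections into :class:`CellRecord` rows.

    *projections* is a list of ``(detection, percent_from_apex,
    distance_to_path_um)`` triples as produced by ``project_cells``. Cells
    are ordered (and numbered from 1) by percent distance from the apex;
    when the path's total length is given, each record also carries its
    absolute arc distance from the apex in microns.
    """
    ordered = sorted(projections, key=lambda t: t[1])
    records = []
    for i, (det, percent, dist_um) in enumerate(ordered, start=1):
        records.append(
            CellRecord(
                cell_id=i,
                label=det.label,
                centroid=det.centroid,
                percent_from_apex=float(percent),
                distance_um_from_apex=(
                    float(percent) / 100.0 * total_length_um
                    if total_length_um is not None
                    else float("nan")
                ),
                frequency_khz=greenwood_frequency(percent / 100.0, params),
                score=det.score,
                box=det.box,
                distance_to_path_um=float(dist_um),
            )
        )
    return records


@dataclass
class Cochleogram:
    """Per-class cell counts over percent-of-cochlear-length bins."""

    bin_edges: np.ndarray
    counts_ihc: np.ndarray
    counts_ohc: np.ndarray
    bin_size_percent: float

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def build_cochleogram(cells: list, bin_size_percent: float = DEFAULT_BIN_SIZE_PERCENT) -> Cochleogram:
    """Histogram cell positions into [0, 100] percent-length bins.

    Bins are half-open [edge, edge + size) with the last bin closed at 100,
    anchored at the apex (0%). Counts per class always sum to the number of
    cells of that class.
    """
    if bin_size_percent <= 0:
        raise InputError("bin_size_percent must be positive")
    n_bins = int(round(100.0 / bin_size_percent))
    if abs(n_bins * bin_size_percent - 100.0) > 1e-9:
        raise InputError(f"bin size {bin_size_percent} does not divide 100%")
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    pct_ihc = [c.percent_from_apex for c in cells if c.label == "IHC"]
    pct_ohc = [c.percent_from_apex for c in cells if c.label == "OHC"]
    counts_ihc, _ = np.histogram(pct_ihc, bins=edges)
    counts_ohc, _ = np.histogram(pct_ohc, bins=edges)
    return Cochleogram(
        bin_edges=edges,
        counts_ihc=counts_ihc.astype(int),
        counts_ohc=counts_ohc.astype(int),
        bin_size_percent=float(bin_size_percent),
    )
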