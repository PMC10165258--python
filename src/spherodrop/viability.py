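"""Image-based spheroid viability scoring.

A spheroid imaged on a wide-field epifluorescence microscope integrates
signal along the optical axis, so per-pixel propidium-iodide (PI) intensity
is treated as a column integral of dead-cell signal.  The score combines:

* an Otsu threshold on the green (GFP) channel and a robust global
  threshold on the PI channel (median + 2 sigma over the full field of
  view) to build the spheroid mask;
* a per-image normalisation factor ``K`` — the PI intensity a fully dead
  pixel column would carry, estimated as mean + 2 sigma of the
  above-threshold PI pixels;
* viability = 1 − (integrated PI over the PI mask) / (K × mask area).

All standard deviations are population standard deviations (divide by n):
the pixel population is exhaustive, not a sample.  Both thresholds use a
strict ``>`` comparison, so a constant image yields an empty mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "SpheroidMask",
    "ViabilityRecord",
    "otsu_threshold",
    "pi_threshold",
    "build_mask",
    "estimate_K",
    "compute_viability",
    "measure_radius",
    "score_well",
]


@dataclass
class SpheroidMask:
    """Spheroid segmentation: overall mask (live ∪ dead) and PI-positive mask.

    ``pi`` is always a subset of ``overall``.  ``flags`` records degenerate
    conditions (empty mask, degenerate Otsu input) for downstream exclusion.
    """

    overall: np.ndarray
    pi: np.ndarray
    pixel_size: float = 1.0
    gfp_threshold: float = float("nan")
    pi_threshold: float = float("nan")
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.overall = np.asarray(self.overall, dtype=bool)
        self.pi = np.asarray(self.pi, dtype=bool) & self.overall

    @property
    def area_px(self) -> int:
        return int(self.overall.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size**2


@dataclass
class ViabilityRecord:
    """One spheroid at one timepoint."""

    anchor: str
    day: int
    viability: float
    raw_viability: float
    integrated_pi: float
    K: float
    area_px: int
    radius_um: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    def as_row(self) -> dict:
        return {
            "anchor": self.anchor,
            "day": self.day,
            "viability": self.viability,
            "raw_viability": self.raw_viability,
            "radius_um": self.radius_um,
            "area_px": self.area_px,
            "K": self.K,
            "int_pi": self.integrated_pi,
            "flags": ";".join(self.flags),
        }


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu threshold: the grey level minimising within-class intensity variance.

    Candidates are the observed grey levels; the partition is
    ``{pixels <= t}`` vs ``{pixels > t}``.  Ties resolve to the lowest
    level.  A constant image returns that constant (degenerate: with the
    strict ``>`` convention the foreground is then empty).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    values, counts = np.unique(image.ravel(), return_counts=True)
    if values.size == 1:
        return float(values[0])
    values = values.astype(np.float64)
    w = counts.astype(np.float64)
    # cumulative moments for the <=t class at every candidate t = values[i]
    cw = np.cumsum(w)
    cs = np.cumsum(w * values)
    css = np.cumsum(w * values**2)
    n = cw[-1]
    # within-class variance = w1*var1 + w2*var2 (weights sum to 1)
    lo_w = cw[:-1]
    hi_w = n - lo_w
    lo_var = css[:-1] / lo_w - (cs[:-1] / lo_w) ** 2
    hi_mean = (cs[-1] - cs[:-1]) / hi_w
    hi_var = (css[-1] - css[:-1]) / hi_w - hi_mean**2
    wcv = (lo_w * lo_var + hi_w * hi_var) / n
    return float(values[int(np.argmin(wcv))])


def pi_threshold(pi_image: np.ndarray) -> float:
    """PI positivity threshold over the complete field of view.

    threshold = median(all pixels) + 2 * population sigma(all pixels).
    The image must be the full frame, not a pre-masked crop: the median
    and sigma are meant to capture the background.
    """
    pi_image = np.asarray(pi_image, dtype=np.float64)
    return float(np.median(pi_image) + 2.0 * pi_image.std())


def estimate_K(pi_image: np.ndarray, threshold: float) -> float | None:
    """Normalisation factor K: PI intensity of a fully dead pixel column.

    K = mean + 2 * population sigma of the pixels strictly above
    ``threshold``.  Returns ``None`` when no pixel exceeds the threshold —
    the caller must then treat the well as fully viable and flag it.
    """
    pi_image = np.asarray(pi_image, dtype=np.float64)
    above = pi_image[pi_image > threshold]
    if above.size == 0:
        return None
    return float(above.mean() + 2.0 * above.std())


def build_mask(
    gfp_image: np.ndarray,
    pi_image: np.ndarray,
    pixel_size: float = 1.0,
    min_area: int = 10,
    max_fill: float = 0.45,
) -> SpheroidMask:
    """Segment the spheroid by combining a GFP mask and a PI mask.

    The overall mask is the union of ``gfp > otsu`` and ``pi > median+2σ``,
    reduced to its largest 4-connected component with holes filled; the PI
    mask is the PI-positive pixels inside it.

    Otsu always splits the histogram, even of a featureless frame; a GFP
    mask covering more than ``max_fill`` of the field of view is therefore
    treated as degenerate and dropped (a spheroid never fills the well).
    Components below ``min_area`` pixels are rejected, so an all-background
    frame yields an empty, flagged mask rather than noise specks.
    """
    gfp_image = np.asarray(gfp_image)
    pi_image = np.asarray(pi_image)
    if gfp_image.shape != pi_image.shape:
        raise ValueError(
            f"channel shapes differ: GFP {gfp_image.shape} vs PI {pi_image.shape}"
        )
    flags: list[str] = []
    t_gfp = otsu_threshold(gfp_image)
    t_pi = pi_threshold(pi_image)
    gfp_mask = gfp_image > t_gfp
    if gfp_mask.mean() > max_fill:
        flags.append("degenerate_gfp")
        gfp_mask = np.zeros_like(gfp_mask)
    pi_pos = pi_image > t_pi
    union = gfp_mask | pi_pos
    overall = np.zeros_like(union)
    if union.any():
        labels = measure.label(union, connectivity=1)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        biggest = int(sizes.argmax())
        if sizes[biggest] >= min_area:
            overall = ndimage.binary_fill_holes(labels == biggest)
    if not overall.any():
        flags.append("empty_mask")
    return SpheroidMask(
        overall=overall,
        pi=pi_pos,
        pixel_size=pixel_size,
        gfp_threshold=t_gfp,
        pi_threshold=t_pi,
        flags=tuple(flags),
    )


def compute_viability(
    pi_image: np.ndarray,
    mask: SpheroidMask,
    K: float,
    subtract_background: bool = False,
) -> tuple[float, float, float]:
    """Viability = 1 − ∫PI / (K × Area), clamped to [0, 1].

    ``∫PI`` is the raw PI intensity summed over the PI mask; ``Area`` is
    the overall-mask pixel count.  ``subtract_background`` removes the
    field-of-view median from each integrated pixel before summing (off
    by default: the formula is applied as stated).  Returns
    ``(viability, raw_unclamped, integrated_pi)`` — the raw value is kept
    for diagnostics.
    """
    if mask.area_px == 0:
        raise ValueError("no spheroid: overall mask is empty")
    if not K > 0:
        raise ValueError(f"normalisation factor K must be positive, got {K}")
    pi_image = np.asarray(pi_image, dtype=np.float64)
    vals = pi_image[mask.pi]
    if subtract_background:
        vals = np.clip(vals - np.median(pi_image), 0.0, None)
    integral = float(vals.sum())
    raw = 1.0 - integral / (K * mask.area_px)
    return float(min(1.0, max(0.0, raw))), raw, integral


def measure_radius(mask: SpheroidMask) -> float:
    """Radius (μm) of the circle with the mask's area: sqrt(area / π)."""
    if mask.area_px == 0:
        raise ValueError("empty mask has no radius")
    return math.sqrt(mask.area_um2 / math.pi)


def score_well(
    gfp_image: np.ndarray,
    pi_image: np.ndarray,
    anchor: str = "",
    day: int = 0,
    pixel_size: float = 1.0,
    min_area: int = 10,
    subtract_background: bool = False,
) -> ViabilityRecord:
    """Full viability readout of one well: mask, K, viability, radius.

    Degenerate cases are flagged, never raised: an empty overall mask gives
    a NaN viability (``empty_mask``); an empty PI-positive set gives
    viability 1 (``no_pi_signal`` — K is then undefined and there is no
    evidence of death).
    """
    mask = build_mask(gfp_image, pi_image, pixel_size=pixel_size, min_area=min_area)
    flags = list(mask.flags)
    if mask.area_px == 0:
        return ViabilityRecord(
            anchor, day, float("nan"), float("nan"), 0.0, float("nan"), 0, float("nan"),
            tuple(flags),
        )
    radius = measure_radius(mask)
    K = estimate_K(pi_image, mask.pi_threshold)
    if K is None or not mask.pi.any():
        flags.append("no_pi_signal")
        return ViabilityRecord(
            anchor, day, 1.0, 1.0, 0.0, float("nan"), mask.area_px, radius, tuple(flags)
        )
    viability, raw, integral = compute_viability(
        pi_image, mask, K, subtract_background=subtract_background
    )
    if raw < 0.0 or raw > 1.0:
        flags.append("clipped")
    return ViabilityRecord(
        anchor, day, viability, raw, integral, K, mask.area_px, radius, tuple(flags)
    )
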