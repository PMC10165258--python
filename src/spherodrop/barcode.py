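"""Fluorescent barcode decoding: dye intensity → drug concentration level.

Each secondary droplet carries a drug dilution together with a barcode dye
at a matched dilution, so the dye fluorescence read on the chip encodes the
drug concentration.  Calibration is a least-squares line in log10(intensity)
vs log10(concentration); decoding assigns the level whose predicted
intensity is nearest in log space, with the margin to the runner-up kept
for audit.  A green control dye marks no-drug control droplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "ConditionAssignment",
    "DecodeResult",
    "fit_calibration",
    "decode_level",
    "classify_condition",
    "read_calibration_csv",
]


@dataclass
class CalibrationCurve:
    """Monotone log–log calibration of one dye on one channel."""

    dye: str
    channel: str
    concentrations: np.ndarray
    intensities: np.ndarray
    slope: float
    intercept: float          # log10(intensity) at 1 μM
    residuals: np.ndarray

    @classmethod
    def fit(
        cls,
        dye: str,
        channel: str,
        concentrations: np.ndarray,
        intensities: np.ndarray,
    ) -> "CalibrationCurve":
        conc = np.asarray(concentrations, dtype=np.float64)
        inten = np.asarray(intensities, dtype=np.float64)
        if conc.size < 2:
            raise ValueError("calibration needs at least 2 points")
        if np.any(conc <= 0) or np.any(inten <= 0):
            raise ValueError("calibration points must be strictly positive")
        order = np.argsort(conc)
        conc, inten = conc[order], inten[order]
        if np.any(np.diff(conc) <= 0):
            raise ValueError("duplicate concentrations in calibration")
        if np.any(np.diff(inten) <= 0):
            raise ValueError(
                f"non-monotone calibration for dye {dye!r}: intensity must "
                "increase with concentration (dye does not provide a "
                "consistent calibration range)"
            )
        lc, li = np.log10(conc), np.log10(inten)
        res = stats.linregress(lc, li)
        residuals = li - (res.intercept + res.slope * lc)
        return cls(dye, channel, conc, inten, float(res.slope),
                   float(res.intercept), residuals)

    def predict_intensity(self, concentration) -> np.ndarray | float:
        c = np.asarray(concentration, dtype=np.float64)
        out = 10.0 ** (self.intercept + self.slope * np.log10(c))
        return float(out) if out.ndim == 0 else out

    @property
    def intensity_range(self) -> tuple[float, float]:
        return float(self.intensities[0]), float(self.intensities[-1])


def fit_calibration(
    points: pd.DataFrame | None = None,
    dye: str = "",
    channel: str = "",
    concentrations=None,
    intensities=None,
) -> CalibrationCurve:
    """Fit one dye's calibration from a points table or raw arrays.

    ``points`` follows the calibration CSV layout
    (``dye,channel,concentration_uM,intensity``); alternatively pass the
    arrays directly.
    """
    if points is not None:
        dye = dye or str(points["dye"].iloc[0])
        channel = channel or str(points["channel"].iloc[0])
        concentrations = points["concentration_uM"].to_numpy()
        intensities = points["intensity"].to_numpy()
    return CalibrationCurve.fit(dye, channel, concentrations, intensities)


def read_calibration_csv(path) -> dict[str, CalibrationCurve]:
    """Read a calibration CSV and fit one curve per channel."""
    table = pd.read_csv(path)
    return {
        str(channel): fit_calibration(group)
        for channel, group in table.groupby("channel")
    }


@dataclass
class DecodeResult:
    """Decoded level for one dye intensity.

    ``level`` is 1-based into the concentration list; 0 means blank
    (zero concentration / control axis).  ``margin`` is the log10 distance
    from the intensity to the decision boundary with the runner-up level:
    half the excess of the runner-up's distance over the winner's.  An
    intensity sitting exactly on a predicted level has margin = half the
    inter-level log gap; a tie has margin 0.
    """

    level: int
    margin: float
    flags: tuple[str, ...] = ()


def decode_level(
    intensity: float,
    curve: CalibrationCurve,
    levels,
    blank_intensity: float = 10.0,
    blank_sd: float = 0.0,
    out_of_range_factor: float = 3.0,
) -> DecodeResult:
    """Assign an intensity to the nearest concentration level in log space.

    Intensities at or below ``blank_intensity + 3·blank_sd`` decode to the
    blank level 0.  Ties between adjacent levels resolve to the lower
    concentration (conservative toward under-dosing).  Intensities beyond
    ``out_of_range_factor`` times the calibrated range are flagged.
    """
    levels = np.asarray(levels, dtype=np.float64)
    if levels.size == 0:
        return DecodeResult(0, np.inf)
    if np.any(np.diff(levels) <= 0) or np.any(levels <= 0):
        raise ValueError("levels must be strictly positive and increasing")
    if intensity <= 0:
        raise ValueError(f"intensity must be positive, got {intensity}")
    if intensity <= blank_intensity + 3.0 * blank_sd:
        return DecodeResult(0, np.inf)
    predicted = curve.predict_intensity(levels)
    dist = np.abs(np.log10(intensity) - np.log10(predicted))
    # argmin returns the first minimum → ties resolve to the lower level
    best = int(np.argmin(dist))
    if dist.size == 1:
        margin = np.inf
    else:
        margin = float(np.partition(dist, 1)[1] - dist[best]) / 2.0
    flags: tuple[str, ...] = ()
    lo, hi = curve.intensity_range
    if intensity > hi * out_of_range_factor or intensity < lo / out_of_range_factor:
        flags = ("out_of_range",)
    return DecodeResult(best + 1, margin, flags)


@dataclass
class ConditionAssignment:
    """Decoded condition of one anchor: grid cell, control flags, audit data."""

    anchor: str
    level_a: int
    level_b: int
    conc_a: float
    conc_b: float
    control_a: bool
    control_b: bool
    double_negative: bool
    intensities: dict[str, float] = field(default_factory=dict)
    margin_a: float = np.inf
    margin_b: float = np.inf
    flags: tuple[str, ...] = ()

    @property
    def ambiguous(self) -> bool:
        return "ambiguous" in self.flags

    def as_row(self) -> dict:
        return {
            "anchor": self.anchor,
            "level_a": self.level_a, "level_b": self.level_b,
            "conc_a": self.conc_a, "conc_b": self.conc_b,
            "control_a": self.control_a, "control_b": self.control_b,
            "double_negative": self.double_negative,
            "margin_a": self.margin_a, "margin_b": self.margin_b,
            "flags": ";".join(self.flags),
        }


def classify_condition(
    intensities: dict[str, float],
    curve_a: CalibrationCurve,
    curve_b: CalibrationCurve,
    levels_a,
    levels_b,
    anchor: str = "",
    blank_intensity: float = 10.0,
    blank_sd: float = 0.0,
    green_threshold: float | None = None,
) -> ConditionAssignment:
    """Classify one anchor from its BLUE / FARRED / GREEN intensities.

    BLUE decodes drug A, FARRED drug B.  A blank drug axis is recorded as
    zero concentration (some droplets fuse with a single drug droplet).
    GREEN above threshold marks a control droplet: with both drug axes
    blank this is the double-negative control; with a drug dye also high
    the well is flagged ambiguous and excluded from aggregation.
    """
    for ch in ("BLUE", "FARRED", "GREEN"):
        if ch not in intensities:
            raise ValueError(f"missing channel {ch!r} for anchor {anchor!r}")
    if green_threshold is None:
        green_threshold = 10.0 * max(blank_intensity, 1e-12)
    dec_a = decode_level(intensities["BLUE"], curve_a, levels_a,
                         blank_intensity, blank_sd)
    dec_b = decode_level(intensities["FARRED"], curve_b, levels_b,
                         blank_intensity, blank_sd)
    green_on = intensities["GREEN"] > green_threshold
    flags = tuple(f"a_{f}" for f in dec_a.flags) + tuple(f"b_{f}" for f in dec_b.flags)
    if green_on and (dec_a.level > 0 or dec_b.level > 0):
        flags = flags + ("ambiguous",)
    levels_a = np.asarray(levels_a, dtype=np.float64)
    levels_b = np.asarray(levels_b, dtype=np.float64)
    c_a = 0.0 if dec_a.level == 0 else float(levels_a[dec_a.level - 1])
    c_b = 0.0 if dec_b.level == 0 else float(levels_b[dec_b.level - 1])
    return ConditionAssignment(
        anchor=anchor,
        level_a=dec_a.level, level_b=dec_b.level,
        conc_a=c_a, conc_b=c_b,
        control_a=dec_a.level == 0, control_b=dec_b.level == 0,
        double_negative=dec_a.level == 0 and dec_b.level == 0 and green_on,
        intensities=dict(intensities),
        margin_a=dec_a.margin, margin_b=dec_b.margin,
        flags=flags,
    )
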