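"""Synthetic chip experiment with known ground truth.

Emulates the anchored-droplet spheroid screen at desk scale: disk-shaped
spheroids with a live (GFP) body and a dead (PI-positive) pixel fraction on
a noisy background; fluorescent barcode intensities tied to drug dilution
through a calibration curve; and a dose–response surface with Hill-type
single-drug curves, a tunable Loewe interaction term and per-drug onset
kinetics over days.  Every stochastic draw comes from one seeded
``numpy.random.Generator`` passed explicitly — no global state — so a fixed
seed reproduces images and tables byte for byte.

The surface and noise models are configurable stand-ins, not claims about
any particular cell line's biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .barcode import CalibrationCurve

__all__ = [
    "SpheroidSpec",
    "ResponseModel",
    "ChipDesign",
    "SimulatedChip",
    "render_well",
    "simulate_viability",
    "simulate_chip",
    "library_accounting",
    "default_calibrations",
    "write_chip",
    "load_chip",
]

CHANNELS = ("BF", "GFP", "PI", "BLUE", "FARRED", "GREEN")
DEAD_GEOMETRIES = ("uniform", "core", "speckle")


@dataclass
class SpheroidSpec:
    """Geometry and photometry of one rendered spheroid.

    ``dead_intensity_scale`` sets the PI plateau of a dead pixel column as a
    multiple of the live-pixel PI background, so the rendered dynamic range
    scales with ``background``.
    """

    center: tuple[float, float] = (64.0, 64.0)  # (row, col) pixels
    radius: float = 25.0                        # μm
    dead_fraction: float = 0.0
    dead_geometry: str = "uniform"
    live_intensity: float = 900.0               # counts (GFP plateau)
    dead_intensity_scale: float = 8.0
    background: float = 100.0                   # counts
    noise_sd: float = 2.0                       # counts, additive Gaussian
    pixel_size: float = 1.0                     # μm / pixel
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError(f"dead_fraction must be in [0,1], got {self.dead_fraction}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dead_geometry not in DEAD_GEOMETRIES:
            raise ValueError(
                f"dead_geometry must be one of {DEAD_GEOMETRIES}, got {self.dead_geometry!r}"
            )

    @property
    def radius_px(self) -> float:
        return self.radius / self.pixel_size


@dataclass
class ResponseModel:
    """Dose–response surface with interaction and onset kinetics.

    Effective single-drug doses are x = cA/IC50_A(day), y = cB/IC50_B(day).
    The combined effective dose is

        U = max(x, y, x + y + alpha * sqrt(x*y))

    and viability = bottom + (top − bottom) / (1 + U^hill).  alpha = 0 is
    exactly Loewe-additive (U = x + y); alpha > 0 synergy, alpha < 0
    antagonism.  The max() guard keeps the surface monotone non-increasing
    in each concentration for alpha >= −1: a combination is never less
    potent than its stronger component alone.

    The per-day IC50 decays as IC50(day) = ic50 * (1 + inflation *
    exp(−kinetics * day)), emulating slower-acting drugs whose apparent
    IC50 falls over the assay days.  A drug whose exposure starts on day
    ``start`` contributes nothing before that day, and its clock starts
    then (sequential protocols).
    """

    ic50_a: float
    ic50_b: float
    hill: float = 1.5
    top: float = 1.0
    bottom: float = 0.0
    alpha: float = 0.0
    kinetics_a: float = 1.0
    kinetics_b: float = 1.0
    inflation_a: float = 0.0
    inflation_b: float = 0.0

    def __post_init__(self) -> None:
        if self.ic50_a <= 0 or self.ic50_b <= 0:
            raise ValueError("IC50s must be positive")
        if self.hill <= 0:
            raise ValueError("hill must be positive")
        if self.top < self.bottom:
            raise ValueError(f"top ({self.top}) < bottom ({self.bottom})")
        if self.alpha < -2.0:
            raise ValueError("alpha < -2 gives a negative effective dose")

    def ic50_at(self, drug: str, day: float, start: float = 0.0) -> float:
        """Apparent IC50 of one drug at a given day; inf before exposure."""
        if day < start:
            return math.inf
        t = day - start
        if drug == "A":
            return self.ic50_a * (1.0 + self.inflation_a * math.exp(-self.kinetics_a * t))
        if drug == "B":
            return self.ic50_b * (1.0 + self.inflation_b * math.exp(-self.kinetics_b * t))
        raise ValueError(f"unknown drug {drug!r}")


def simulate_viability(
    c_a: float,
    c_b: float,
    model: ResponseModel,
    day: float,
    start_a: float = 0.0,
    start_b: float = 0.0,
) -> float:
    """Ground-truth viability at one concentration pair and day."""
    if c_a < 0 or c_b < 0:
        raise ValueError("concentrations must be non-negative")
    if day < 0:
        raise ValueError("day must be non-negative")
    ic_a = model.ic50_at("A", day, start_a)
    ic_b = model.ic50_at("B", day, start_b)
    x = 0.0 if math.isinf(ic_a) else c_a / ic_a
    y = 0.0 if math.isinf(ic_b) else c_b / ic_b
    u = max(x, y, x + y + model.alpha * math.sqrt(x * y))
    if u == 0.0:
        return model.top
    return model.bottom + (model.top - model.bottom) / (1.0 + u**model.hill)


def _disk_pixels(spec: SpheroidSpec, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r_px = spec.radius_px
    cr, cc = spec.center
    if (cr - r_px < 0 or cc - r_px < 0
            or cr + r_px > shape[0] - 1 or cc + r_px > shape[1] - 1):
        raise ValueError(
            f"spheroid (center={spec.center}, radius={r_px:.1f} px) extends "
            f"beyond image bounds {shape}"
        )
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    dist2 = (rows - cr) ** 2 + (cols - cc) ** 2
    disk = dist2 <= r_px**2
    return disk, dist2, r_px


def render_well(
    spec: SpheroidSpec,
    seed: int | np.random.Generator = 0,
    shape: tuple[int, int] = (128, 128),
) -> tuple[dict[str, np.ndarray], dict]:
    """Render one well's GFP and PI channels plus ground truth.

    GFP: disk at ``live_intensity`` over background.  PI: dead pixels at
    the dead plateau, everything else at background.  Dead pixels follow
    ``dead_geometry``: ``uniform`` scatters exactly round(f·n) pixels,
    ``speckle`` draws per-pixel Bernoulli(f), ``core`` fills a concentric
    disk of area fraction f.  Gaussian read noise is added and values are
    clipped to the bit depth.

    Returns ``(channels, truth)`` with truth holding the viability
    (1 − dead_fraction), the dead-pixel mask and the disk mask.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    disk, dist2, r_px = _disk_pixels(spec, shape)
    n_disk = int(disk.sum())

    dead = np.zeros(shape, dtype=bool)
    f = spec.dead_fraction
    if f > 0:
        if spec.dead_geometry == "core":
            dead = disk & (dist2 <= f * r_px**2)
        elif spec.dead_geometry == "speckle":
            dead = disk & (rng.random(shape) < f)
        else:  # uniform: exact count, scattered
            n_dead = int(round(f * n_disk))
            flat = np.flatnonzero(disk)
            chosen = rng.choice(flat, size=n_dead, replace=False)
            dead.ravel()[chosen] = True

    gfp = np.full(shape, spec.background, dtype=np.float64)
    gfp[disk] = spec.live_intensity
    pi = np.full(shape, spec.background, dtype=np.float64)
    pi[dead] = spec.dead_intensity_scale * spec.background
    if spec.noise_sd > 0:
        gfp += rng.normal(0.0, spec.noise_sd, shape)
        pi += rng.normal(0.0, spec.noise_sd, shape)
    top = float(2**spec.bit_depth - 1)
    channels = {
        "GFP": np.clip(gfp, 0.0, top),
        "PI": np.clip(pi, 0.0, top),
        "BF": np.full(shape, spec.background),  # flat placeholder
    }
    truth = {
        "viability": 1.0 - f,
        "dead_fraction": f,
        "dead_mask": dead,
        "disk_mask": disk,
        "n_disk_px": n_disk,
    }
    return channels, truth


@dataclass
class ChipDesign:
    """Layout of one chip: condition grid, concentration levels, anchors.

    Level index 0 on an axis is the zero-concentration control; levels
    1..n map to log-spaced concentrations between ``conc_*`` bounds
    (inclusive).  Every anchor receives exactly one condition; all
    (n_levels_a+1) × (n_levels_b+1) grid cells are covered when the anchor
    count allows, extra anchors cycle through the cells as replicates.
    """

    n_levels_a: int = 6
    n_levels_b: int = 7
    conc_a: tuple[float, float] = (0.01, 10.0)   # μM (min, max)
    conc_b: tuple[float, float] = (0.03, 30.0)   # μM
    n_anchors: int = 80
    n_cols: int = 8
    drug_a: str = "etoposide"
    drug_b: str = "cisplatin"

    def __post_init__(self) -> None:
        if self.n_levels_a < 0 or self.n_levels_b < 0:
            raise ValueError("level counts must be >= 0")
        for lo, hi in (self.conc_a, self.conc_b):
            if lo <= 0 or hi <= lo:
                raise ValueError("concentration ranges must be positive and increasing")

    def _levels(self, bounds: tuple[float, float], n: int) -> np.ndarray:
        if n == 0:
            return np.array([])
        if n == 1:
            return np.array([bounds[1]])
        return np.logspace(math.log10(bounds[0]), math.log10(bounds[1]), n)

    @property
    def levels_a(self) -> np.ndarray:
        return self._levels(self.conc_a, self.n_levels_a)

    @property
    def levels_b(self) -> np.ndarray:
        return self._levels(self.conc_b, self.n_levels_b)

    @property
    def n_conditions(self) -> int:
        return (self.n_levels_a + 1) * (self.n_levels_b + 1)

    def anchor_ids(self) -> list[str]:
        return [f"{i // self.n_cols}-{i % self.n_cols}" for i in range(self.n_anchors)]

    def assign_conditions(self, rng: np.random.Generator) -> list[tuple[int, int]]:
        """Randomised anchor → (level_a, level_b) assignment covering all cells."""
        cells = [(a, b) for a in range(self.n_levels_a + 1)
                 for b in range(self.n_levels_b + 1)]
        if len(cells) > self.n_anchors:
            raise ValueError(
                f"{len(cells)} conditions but only {self.n_anchors} anchors"
            )
        assignment = [cells[i % len(cells)] for i in range(self.n_anchors)]
        order = rng.permutation(self.n_anchors)
        return [assignment[i] for i in order]


def default_calibrations(
    blue_base: float = 4000.0, farred_base: float = 3500.0
) -> dict[str, CalibrationCurve]:
    """Proportional dye calibrations over 3 decades (intensity = a·conc).

    The bases put the lowest decoded level (0.01 μM) well above the blank
    autofluorescence floor and the highest (10 μM) inside 16-bit range.
    """
    conc = np.logspace(-2, 1, 7)
    return {
        "BLUE": CalibrationCurve.fit("blue-dye", "BLUE", conc, blue_base * conc),
        "FARRED": CalibrationCurve.fit("farred-dye", "FARRED", conc, farred_base * conc),
    }


@dataclass
class SimulatedChip:
    """Images plus ground truth for one simulated chip."""

    design: ChipDesign
    truth: pd.DataFrame                      # one row per anchor per day
    images: dict[tuple[str, int], dict[str, np.ndarray]] = field(repr=False, default_factory=dict)
    barcodes: pd.DataFrame | None = None     # one row per anchor
    days: tuple[int, ...] = ()


def simulate_chip(
    design: ChipDesign,
    model: ResponseModel,
    calibrations: dict[str, CalibrationCurve] | None = None,
    days: list[int] = (0, 1, 2, 3),
    seed: int = 0,
    barcode_sigma: float = 0.05,
    image_noise_sd: float = 2.0,
    start_a: float = 0.0,
    start_b: float = 0.0,
    shape: tuple[int, int] = (96, 96),
    radius_um: float = 22.0,
    blank_intensity: float = 10.0,
    green_intensity: float = 4000.0,
    spec: SpheroidSpec | None = None,
) -> SimulatedChip:
    """Simulate a full chip: barcoded conditions, per-day well images, truth.

    Barcode intensities follow the calibration mapping with multiplicative
    log-normal noise (``barcode_sigma`` is the sigma of the log); a blank
    axis sits at ``blank_intensity``; double-negative controls carry the
    green control dye.  Each well's PI/GFP images are rendered from the
    response surface's ground-truth viability, converted to a dead pixel
    fraction.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    calibrations = calibrations or default_calibrations()
    base = spec or SpheroidSpec(
        center=(shape[0] / 2, shape[1] / 2), radius=radius_um, noise_sd=image_noise_sd
    )
    assignment = design.assign_conditions(rng)
    anchors = design.anchor_ids()
    levels_a, levels_b = design.levels_a, design.levels_b

    def noisy(x: float) -> float:
        if barcode_sigma <= 0:
            return x
        return float(x * np.exp(rng.normal(0.0, barcode_sigma)))

    bc_rows = []
    for anchor, (la, lb) in zip(anchors, assignment):
        c_a = 0.0 if la == 0 else float(levels_a[la - 1])
        c_b = 0.0 if lb == 0 else float(levels_b[lb - 1])
        blue = noisy(blank_intensity if la == 0
                     else calibrations["BLUE"].predict_intensity(c_a))
        farred = noisy(blank_intensity if lb == 0
                       else calibrations["FARRED"].predict_intensity(c_b))
        green = noisy(green_intensity if (la == 0 and lb == 0) else blank_intensity)
        bc_rows.append({
            "anchor": anchor, "level_a": la, "level_b": lb,
            "conc_a": c_a, "conc_b": c_b,
            "BLUE": blue, "FARRED": farred, "GREEN": green,
        })
    barcodes = pd.DataFrame(bc_rows)

    images: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    truth_rows = []
    for row in bc_rows:
        for day in days:
            v = simulate_viability(row["conc_a"], row["conc_b"], model, day,
                                   start_a=start_a, start_b=start_b)
            f = float(min(1.0, max(0.0, 1.0 - v)))
            well_spec = SpheroidSpec(
                center=base.center, radius=base.radius, dead_fraction=f,
                dead_geometry=base.dead_geometry,
                live_intensity=base.live_intensity,
                dead_intensity_scale=base.dead_intensity_scale,
                background=base.background, noise_sd=base.noise_sd,
                pixel_size=base.pixel_size, bit_depth=base.bit_depth,
            )
            channels, _ = render_well(well_spec, seed=rng, shape=shape)
            for dye in ("BLUE", "FARRED", "GREEN"):
                channels[dye] = np.full(shape, row[dye])
            images[(row["anchor"], day)] = channels
            truth_rows.append({
                "anchor": row["anchor"], "day": day,
                "level_a": row["level_a"], "level_b": row["level_b"],
                "conc_a": row["conc_a"], "conc_b": row["conc_b"],
                "viability_true": v, "dead_fraction": f,
            })
    truth = pd.DataFrame(truth_rows)
    return SimulatedChip(design=design, truth=truth, images=images,
                         barcodes=barcodes, days=tuple(days))


def library_accounting(
    n_concentrations: int, plug_volume_ul: float, droplet_volume_nl: float
) -> int:
    """Droplet count of a library: n plugs of ``plug_volume_ul`` each split
    into ``droplet_volume_nl`` droplets; count = floor(n · plug / droplet)."""
    if n_concentrations <= 0 or plug_volume_ul <= 0 or droplet_volume_nl <= 0:
        raise ValueError("all quantities must be positive")
    plug_nl = plug_volume_ul * 1000.0
    if droplet_volume_nl > plug_nl:
        raise ValueError(
            f"droplet volume {droplet_volume_nl} nL exceeds plug volume {plug_nl} nL"
        )
    return int(n_concentrations * plug_nl // droplet_volume_nl)


def write_chip(sim: SimulatedChip, outdir: str | Path, chip_index: int = 0) -> Path:
    """Write a simulated chip to disk: one grayscale TIFF per
    anchor/channel/day plus the ground-truth CSV and design YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (anchor, day), channels in sim.images.items():
        for name, img in channels.items():
            fname = f"chip{chip_index}_anchor{anchor}_d{day}_{name}.tif"
            tifffile.imwrite(outdir / fname, img.astype(np.uint16))
    sim.truth.assign(chip=chip_index).to_csv(
        outdir / f"chip{chip_index}_truth.csv", index=False
    )
    d = sim.design
    design_doc = {
        "chip": chip_index,
        "drug_a": d.drug_a, "drug_b": d.drug_b,
        "n_levels_a": d.n_levels_a, "n_levels_b": d.n_levels_b,
        "levels_a_uM": [float(x) for x in d.levels_a],
        "levels_b_uM": [float(x) for x in d.levels_b],
        "n_anchors": d.n_anchors, "days": list(sim.days),
    }
    with open(outdir / f"chip{chip_index}_design.yaml", "w") as fh:
        yaml.safe_dump(design_doc, fh)
    return outdir


def load_chip(indir: str | Path, chip_index: int = 0) -> SimulatedChip:
    """Load a written chip (TIFFs + design YAML) back into memory.

    The ground-truth CSV, if present, is attached; images are keyed by
    ``(anchor, day)`` exactly as :func:`simulate_chip` produces them.
    """
    indir = Path(indir)
    with open(indir / f"chip{chip_index}_design.yaml") as fh:
        doc = yaml.safe_load(fh)
    design = ChipDesign(
        n_levels_a=doc["n_levels_a"], n_levels_b=doc["n_levels_b"],
        conc_a=(doc["levels_a_uM"][0], doc["levels_a_uM"][-1]),
        conc_b=(doc["levels_b_uM"][0], doc["levels_b_uM"][-1]),
        n_anchors=doc["n_anchors"],
        drug_a=doc.get("drug_a", "drugA"), drug_b=doc.get("drug_b", "drugB"),
    )
    images: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    days: set[int] = set()
    prefix = f"chip{chip_index}_anchor"
    for path in sorted(indir.glob(f"{prefix}*_d*_*.tif")):
        rest = path.stem[len(prefix):]          # "{r}-{c}_d{day}_{channel}"
        anchor, day_part, channel = rest.split("_")
        day = int(day_part[1:])
        days.add(day)
        images.setdefault((anchor, day), {})[channel] = tifffile.imread(path)
    truth_path = indir / f"chip{chip_index}_truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    return SimulatedChip(design=design, truth=truth, images=images,
                         days=tuple(sorted(days)))
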