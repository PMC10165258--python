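"""End-to-end orchestration: tracking, aggregation, heatmaps, reporting.

Spheroid identity across days comes for free from the anchor array — each
droplet is held at a fixed trap position — so tracks are keyed by anchor
id, with :func:`match_anchors` available to re-establish identity between
imaging sessions that shifted the stage.  The pipeline chains barcode
decoding → per-day viability scoring → per-day heatmaps → per-day
single-drug IC50s → diagonal combined IC50 and FIC, writing CSV tables,
PNG heatmaps and a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy.spatial import cKDTree  # noqa: E402

from . import synthetic
from .barcode import CalibrationCurve, classify_condition
from .dose_response import FlatResponseError, fit_sigmoid
from .synergy import combined_ic50, compute_fic, select_diagonal
from .viability import score_well

__all__ = ["AnchorTrack", "HeatmapGrid", "RegistrationError", "match_anchors",
           "aggregate_heatmap", "count_conditions", "analyze_chip",
           "run_pipeline"]


class RegistrationError(RuntimeError):
    """Day-to-day anchor registration failed (shift beyond tolerance)."""


@dataclass
class AnchorTrack:
    """One anchor's identity-preserved history: condition plus per-day records."""

    anchor: str
    condition: dict
    records: dict[int, dict] = field(default_factory=dict)


@dataclass
class HeatmapGrid:
    """Per-condition-cell mean viability on the (level_a, level_b) grid."""

    day: int
    mean: np.ndarray     # shape (n_levels_b + 1, n_levels_a + 1), NaN = empty
    count: np.ndarray
    excluded: int = 0


def match_anchors(
    positions_t: np.ndarray,
    positions_t1: np.ndarray,
    max_shift: float = 20.0,
) -> tuple[dict[int, int], np.ndarray]:
    """Match anchor positions across two timepoints.

    Estimates a global rigid translation (median displacement of nearest
    neighbours), removes it, then keeps mutual-nearest-neighbour pairs.
    Returns ``(mapping, shift)`` where ``mapping[i] = j`` links index i at
    time t to index j at t+1; unmatched anchors are absent from the
    mapping.  Raises :class:`RegistrationError` if the estimated shift
    exceeds ``max_shift``.
    """
    p0 = np.asarray(positions_t, dtype=np.float64)
    p1 = np.asarray(positions_t1, dtype=np.float64)
    if p0.ndim != 2 or p1.ndim != 2 or p0.shape[1] != 2 or p1.shape[1] != 2:
        raise ValueError("positions must be (n, 2) arrays")
    tree1 = cKDTree(p1)
    _, nn = tree1.query(p0)
    shift = np.median(p1[nn] - p0, axis=0)
    if float(np.hypot(*shift)) > max_shift:
        raise RegistrationError(
            f"estimated shift {shift} exceeds max_shift={max_shift}"
        )
    p0s = p0 + shift
    tree1 = cKDTree(p1)
    tree0 = cKDTree(p0s)
    _, fwd = tree1.query(p0s)       # each t anchor's nearest t+1 anchor
    _, back = tree0.query(p1)       # each t+1 anchor's nearest t anchor
    mapping = {i: int(j) for i, j in enumerate(fwd) if back[j] == i}
    return mapping, shift


def count_conditions(
    n_levels_a: int, n_levels_b: int, include_controls: bool = True
) -> int:
    """Number of distinct condition cells on the checkerboard.

    With controls, each axis gains a zero level:
    (n_levels_a + 1) × (n_levels_b + 1); e.g. 6 and 7 drug levels give the
    56-condition grid of a single combinatorial run.
    """
    if n_levels_a < 0 or n_levels_b < 0:
        raise ValueError("level counts must be non-negative")
    if include_controls:
        return (n_levels_a + 1) * (n_levels_b + 1)
    return n_levels_a * n_levels_b


def aggregate_heatmap(
    records: pd.DataFrame,
    day: int,
    n_levels_a: int,
    n_levels_b: int,
) -> HeatmapGrid:
    """Per-cell arithmetic mean viability at one day.

    Flagged wells (ambiguous barcode, empty mask, failed K) are excluded
    and counted.  Empty cells hold NaN.
    """
    df = records[records["day"] == day]
    flagged = df["excluded"] if "excluded" in df else pd.Series(False, index=df.index)
    excluded = int(flagged.sum())
    df = df[~flagged]
    mean = np.full((n_levels_b + 1, n_levels_a + 1), np.nan)
    count = np.zeros((n_levels_b + 1, n_levels_a + 1), dtype=int)
    for (la, lb), grp in df.groupby(["level_a", "level_b"]):
        mean[int(lb), int(la)] = grp["viability"].mean()
        count[int(lb), int(la)] = len(grp)
    return HeatmapGrid(day=day, mean=mean, count=count, excluded=excluded)


def _plot_heatmap(grid: HeatmapGrid, design: synthetic.ChipDesign, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid.mean, origin="lower", vmin=0, vmax=1, cmap="viridis")
    ax.set_xlabel(f"{design.drug_a} level (0 = none)")
    ax.set_ylabel(f"{design.drug_b} level (0 = none)")
    ax.set_title(f"mean viability, day {grid.day}")
    fig.colorbar(im, ax=ax, label="viability")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def analyze_chip(
    sim: synthetic.SimulatedChip,
    calibrations: dict[str, CalibrationCurve],
    blank_intensity: float = 10.0,
    blank_sd: float = 0.0,
    barcode_day: int | None = None,
) -> pd.DataFrame:
    """Decode conditions and score viability for every anchor and day.

    The earliest imaged day (right after drug addition) is used only for
    barcode reading; viability is scored on the later days.  Returns one
    row per anchor per scored day with decoded condition, viability and an
    ``excluded`` flag for wells unusable downstream.
    """
    days = sorted(sim.days)
    if barcode_day is None:
        barcode_day = days[0]
    score_days = [d for d in days if d != barcode_day] or days

    anchors = sorted({a for a, _ in sim.images})
    rows = []
    for anchor in anchors:
        bc_imgs = sim.images[(anchor, barcode_day)]
        intensities = {ch: float(np.median(bc_imgs[ch]))
                       for ch in ("BLUE", "FARRED", "GREEN")}
        cond = classify_condition(
            intensities, calibrations["BLUE"], calibrations["FARRED"],
            sim.design.levels_a, sim.design.levels_b,
            anchor=anchor, blank_intensity=blank_intensity, blank_sd=blank_sd,
        )
        for day in score_days:
            imgs = sim.images[(anchor, day)]
            rec = score_well(imgs["GFP"], imgs["PI"], anchor=anchor, day=day)
            excluded = cond.ambiguous or "empty_mask" in rec.flags
            rows.append({**cond.as_row(), **rec.as_row(), "excluded": excluded})
    df = pd.DataFrame(rows).sort_values(["anchor", "day"], kind="mergesort")
    return df.reset_index(drop=True)


def _single_drug_fit(df: pd.DataFrame, axis: str, day: int, pin_top: float | None):
    """Fit one drug's dose response using its single-drug wells at one day."""
    other = "b" if axis == "a" else "a"
    sub = df[(df["day"] == day) & ~df["excluded"]
             & (df[f"level_{axis}"] >= 1) & (df[f"level_{other}"] == 0)]
    if sub.empty:
        raise FlatResponseError(f"no single-drug wells for axis {axis}")
    return fit_sigmoid(sub[f"conc_{axis}"], sub["viability"], pin_top=pin_top)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full synthetic screen: simulate → decode → score → fit → FIC.

    ``config`` is a dict or a YAML path; see the packaged example in the
    README.  Writes ``records.csv`` (per anchor per day), per-day heatmap
    CSV/PNG, ``fits.csv`` (per-day per-drug IC50s), ``fic.csv`` and
    ``manifest.json`` to ``outdir``.  Idempotent: a fixed seed and config
    give byte-identical tables.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    seed = int(config.get("seed", 0))
    n_chips = int(config.get("n_chips", 1))
    days = list(config.get("days", [0, 1, 2, 3]))
    protocol = dict(config.get("protocol", {}))
    label = protocol.get("label", "simultaneous")
    start_a = float(protocol.get("start_a", 0.0))
    start_b = float(protocol.get("start_b", 0.0))
    noise = dict(config.get("noise", {}))
    imaging = dict(config.get("imaging", {}))

    design = synthetic.ChipDesign(**config.get("design", {}))
    model = synthetic.ResponseModel(**config["model"])
    calibrations = synthetic.default_calibrations()

    barcode_sigma = float(noise.get("barcode_sigma", 0.05))
    blank_intensity = 10.0
    # log-normal barcode noise widens the blank; margin follows its sd
    blank_sd = blank_intensity * (np.exp(barcode_sigma) - 1.0)

    all_records = []
    chip_seeds = []
    for chip in range(n_chips):
        chip_seed = (seed * 1000 + chip) % (2**31 - 1)
        chip_seeds.append(chip_seed)
        sim = synthetic.simulate_chip(
            design, model, calibrations, days=days, seed=chip_seed,
            barcode_sigma=barcode_sigma, blank_intensity=blank_intensity,
            image_noise_sd=float(noise.get("image_noise_sd", 2.0)),
            start_a=start_a, start_b=start_b,
            shape=tuple(imaging.get("shape", (96, 96))),
            radius_um=float(imaging.get("radius_um", 22.0)),
        )
        df = analyze_chip(sim, calibrations, blank_intensity=blank_intensity,
                          blank_sd=blank_sd)
        df.insert(0, "chip", chip)
        all_records.append(df)
    records = pd.concat(all_records, ignore_index=True)
    records.to_csv(outdir / "records.csv", index=False)

    score_days = sorted(records["day"].unique())
    fit_day = int(config.get("fit_day", score_days[-1]))

    heatmaps = {}
    for day in score_days:
        grid = aggregate_heatmap(records, day, design.n_levels_a, design.n_levels_b)
        heatmaps[day] = grid
        pd.DataFrame(grid.mean).to_csv(outdir / f"heatmap_d{day}.csv", index=False)
        _plot_heatmap(grid, design, outdir / f"heatmap_d{day}.png")

    pin = None
    if config.get("pin_top_to_controls", True):
        ctrl = records[(records["day"] == fit_day) & ~records["excluded"]
                       & (records["level_a"] == 0) & (records["level_b"] == 0)]
        if len(ctrl) >= 3:
            pin = float(ctrl["viability"].mean())

    fit_rows = []
    fits = {}
    for day in score_days:
        for axis, drug in (("a", design.drug_a), ("b", design.drug_b)):
            try:
                fit = _single_drug_fit(records, axis, day, pin_top=pin)
            except (FlatResponseError, ValueError):
                continue
            fits[(day, axis)] = fit
            fit_rows.append({"day": day, "drug": drug, **fit.as_row()})
    pd.DataFrame(fit_rows).to_csv(outdir / "fits.csv", index=False)

    fic_rows = []
    replicate_fics = []
    if (fit_day, "a") in fits and (fit_day, "b") in fits:
        usable = records[~records["excluded"]]
        diag = select_diagonal(usable, day=fit_day)
        combo = combined_ic50(diag, pin_top=pin)
        fic = compute_fic(combo.ic50, fits[(fit_day, "a")].ic50,
                          fits[(fit_day, "b")].ic50)
        for chip in sorted(usable["chip"].unique()):
            try:
                chip_df = usable[usable["chip"] == chip]
                c = combined_ic50(select_diagonal(chip_df, day=fit_day), pin_top=pin)
                a = fit_sigmoid(
                    chip_df[(chip_df["day"] == fit_day) & (chip_df["level_a"] >= 1)
                            & (chip_df["level_b"] == 0)]["conc_a"],
                    chip_df[(chip_df["day"] == fit_day) & (chip_df["level_a"] >= 1)
                            & (chip_df["level_b"] == 0)]["viability"], pin_top=pin)
                b = fit_sigmoid(
                    chip_df[(chip_df["day"] == fit_day) & (chip_df["level_b"] >= 1)
                            & (chip_df["level_a"] == 0)]["conc_b"],
                    chip_df[(chip_df["day"] == fit_day) & (chip_df["level_b"] >= 1)
                            & (chip_df["level_a"] == 0)]["viability"], pin_top=pin)
                replicate_fics.append(compute_fic(c.ic50, a.ic50, b.ic50))
            except (FlatResponseError, ValueError):
                continue
        fic_rows.append({
            "protocol": label, "day": fit_day, "fic": fic,
            "ic50_combo": combo.ic50,
            "ic50_A": fits[(fit_day, "a")].ic50,
            "ic50_B": fits[(fit_day, "b")].ic50,
            "n_rep": len(replicate_fics),
            "replicate_fics": ";".join(f"{f:.6g}" for f in replicate_fics),
        })
    pd.DataFrame(fic_rows).to_csv(outdir / "fic.csv", index=False)

    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "config": config,
        "config_sha256": config_hash,
        "protocol": label,
        "chip_seeds": chip_seeds,
        "n_records": int(len(records)),
        "n_excluded": int(records["excluded"].sum()),
        "fit_day": fit_day,
        "conventions": {
            "threshold_comparison": "strict >",
            "sigma": "population (ddof=0)",
            "combined_dose": "sum cA + cB",
            "tie_break_decode": "lower level",
            "viability_clamped": True,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {"records": records, "heatmaps": heatmaps, "fits": fits,
            "fic": pd.DataFrame(fic_rows), "replicate_fics": replicate_fics,
            "manifest": manifest, "outdir": outdir}
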