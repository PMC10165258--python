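"""Loewe-diagonal synergy analysis: combined IC50, FIC, protocol comparison.

The checkerboard's diagonal — grid cells whose ascending level index
matches on both drug axes — gives a one-dimensional dose series for the
combination.  Fitting viability against the total dose cA + cB on that
diagonal yields a combined IC50; dividing it by the mean of the two
single-drug IC50s gives the Fractional Inhibitory Concentration (FIC).
FIC < 1 indicates synergy, FIC > 1 antagonism; a drug combined with itself
under Loewe additivity sits exactly at FIC = 1, which is the identity the
total-dose convention preserves.

Protocol comparisons (simultaneous vs sequential orders) use a two-sided
Wilcoxon–Mann–Whitney rank-sum test on per-chip FIC replicates, with exact
enumeration at small sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import DoseResponseFit, fit_sigmoid

__all__ = ["FICResult", "select_diagonal", "combined_ic50", "compute_fic",
           "rank_sum_test", "compare_fic"]

EXACT_N_MAX = 12


def select_diagonal(records: pd.DataFrame, day: int | None = None) -> pd.DataFrame:
    """Wells on the checkerboard diagonal (equal non-zero level indices).

    ``records`` needs columns ``level_a, level_b, conc_a, conc_b,
    viability`` (and ``day`` if ``day`` is given).  Returns the subset with
    ``level_a == level_b >= 1`` annotated with ``total_dose = conc_a +
    conc_b``.  Diagonal membership matches level indices, not absolute
    concentrations: the two drugs span different ranges.
    """
    df = records
    if day is not None:
        df = df[df["day"] == day]
    diag = df[(df["level_a"] == df["level_b"]) & (df["level_a"] >= 1)].copy()
    if diag.empty:
        cells = sorted(
            set(zip(df["level_a"].astype(int), df["level_b"].astype(int)))
        )
        raise ValueError(f"no diagonal wells; available grid cells: {cells}")
    diag["total_dose"] = diag["conc_a"] + diag["conc_b"]
    return diag


def combined_ic50(diagonal: pd.DataFrame, **fit_options) -> DoseResponseFit:
    """Combined IC50 in total-dose units: 4PL fit of viability vs cA + cB."""
    if diagonal.empty:
        raise ValueError("empty diagonal subset")
    fit = fit_sigmoid(diagonal["total_dose"], diagonal["viability"], **fit_options)
    fit.units = "uM (total dose)"
    return fit


def compute_fic(combined: float, ic50_a: float, ic50_b: float) -> float:
    """FIC = combined IC50 / mean(single-drug IC50s); <1 synergy, >1 antagonism."""
    if combined <= 0 or ic50_a <= 0 or ic50_b <= 0:
        raise ValueError("all IC50s must be positive")
    return combined / ((ic50_a + ic50_b) / 2.0)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon–Mann–Whitney p-value.

    Exact enumeration of all C(n, n_x) group splits of the pooled sample
    when the combined n <= 12; tie-corrected normal approximation
    otherwise.  Ties get average ranks in both branches.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    n = x.size + y.size
    if n <= EXACT_N_MAX:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        w_obs = float(ranks[: x.size].sum())
        mu = x.size * (n + 1) / 2.0
        dev = abs(w_obs - mu)
        hits = 0
        for idx in combinations(range(n), x.size):
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                hits += 1
        return hits / comb(n, x.size)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


@dataclass
class FICResult:
    """FIC of one protocol with its ingredients and per-chip replicates."""

    protocol: str
    fic: float
    ic50_combined: float
    ic50_a: float
    ic50_b: float
    replicate_fics: list[float] = field(default_factory=list)

    def as_row(self) -> dict:
        return {"protocol": self.protocol, "fic": self.fic,
                "ic50_combo": self.ic50_combined, "ic50_A": self.ic50_a,
                "ic50_B": self.ic50_b, "n_rep": len(self.replicate_fics)}


def compare_fic(groups: dict[str, list[float]]) -> pd.DataFrame:
    """Pairwise rank-sum comparison of per-replicate FIC values by protocol.

    Returns a table ``protocol_1, protocol_2, p_value, significance`` with
    '*' at p < 0.05 and 'n.s.' otherwise.
    """
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"protocol {label!r} has < 2 replicates")
    rows = []
    labels = list(groups)
    for a, b in combinations(labels, 2):
        p = rank_sum_test(groups[a], groups[b])
        rows.append({"protocol_1": a, "protocol_2": b, "p_value": p,
                     "significance": "*" if p < 0.05 else "n.s."})
    return pd.DataFrame(rows)
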