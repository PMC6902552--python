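"""Correlation testing, the 24-window LA scan and the gene-expression scan.

Three multiple-testing regimes coexist in this analysis and are kept
deliberately distinct:

* the per-metabolite nominal screen against 24 h LA reports p < 0.05 counts
  and Benjamini–Hochberg q-values over all tested metabolites;
* the sliding-window scan (24 consecutive 3 h windows over the 72 h before
  sampling) corrects the 24 per-window prediction p-values by BH FDR and
  flags q < 0.1;
* the gene scan (default: seven circadian-related hippocampal genes)
  applies Bonferroni control, flagging p < alpha/m (0.05/7 ≈ 0.00714).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activity import ActivitySummary, la24h_targets, window_annotations, window_targets, N_WINDOWS
from .exceptions import UndefinedCorrelationError
from .metabolome import MetabolomeMatrix
from .predictor import NestedLOOCV, NestedLOOCVResults, PredictorConfig


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value.

    The p-value comes from ``t = r sqrt(n-2)/sqrt(1-r^2)`` on ``n-2``
    degrees of freedom.  Constant input raises
    :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order.

    Equivalent to ``q_(i) = min_{j>=i} p_(j) * m / j`` capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance level per test: alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if int(m) != m or m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


@dataclass
class MetaboliteScreenResult:
    """Per-metabolite (r, p, q) against 24 h LA, with threshold counts."""

    table: pd.DataFrame  # index metabolite; columns r, p, q
    nominal_alpha: float = 0.05
    q_threshold: float = 0.1

    @property
    def n_nominal(self) -> int:
        return int((self.table["p"] < self.nominal_alpha).sum())

    @property
    def n_fdr(self) -> int:
        return int((self.table["q"] < self.q_threshold).sum())

    def summary(self) -> str:
        m = len(self.table)
        return (
            f"Metabolite screen vs 24 h LA: {m} metabolites tested; "
            f"{self.n_nominal} at p < {self.nominal_alpha:g}; "
            f"{self.n_fdr} survive BH FDR at q < {self.q_threshold:g}"
        )


def metabolite_screen(
    m: MetabolomeMatrix,
    la24h: pd.Series,
    nominal_alpha: float = 0.05,
    q_threshold: float = 0.1,
) -> MetaboliteScreenResult:
    """Two-sided Pearson test of every metabolite against 24 h LA, with BH
    q-values over all tested metabolites."""
    features = m.features()
    y = la24h.loc[features.index].to_numpy(dtype=float)
    rows = {}
    for name in features.columns:
        r, p = pearson_test(features[name].to_numpy(dtype=float), y)
        rows[name] = {"r": r, "p": p}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "metabolite"
    table["q"] = bh_fdr(table["p"].to_numpy())
    return MetaboliteScreenResult(table=table, nominal_alpha=nominal_alpha, q_threshold=q_threshold)


@dataclass
class WindowScanResult:
    """Per-window prediction performance with BH FDR flags at q < 0.1."""

    table: pd.DataFrame  # index window 1..24; columns hours_before, phase, r, p, q, significant
    q_threshold: float = 0.1
    fits: list[NestedLOOCVResults] = field(default_factory=list, repr=False)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_windows(self) -> list[int]:
        return [int(w) for w in self.table.index[self.table["significant"]]]

    def summary(self) -> str:
        sig = self.significant_windows()
        lines = [
            f"Sliding-window scan: {len(self.table)} windows of 3 h over the 72 h before sampling",
            f"Significant after BH FDR (q < {self.q_threshold:g}): {len(sig)} window(s) {sig}",
        ]
        for w in sig:
            row = self.table.loc[w]
            lines.append(
                f"  window {w:2d} ({row['hours_before']}): r = {row['r']:.2f}, P = {row['p']:.2g}, q = {row['q']:.2g}"
            )
        return "\n".join(lines)


def window_scan(
    m: MetabolomeMatrix,
    summaries: Sequence[ActivitySummary],
    config: PredictorConfig | None = None,
    q_threshold: float = 0.1,
    keep_fits: bool = False,
) -> WindowScanResult:
    """Nested-LOOCV prediction of each of the 24 3 h-window LAs, with BH FDR
    over the 24 per-window p-values."""
    features = m.features()
    annotations = window_annotations(summaries)
    rows = []
    fits = []
    for w in range(1, N_WINDOWS + 1):
        y = window_targets(summaries, w)
        res = NestedLOOCV.from_dataframe(features, y, config=config).fit()
        if keep_fits:
            fits.append(res)
        rows.append(
            {
                "hours_before": f"{3 * (w - 1)}-{3 * w}h",
                "phase": annotations.loc[w],
                "r": res.pearson_r,
                "p": res.p_value,
            }
        )
    table = pd.DataFrame(rows, index=pd.RangeIndex(1, N_WINDOWS + 1, name="window"))
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["q"] < q_threshold
    return WindowScanResult(table=table, q_threshold=q_threshold, fits=fits)


@dataclass
class GeneScanResult:
    """Per-gene prediction performance with Bonferroni flags."""

    table: pd.DataFrame  # index gene; columns r, p, significant
    alpha: float = 0.05
    threshold: float = 0.05
    fits: list[NestedLOOCVResults] = field(default_factory=list, repr=False)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def summary(self) -> str:
        sig = self.table.index[self.table["significant"]].tolist()
        lines = [
            f"Gene-expression scan: {len(self.table)} genes, Bonferroni threshold "
            f"P < {self.threshold:.3g} (= {self.alpha:g}/{len(self.table)})",
            f"Significant: {sig if sig else 'none'}",
        ]
        return "\n".join(lines)


def gene_scan(
    m: MetabolomeMatrix,
    expression: pd.DataFrame,
    config: PredictorConfig | None = None,
    alpha: float = 0.05,
    keep_fits: bool = False,
) -> GeneScanResult:
    """Nested-LOOCV prediction of each gene's log2 expression from the
    metabolome, Bonferroni-corrected over the genes tested."""
    if expression.shape[1] < 1:
        raise ValueError("need at least one gene")
    features = m.features()
    thr = bonferroni_threshold(alpha, expression.shape[1])
    rows = {}
    fits = []
    for gene in expression.columns:
        y = expression[gene]
        res = NestedLOOCV.from_dataframe(features, y, config=config).fit()
        if keep_fits:
            fits.append(res)
        rows[gene] = {"r": res.pearson_r, "p": res.p_value}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    table["significant"] = table["p"] < thr
    return GeneScanResult(table=table, alpha=alpha, threshold=thr, fits=fits)


def predict_la24h(
    m: MetabolomeMatrix,
    summaries: Sequence[ActivitySummary],
    config: PredictorConfig | None = None,
    leak_feature_ranking: bool = False,
) -> NestedLOOCVResults:
    """Convenience wrapper: nested-LOOCV prediction of the 24 h LA."""
    features = m.features()
    y = la24h_targets(summaries)
    return NestedLOOCV.from_dataframe(features, y, config=config).fit(leak_feature_ranking=leak_feature_ranking)
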