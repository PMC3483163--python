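"""Expression-matrix normalization, per-line log fold changes and summaries.

Probe-by-sample intensity matrices (background-subtracted, so values at or
below zero can occur) are quantile normalized across all samples jointly,
then each treated column is compared with the matched untreated column of
the same cell line to give a per-line log2 fold change per probe: iFC for
imatinib, oFC for omacetaxine.  Intensities are floored at 1.0 before
ratios so fold changes stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "FoldChangeTable",
    "CONDITIONS",
    "DEFAULT_FLOOR",
    "quantile_normalize",
    "log_fold_change",
    "fold_change_table",
    "paired_t_test",
    "enrichment_score",
    "load_expression",
    "write_expression",
]

CONDITIONS = ("untreated", "imatinib", "omacetaxine")
DEFAULT_FLOOR = 1.0


@dataclass
class ExpressionMatrix:
    """Probe x sample intensities; sample ids are "line_id:condition"."""

    probe_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("intensity matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities, index=self.probe_ids, columns=self.sample_ids
        )

    def column(self, line_id: str, condition: str) -> np.ndarray:
        return self.intensities[:, self.sample_ids.index(f"{line_id}:{condition}")]

    @property
    def line_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            line = s.split(":", 1)[0]
            if line not in seen:
                seen.append(line)
        return seen


@dataclass
class FoldChangeTable:
    """Per-line log2 fold changes per probe for both drugs."""

    probe_ids: list[str]
    line_ids: list[str]
    ifc: np.ndarray  # probes x lines, imatinib vs untreated
    ofc: np.ndarray  # probes x lines, omacetaxine vs untreated

    def mean_ifc(self) -> np.ndarray:
        return self.ifc.mean(axis=1)

    def mean_ofc(self) -> np.ndarray:
        return self.ofc.mean(axis=1)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean empirical distribution.

    Rank each column; entry with (average) rank r is replaced by the mean of
    the r-th order statistics across columns, interpolating for fractional
    tie ranks.  After normalization all column sorted vectors are identical.
    """
    X = m.intensities
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    n = X.shape[0]
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            warnings.warn(f"constant sample column {m.sample_ids[j]!r}")
        ranks = stats.rankdata(col, method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    return ExpressionMatrix(list(m.probe_ids), list(m.sample_ids), out)


def log_fold_change(treated, untreated, floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """Per-probe log2 ratio of floored treated over floored untreated."""
    treated = np.asarray(treated, dtype=float)
    untreated = np.asarray(untreated, dtype=float)
    if treated.shape != untreated.shape:
        raise ValueError("treated/untreated vectors differ in length")
    return np.log2(np.maximum(treated, floor) / np.maximum(untreated, floor))


def fold_change_table(
    m: ExpressionMatrix, floor: float = DEFAULT_FLOOR
) -> FoldChangeTable:
    """Per-line iFC and oFC for every probe (requires all three conditions)."""
    lines = m.line_ids
    have = set(m.sample_ids)
    for line in lines:
        for cond in CONDITIONS:
            if f"{line}:{cond}" not in have:
                raise ValueError(f"line {line!r} lacks condition {cond!r}")
    ifc = np.column_stack(
        [log_fold_change(m.column(l, "imatinib"), m.column(l, "untreated"), floor)
         for l in lines]
    )
    ofc = np.column_stack(
        [log_fold_change(m.column(l, "omacetaxine"), m.column(l, "untreated"), floor)
         for l in lines]
    )
    return FoldChangeTable(list(m.probe_ids), lines, ifc, ofc)


def paired_t_test(treated, untreated) -> tuple[float, float]:
    """Two-sided paired Student's t test on matched measurements."""
    treated = np.asarray(treated, dtype=float)
    untreated = np.asarray(untreated, dtype=float)
    if treated.shape != untreated.shape or treated.shape[0] < 2:
        raise ValueError("need >= 2 matched pairs")
    d = treated - untreated
    if np.ptp(d) == 0 and d[0] != 0:
        raise ValueError("zero variance of paired differences")
    t, p = stats.ttest_rel(treated, untreated)
    return float(t), float(p)


def enrichment_score(pvalues) -> float:
    """Mean -log10(p) over a probe set; p = 0 is clamped with a warning."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    return float(np.mean(-np.log10(p)))


# ---------------------------------------------------------------------------
# tabular I/O


def load_expression(path) -> ExpressionMatrix:
    """Read a probe x sample matrix (TSV or CSV, delimiter autodetected)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return ExpressionMatrix(
        probe_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        intensities=df.to_numpy(dtype=float),
    )


def write_expression(m: ExpressionMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="probe_id")
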