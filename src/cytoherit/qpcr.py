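"""qPCR replicate QC, 2^-ddCT relative quantitation and platform concordance.

Cycle-threshold (CT) triplicates are accepted if their standard deviation is
<= 0.3; otherwise the tightest duplicate is tried, and if that also exceeds
0.3 the sample is excluded.  Relative quantitation assumes perfect PCR
doubling: ddCT = (CT_target - CT_reference)_treated - (CT_target -
CT_reference)_control and the fold change is 2^-ddCT.  Concordance between
microarray and qPCR fold changes uses Pearson's correlation when both
margins pass a Shapiro-Wilk normality gate and Spearman's otherwise; the
microarray fold changes are first corrected for the reference gene (HPRT1)
so the two platforms share a normalizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CTRecord",
    "RelativeQuant",
    "CT_SD_LIMIT",
    "qc_ct",
    "ddct",
    "hprt1_correct",
    "platform_concordance",
    "load_ct_table",
    "relative_quant_table",
]

CT_SD_LIMIT = 0.3


@dataclass(frozen=True)
class CTRecord:
    sample_id: str
    gene: str
    condition: str  # untreated | imatinib | omacetaxine
    ct_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.ct_replicates) <= 3:
            raise ValueError("1-3 CT replicates expected")
        if any(not 0 < ct < 45 for ct in self.ct_replicates):
            raise ValueError(f"CT values out of range: {self.ct_replicates}")


@dataclass(frozen=True)
class RelativeQuant:
    sample_id: str
    gene: str
    condition: str
    ddct: float
    rq: float  # 2^-ddct


def qc_ct(replicates) -> float | None:
    """Mean CT of the accepted replicate subset, or None if excluded.

    Triplicates with sample SD (n-1 denominator) <= 0.3 are averaged; if the
    SD is larger, the pair with the smallest SD is assessed, and if that SD
    also exceeds 0.3 the sample is excluded.
    """
    cts = np.asarray(list(replicates), dtype=float)
    if cts.size == 1:
        return float(cts[0])
    if cts.size <= 3 and np.std(cts, ddof=1) <= CT_SD_LIMIT:
        return float(cts.mean())
    if cts.size == 2:
        return None
    best = min(combinations(cts, 2), key=lambda pr: np.std(pr, ddof=1))
    if np.std(best, ddof=1) <= CT_SD_LIMIT:
        return float(np.mean(best))
    return None


def ddct(
    target_treated: float | None,
    ref_treated: float | None,
    target_control: float | None,
    ref_control: float | None,
    *,
    sample_id: str = "",
    gene: str = "",
    condition: str = "",
) -> RelativeQuant | None:
    """2^-ddCT relative quantitation; any excluded input propagates None."""
    cts = (target_treated, ref_treated, target_control, ref_control)
    if any(ct is None for ct in cts):
        return None
    delta = (target_treated - ref_treated) - (target_control - ref_control)
    return RelativeQuant(
        sample_id=sample_id,
        gene=gene,
        condition=condition,
        ddct=float(delta),
        rq=float(2.0 ** (-delta)),
    )


def hprt1_correct(micro_fc, reference_fc) -> np.ndarray:
    """Subtract the reference-gene (HPRT1) log FC from each microarray log FC."""
    micro_fc = np.asarray(micro_fc, dtype=float)
    reference_fc = np.asarray(reference_fc, dtype=float)
    return micro_fc - reference_fc


def platform_concordance(
    micro_fc, qpcr_log_rq, normality_alpha: float = 0.05
) -> tuple[float, float, str]:
    """Correlate microarray and qPCR log fold changes.

    Returns (coefficient, two-sided p, method), with method "pearson" if both
    margins pass Shapiro-Wilk at ``normality_alpha`` and "spearman"
    otherwise.
    """
    x = np.asarray(micro_fc, dtype=float)
    y = np.asarray(qpcr_log_rq, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant margin: correlation undefined")
    normal = (
        stats.shapiro(x).pvalue > normality_alpha
        and stats.shapiro(y).pvalue > normality_alpha
    )
    if normal:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return float(r), float(p), method


# ---------------------------------------------------------------------------
# tabular I/O


def load_ct_table(path) -> list[CTRecord]:
    """Read a CT TSV: sample_id, gene, condition, ct1, ct2, ct3 (blanks ok)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for r in df.itertuples():
        cts = tuple(
            float(v) for v in (r.ct1, getattr(r, "ct2", None), getattr(r, "ct3", None))
            if v is not None and not pd.isna(v)
        )
        records.append(
            CTRecord(
                sample_id=str(r.sample_id),
                gene=str(r.gene),
                condition=str(r.condition),
                ct_replicates=cts,
            )
        )
    return records


def relative_quant_table(
    records: list[CTRecord], reference_gene: str = "HPRT1"
) -> pd.DataFrame:
    """2^-ddCT per (sample, target gene, treated condition).

    Control condition is "untreated"; excluded samples appear with NaN rq.
    """
    means: dict[tuple[str, str, str], float | None] = {}
    for rec in records:
        means[(rec.sample_id, rec.gene, rec.condition)] = qc_ct(rec.ct_replicates)
    rows = []
    for (sample, gene, cond), ct in sorted(means.items()):
        if gene == reference_gene or cond == "untreated":
            continue
        rq = ddct(
            ct,
            means.get((sample, reference_gene, cond)),
            means.get((sample, gene, "untreated")),
            means.get((sample, reference_gene, "untreated")),
            sample_id=sample,
            gene=gene,
            condition=cond,
        )
        rows.append(
            {
                "sample_id": sample,
                "gene": gene,
                "condition": cond,
                "ddct": np.nan if rq is None else rq.ddct,
                "rq": np.nan if rq is None else rq.rq,
                "log2_rq": np.nan if rq is None else -rq.ddct,
            }
        )
    return pd.DataFrame(rows)
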