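"""FDR correction, fold-change clustering, ellipses and group tests.

Per-probe p-values are corrected by the Benjamini-Hochberg step-up
procedure.  Probes significant for either drug are clustered with k-means
(Euclidean distance, Lloyd refinement, fixed k = 4 by default) in the
(iFC, oFC) plane, and each cluster is summarized by its mean fold changes
and enrichment scores (mean -log10 of the FDR-corrected p-values).
Bivariate confidence ellipses, Kruskal-Wallis group comparisons and the
one-sample proportion chi-square (used for cis-regulation enrichment)
round out the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .expression import enrichment_score

__all__ = [
    "QValueTable",
    "ClusterReport",
    "EllipseSpec",
    "DEFAULT_K",
    "bh_qvalues",
    "kmeans_fc",
    "cluster_summary",
    "significant_overlap",
    "confidence_ellipse",
    "kruskal_wallis",
    "proportion_chi2",
]

DEFAULT_K = 4


@dataclass
class QValueTable:
    probe_ids: list[str]
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray  # bool, q < alpha
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p": self.p, "q": self.q, "significant": self.significant},
            index=self.probe_ids,
        )


@dataclass
class ClusterReport:
    probe_ids: list[str]
    assignment: np.ndarray  # labels in 1..k
    centers: np.ndarray  # k x 2, (iFC, oFC)
    inertia: float

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment - 1, minlength=self.k)


@dataclass
class EllipseSpec:
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    rotation: float  # radians, major axis vs x-axis
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse (for coverage checks)."""
        pts = np.atleast_2d(points) - np.asarray(self.center)
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.array([[c, s], [-s, c]])
        uv = pts @ rot.T
        a, b = self.semi_axes
        return (uv[:, 0] / a) ** 2 + (uv[:, 1] / b) ** 2 <= 1.0


def bh_qvalues(p, alpha: float = 0.05, probe_ids=None) -> QValueTable:
    """Benjamini-Hochberg step-up q-values at level ``alpha``."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    if probe_ids is None:
        probe_ids = [str(i) for i in range(p.size)]
    return QValueTable(
        probe_ids=list(probe_ids), p=p, q=q, significant=q < alpha, alpha=alpha
    )


def kmeans_fc(
    points,
    k: int = DEFAULT_K,
    seed: int = 0,
    restarts: int = 100,
    probe_ids=None,
) -> ClusterReport:
    """Seeded k-means (Lloyd, Euclidean) on (iFC, oFC) pairs.

    Random initializations are drawn from the data; the best of ``restarts``
    runs by within-cluster sum of squares is kept, so results are
    deterministic given the seed.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    n = points.shape[0]
    if k <= 0 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(
        n_clusters=k, init="random", n_init=restarts, random_state=seed,
        algorithm="lloyd",
    ).fit(points)
    if probe_ids is None:
        probe_ids = [str(i) for i in range(n)]
    return ClusterReport(
        probe_ids=list(probe_ids),
        assignment=km.labels_ + 1,
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def match_clusters(report: ClusterReport, reference_centers) -> dict[int, int]:
    """Map arbitrary k-means labels onto reference clusters by nearest center."""
    ref = np.asarray(reference_centers, dtype=float)
    mapping = {}
    for lab in range(1, report.k + 1):
        d = np.linalg.norm(ref - report.centers[lab - 1], axis=1)
        mapping[lab] = int(np.argmin(d)) + 1
    return mapping


def cluster_summary(
    report: ClusterReport,
    ifc_means,
    ofc_means,
    q_imatinib=None,
    q_omacetaxine=None,
) -> pd.DataFrame:
    """Per-cluster sizes, mean fold changes and enrichment scores.

    Enrichment scores are the mean -log10 of the supplied FDR-corrected
    p-values (q-values); omitted if not given.  Empty clusters are reported
    with NaN summaries.
    """
    ifc_means = np.asarray(ifc_means, dtype=float)
    ofc_means = np.asarray(ofc_means, dtype=float)
    n = len(report.probe_ids)
    rows = []
    for lab in range(1, report.k + 1):
        mask = report.assignment == lab
        row = {
            "cluster": lab,
            "n": int(mask.sum()),
            "fraction": float(mask.mean()),
        }
        if mask.any():
            row["mean_ifc"] = float(ifc_means[mask].mean())
            row["mean_ofc"] = float(ofc_means[mask].mean())
            if q_imatinib is not None:
                row["enrichment_imatinib"] = enrichment_score(
                    np.asarray(q_imatinib)[mask]
                )
            if q_omacetaxine is not None:
                row["enrichment_omacetaxine"] = enrichment_score(
                    np.asarray(q_omacetaxine)[mask]
                )
        else:
            row["mean_ifc"] = row["mean_ofc"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def significant_overlap(sig_a, sig_b, universe) -> tuple[int, float]:
    """Count and universe fraction of probes significant for both drugs."""
    universe = set(universe)
    a, b = set(sig_a), set(sig_b)
    if not a <= universe or not b <= universe:
        raise ValueError("significant sets must be subsets of the universe")
    inter = a & b
    return len(inter), len(inter) / len(universe)


def confidence_ellipse(points, level: float = 0.95) -> EllipseSpec:
    """Bivariate normal confidence ellipse from the sample mean/covariance.

    Semi-axes are sqrt(eigenvalue * chi2_2 quantile at ``level``); rotation
    follows the leading eigenvector.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 bivariate points")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    cov = np.cov(pts, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[0] <= 1e-12 * max(eigval[1], 1.0):
        raise ValueError("singular covariance: points are (near) collinear")
    scale = stats.chi2.ppf(level, df=2)
    # eigh returns ascending order; major axis last
    major, minor = np.sqrt(eigval[1] * scale), np.sqrt(eigval[0] * scale)
    rotation = float(np.arctan2(eigvec[1, 1], eigvec[0, 1]))
    center = tuple(pts.mean(axis=0))
    return EllipseSpec(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(major), float(minor)),
        rotation=rotation,
        level=level,
    )


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square(k-1) p-value."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        # all observations tied; H defined as 0 under the tie convention
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def proportion_chi2(k: int, n: int, p0: float) -> tuple[float, float]:
    """One-sample goodness-of-fit chi-square for a proportion vs p0 (df=1)."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    if n * p0 < 1:
        import warnings

        warnings.warn("expected count below 1: chi-square approximation poor")
    expected = np.array([n * p0, n * (1 - p0)])
    observed = np.array([k, n - k])
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))
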