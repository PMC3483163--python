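"""End-to-end study orchestration.

Ties the stages together: simulated (or loaded) plates -> viability/IC/SDR
-> heritability of log IC per inhibition threshold (the Table-1-shaped
report); expression matrix -> quantile normalization -> per-line fold
changes -> kinship-corrected per-probe mean tests -> BH FDR -> k-means
clustering -> fold-change/SDR association.  Every tabular output can carry
a provenance header (config hash, seed) so a stage can be rerun in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cluster_stats, dose_response, expression as expr_mod
from .pedigree import Pedigree, kinship_matrix
from .variance_components import (
    CovariateMatrix,
    DegenerateTraitError,
    PolygenicModel,
    TraitVector,
    _nested_polygenic_pair,
    covariate_matrix,
    fit_sporadic,
    heritability_test,
    lrt,
)

__all__ = [
    "RunConfig",
    "StageError",
    "study_covariates",
    "run_heritability_study",
    "run_dex_study",
    "write_tsv",
]

log = logging.getLogger("cytoherit")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    alpha: float = 0.05
    k: int = 4
    thresholds: tuple[int, ...] = tuple(range(10, 100, 10))
    seed: int = 17
    restarts: int = 100
    boundary_mixture: bool = True
    use_kinship_for_fc: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, config: RunConfig | None = None, **meta) -> None:
    """Write a TSV with a machine-readable provenance header."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# cytoherit config_hash={config.digest()} seed={config.seed}\n")
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def study_covariates(ped: Pedigree, ids) -> CovariateMatrix:
    """Age/sex covariate matrix from pedigree annotations (sex 1 = male)."""
    ages = [ped[i].age for i in ids]
    sexes = [1.0 if ped[i].sex == 1 else 0.0 for i in ids]
    ages = [np.nan if a is None else a for a in ages]
    return covariate_matrix(ids, ages, sexes)


def run_heritability_study(
    ped: Pedigree,
    plates: dict,
    config: RunConfig | None = None,
    use_covariates: bool = True,
) -> pd.DataFrame:
    """Heritability of log inhibitory concentrations per drug and threshold.

    ``plates`` maps drug name to its plate records.  For each threshold in
    the IC ladder, IC doses are extracted per line from the 4PL fits, log10
    transformed, inverse-normal transformed, and tested for heritability
    with the polygenic model.  Returns a table with drug, threshold, mean
    dose (molar), h2 and the boundary-mixture p.
    """
    if config is None:
        config = RunConfig()
    rows = []
    for drug, records in plates.items():
        try:
            table = dose_response.ic_table(records, thresholds=config.thresholds)
        except Exception as exc:  # pragma: no cover - surfaced with stage name
            raise StageError(f"viability stage failed for {drug!r}: {exc}") from exc
        table = table[table.drug == drug].set_index("line_id")
        for t in config.thresholds:
            ic = table[f"ic{t}"].dropna()
            ids = list(ic.index)
            X = study_covariates(ped, ids) if use_covariates else None
            K = kinship_matrix(ped, ids)
            trait = TraitVector(ids, np.log10(ic.to_numpy()))
            h2, test = heritability_test(trait, X, K)
            rows.append(
                {
                    "drug": drug,
                    "threshold": t,
                    "mean_dose_molar": float(ic.mean()),
                    "n": len(ids),
                    "h2": h2,
                    "statistic": test.statistic,
                    "p": test.p,
                }
            )
            log.info("heritability %s threshold %d: h2=%.3f p=%.3g", drug, t, h2,
                     test.p)
    return pd.DataFrame(rows)


def _per_probe_mean_tests(
    model: PolygenicModel | None,
    fc: np.ndarray,
    ids: list[str],
    X: CovariateMatrix | None,
    use_kinship: bool,
) -> np.ndarray:
    """Mean-zero LRT p-value per probe (rows of ``fc``)."""
    ps = np.empty(fc.shape[0])
    for i in range(fc.shape[0]):
        y = fc[i]
        try:
            if use_kinship:
                full, constrained = _nested_polygenic_pair(
                    model, y, X,
                    {"include_intercept": True}, {"include_intercept": False},
                )
            else:
                tv = TraitVector(ids, y)
                full = fit_sporadic(tv, X, include_intercept=True)
                constrained = fit_sporadic(tv, X, include_intercept=False)
            ps[i] = lrt(full, constrained, boundary=False).p
        except DegenerateTraitError:
            # constant fold change (e.g. rank-extreme probe after quantile
            # normalization): untestable, reported as NaN
            ps[i] = np.nan
    return ps


def run_dex_study(
    ped: Pedigree,
    matrix: expr_mod.ExpressionMatrix,
    sdr: dict | None = None,
    config: RunConfig | None = None,
    use_covariates: bool = True,
    normalize: bool = True,
) -> dict:
    """Differential-expression study on a probe x sample matrix.

    Returns a dict with keys:

    - ``volcano``: per-probe mean iFC/oFC, raw p and BH q per drug
    - ``clusters``: ClusterReport over probes significant for either drug
    - ``cluster_summary``: per-cluster means and enrichment scores
    - ``overlap``: (count, fraction) of probes significant for both drugs
    - ``association``: per-probe FC-SDR coefficient and p per drug (if
      ``sdr`` supplies per-line slopes for the drug)
    """
    if config is None:
        config = RunConfig()
    if normalize:
        matrix = expr_mod.quantile_normalize(matrix)
    fct = expr_mod.fold_change_table(matrix)
    ids = fct.line_ids
    K = kinship_matrix(ped, ids)
    X = study_covariates(ped, ids) if use_covariates else None
    model = PolygenicModel(K) if config.use_kinship_for_fc else None

    volcano = pd.DataFrame({"probe_id": fct.probe_ids})
    qtables = {}
    for drug, fc in (("imatinib", fct.ifc), ("omacetaxine", fct.ofc)):
        p = _per_probe_mean_tests(model, fc, ids, X, config.use_kinship_for_fc)
        ok = np.isfinite(p)
        q = np.full_like(p, np.nan)
        sub = cluster_stats.bh_qvalues(p[ok], alpha=config.alpha)
        q[ok] = sub.q
        qt = cluster_stats.QValueTable(
            probe_ids=list(fct.probe_ids), p=p, q=q,
            significant=np.where(ok, q < config.alpha, False),
            alpha=config.alpha,
        )
        qtables[drug] = qt
        volcano[f"mean_{'ifc' if drug == 'imatinib' else 'ofc'}"] = fc.mean(axis=1)
        volcano[f"p_{drug}"] = p
        volcano[f"q_{drug}"] = qt.q

    sig_i = qtables["imatinib"].significant
    sig_o = qtables["omacetaxine"].significant
    sig_either = sig_i | sig_o
    overlap = cluster_stats.significant_overlap(
        [pid for pid, s in zip(fct.probe_ids, sig_i) if s],
        [pid for pid, s in zip(fct.probe_ids, sig_o) if s],
        fct.probe_ids,
    )

    result = {"volcano": volcano, "overlap": overlap, "qtables": qtables,
              "significant_either": sig_either}
    if sig_either.sum() >= config.k:
        pts = np.column_stack(
            [fct.mean_ifc()[sig_either], fct.mean_ofc()[sig_either]]
        )
        report = cluster_stats.kmeans_fc(
            pts, k=config.k, seed=config.seed, restarts=config.restarts,
            probe_ids=[p for p, s in zip(fct.probe_ids, sig_either) if s],
        )
        result["clusters"] = report
        result["cluster_summary"] = cluster_stats.cluster_summary(
            report,
            fct.mean_ifc()[sig_either],
            fct.mean_ofc()[sig_either],
            qtables["imatinib"].q[sig_either],
            qtables["omacetaxine"].q[sig_either],
        )

    if sdr:
        assoc_rows = []
        kin_model = PolygenicModel(K)
        for drug, fc in (("imatinib", fct.ifc), ("omacetaxine", fct.ofc)):
            if drug not in sdr:
                continue
            slopes = np.asarray([sdr[drug][i] for i in ids], dtype=float)
            constrained = kin_model.fit(slopes, X, include_intercept=True)
            for i, probe in enumerate(fct.probe_ids):
                fcv = fc[i]
                if np.ptp(fcv) == 0:
                    continue
                full = kin_model.fit(slopes, X, include_intercept=True, extra=fcv)
                if abs(full.h2 - constrained.h2) > 0.05 or (
                    constrained.loglik > full.loglik
                ):
                    # keep the nested pair on the same likelihood mode; a
                    # better constrained fit stays valid for later probes
                    c2 = kin_model.fit(
                        slopes, X, include_intercept=True, h2_hint=full.h2
                    )
                    if c2.loglik > constrained.loglik:
                        constrained = c2
                    f2 = kin_model.fit(
                        slopes, X, include_intercept=True, extra=fcv,
                        h2_hint=constrained.h2,
                    )
                    if f2.loglik > full.loglik:
                        full = f2
                test = lrt(full, constrained, boundary=False)
                assoc_rows.append(
                    {
                        "probe_id": probe,
                        "drug": drug,
                        "coefficient": float(full.beta[-1]),
                        "statistic": test.statistic,
                        "p": test.p,
                    }
                )
        result["association"] = pd.DataFrame(assoc_rows)
    return result
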