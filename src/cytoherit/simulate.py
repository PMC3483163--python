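"""Synthetic study generator with known ground truth.

Emulates the structure of a pedigree-based cytotoxicity study: 17 extended
families of 6-10 members containing sibling, third-degree (first-cousin) and
one monozygotic-twin pair among the assayed cell lines; log-IC drug-response
traits with a chosen additive heritability on the kinship covariance;
plate-level alamarBlue absorbances following 4PL dose-response curves over
the study dose grids with triplicate noise; a probe-by-sample expression
matrix with a planted four-cluster (iFC, oFC) structure plus null probes and
kinship-correlated fold-change residuals; and CT triplicates consistent with
the expression fold changes.

Every generator is a pure function of (config, rng): re-running with the
same seed reproduces the data exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import (
    COEF_570,
    COEF_600,
    IMATINIB_DOSES,
    OMACETAXINE_DOSES,
    PlateRecord,
    four_pl,
)
from .expression import ExpressionMatrix
from .pedigree import Individual, KinshipMatrix, Pedigree
from .qpcr import CTRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "StudyData",
    "simulate_pedigrees",
    "simulate_polygenic_trait",
    "simulate_plate_data",
    "simulate_expression",
    "simulate_ct",
    "simulate_study",
]

# printed per-cluster mean (iFC, oFC) pairs used as planted centers
DEFAULT_CLUSTER_CENTERS = (
    (-0.02, 0.26),
    (-0.08, -0.35),
    (0.36, 0.10),
    (0.13, 0.50),
)
# cluster shares of significant probes (30.95/45.03/9.61/14.42 %) scaled by
# the ~9.1% overall significant fraction of the 48,803-probe array
DEFAULT_CLUSTER_FRACTIONS = (0.0282, 0.0411, 0.0088, 0.0132)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_families: int = 17
    family_size_range: tuple[int, int] = (6, 10)
    n_assayed: int = 55
    h2_ic_imatinib: float = 0.60
    h2_ic_omacetaxine: float = 0.0
    n_probes: int = 4000
    cluster_centers: tuple = DEFAULT_CLUSTER_CENTERS
    cluster_fractions: tuple = DEFAULT_CLUSTER_FRACTIONS
    null_fraction: float = 1.0 - sum(DEFAULT_CLUSTER_FRACTIONS)
    probe_scatter_sd: float = 0.08  # probe true means around cluster centers
    fc_noise_sd: float = 0.25  # per-line log2 FC dispersion around probe mean
    h2r_range: tuple[float, float] = (0.0, 0.5)
    dose_grids: dict = field(
        default_factory=lambda: {
            "imatinib": tuple(IMATINIB_DOSES),
            "omacetaxine": tuple(OMACETAXINE_DOSES),
        }
    )
    # centers/spreads of the per-line true log10 IC50 (molar)
    log_ic50_mean: dict = field(
        default_factory=lambda: {"imatinib": -4.55, "omacetaxine": -7.4}
    )
    log_ic50_sd: dict = field(
        default_factory=lambda: {"imatinib": 0.25, "omacetaxine": 0.3}
    )
    hill: float = 1.0
    plate_noise_sd: float = 2.0  # percent-viability units on triplicates
    ct_noise_sd: float = 0.05  # cycles
    ct_reference: float = 20.0  # reference-gene CT, all conditions

    def __post_init__(self) -> None:
        total = sum(self.cluster_fractions) + self.null_fraction
        if not np.isclose(total, 1.0):
            raise ValueError(
                f"cluster_fractions + null_fraction must sum to 1, got {total}"
            )
        lo, hi = self.family_size_range
        if lo < 4 or hi < lo or self.n_families <= 0 or self.n_probes <= 0:
            raise ValueError("infeasible family/probe counts")
        for h2 in (self.h2_ic_imatinib, self.h2_ic_omacetaxine):
            if not 0 <= h2 < 1:
                raise ValueError("heritability must be in [0, 1)")


@dataclass
class GroundTruth:
    """Everything needed to score the estimators on one simulated study."""

    line_ids: list[str]  # expression lines (the assayed subset)
    log_ic50: dict  # drug -> Series over pedigree members with IC assays
    sdr: dict | None = None  # drug -> np.ndarray (filled when plates made)
    probe_cluster: np.ndarray | None = None  # 0 = null, 1..4 planted
    true_mean_ifc: np.ndarray | None = None
    true_mean_ofc: np.ndarray | None = None
    h2r: np.ndarray | None = None
    fc_ifc: np.ndarray | None = None  # probes x lines generated iFC
    fc_ofc: np.ndarray | None = None


@dataclass
class StudyData:
    pedigree: Pedigree
    assayed_ids: list[str]
    plates: dict  # drug -> list[PlateRecord]
    expression: ExpressionMatrix
    truth: GroundTruth


# ---------------------------------------------------------------------------
# pedigrees


def _nuclear_family(fam: str, size: int, rng, mz: bool) -> list[Individual]:
    f, m = f"{fam}_F", f"{fam}_M"
    members = [
        Individual(f, fam, sex=1, age=float(rng.uniform(20, 70))),
        Individual(m, fam, sex=2, age=float(rng.uniform(20, 70))),
    ]
    for c in range(size - 2):
        members.append(
            Individual(
                f"{fam}_C{c + 1}",
                fam,
                father_id=f,
                mother_id=m,
                sex=int(rng.integers(1, 3)),
                age=float(rng.uniform(20, 70)),
                mz_group=f"{fam}_mz" if mz and c < 2 else None,
            )
        )
    return members


def _three_generation_family(fam: str, size: int, rng) -> list[Individual]:
    """Grandparents, two married-in spouses, two sib parents, cousins below."""
    gf, gm = f"{fam}_GF", f"{fam}_GM"
    a, b = f"{fam}_A", f"{fam}_B"
    sa, sb = f"{fam}_SA", f"{fam}_SB"
    members = [
        Individual(gf, fam, sex=1, age=float(rng.uniform(20, 70))),
        Individual(gm, fam, sex=2, age=float(rng.uniform(20, 70))),
        Individual(a, fam, father_id=gf, mother_id=gm, sex=1,
                   age=float(rng.uniform(20, 70))),
        Individual(b, fam, father_id=gf, mother_id=gm, sex=2,
                   age=float(rng.uniform(20, 70))),
        Individual(sa, fam, sex=2, age=float(rng.uniform(20, 70))),
        Individual(sb, fam, sex=1, age=float(rng.uniform(20, 70))),
    ]
    n_grand = size - 6
    n_a = max(1, n_grand // 2)
    for g in range(n_grand):
        side = "A" if g < n_a else "B"
        father, mother = (a, sa) if side == "A" else (sb, b)
        members.append(
            Individual(
                f"{fam}_{side}G{g + 1}",
                fam,
                father_id=father,
                mother_id=mother,
                sex=int(rng.integers(1, 3)),
                age=float(rng.uniform(20, 70)),
            )
        )
    return members


def simulate_pedigrees(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Pedigree, list[str]]:
    """Generate the family structure and the assayed-line subset.

    Families of size >= 8 get a three-generation layout whose grandchildren
    form first-cousin (third-degree) pairs; smaller families are nuclear with
    sibling sets.  Family 1 carries the single MZ twin pair.  The assayed
    subset is filled round-robin over families from the descendant pool so
    it contains sibling pairs, cousin pairs and exactly one MZ pair.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.family_size_range
    members: list[Individual] = []
    pools: list[list[str]] = []  # per family: assay candidates
    for i in range(config.n_families):
        fam = f"fam{i + 1:02d}"
        size = int(rng.integers(lo, hi + 1))
        if i == 0:
            if size < 4:
                raise ValueError("MZ family needs >= 2 children")
            fam_members = _nuclear_family(fam, size, rng, mz=True)
            pool = [m.individual_id for m in fam_members if not m.is_founder]
        elif size >= 8:
            fam_members = _three_generation_family(fam, size, rng)
            pool = [m.individual_id for m in fam_members if not m.is_founder]
            # grandchildren (cousins) first so they enter the assayed subset
            pool.sort(key=lambda iid: ("G" not in iid.split("_")[1], iid))
        else:
            fam_members = _nuclear_family(fam, size, rng, mz=False)
            pool = [m.individual_id for m in fam_members if not m.is_founder]
        members.extend(fam_members)
        pools.append(pool)

    total = sum(len(p) for p in pools)
    if config.n_assayed > total:
        raise ValueError(
            f"n_assayed = {config.n_assayed} exceeds {total} assayable descendants"
        )
    assayed: list[str] = []
    depth = 0
    while len(assayed) < config.n_assayed:
        for pool in pools:
            if depth < len(pool) and len(assayed) < config.n_assayed:
                assayed.append(pool[depth])
        depth += 1
    return Pedigree(members), assayed


# ---------------------------------------------------------------------------
# traits


def _polygenic_deviates(
    K: KinshipMatrix, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Standardized draws g ~ MVN(0, 2*Phi), shape (n_individuals, n_draws)."""
    lam, U = np.linalg.eigh(K.relatedness)
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal((lam.size, n_draws))
    return U @ (np.sqrt(lam)[:, None] * z)


def simulate_polygenic_trait(
    K: KinshipMatrix,
    h2: float,
    mean: float = 0.0,
    total_var: float = 1.0,
    X: np.ndarray | None = None,
    beta: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Trait y = mean + X beta + g + e with Var(g) = h2 * total_var * 2*Phi."""
    if not 0 <= h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(K.ids)
    g = np.sqrt(h2 * total_var) * _polygenic_deviates(K, 1, rng)[:, 0]
    e = rng.normal(0.0, np.sqrt((1.0 - h2) * total_var), size=n)
    y = mean + g + e
    if X is not None and beta is not None:
        y = y + np.asarray(X, float) @ np.asarray(beta, float)
    return y


# ---------------------------------------------------------------------------
# plates


def _absorbance_for_viability(v: float) -> float:
    """abs570 making the viability equation return v at abs600 = 0.4."""
    den = COEF_570 * 0.8 - COEF_600 * 0.4
    return (v / 100.0 * den + COEF_600 * 0.4) / COEF_570


def simulate_plate_data(
    line_ids,
    true_log_ic50,
    drug: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[PlateRecord]:
    """Triplicate plate absorbances along the study dose grid for one drug.

    Viability follows a 4PL (bottom 0, top 100, configured hill) at each
    line's true log IC50.  Untreated wells sit at (0.8, 0.4); treated wells
    keep abs600 = 0.4 and solve the viability equation for abs570, so with
    zero noise the assay pipeline inverts the generator exactly.  Triplicate
    abs570 noise is scaled so its effect on viability has standard deviation
    ``plate_noise_sd`` percent; viability targets below 0.5% are clipped.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    doses = np.asarray(config.dose_grids[drug], dtype=float)
    true_log_ic50 = np.asarray(true_log_ic50, dtype=float)
    den = COEF_570 * 0.8 - COEF_600 * 0.4
    sd_abs = config.plate_noise_sd / 100.0 * den / COEF_570
    records: list[PlateRecord] = []
    for li, line in enumerate(line_ids):
        for rep in range(3):
            records.append(
                PlateRecord(line, "none", 0.0, rep + 1, 0.8, 0.4)
            )
        for dose in doses:
            v = float(four_pl(np.log10(dose), 0.0, 100.0, true_log_ic50[li],
                              config.hill))
            v = max(v, 0.5)
            base570 = _absorbance_for_viability(v)
            for rep in range(3):
                a570 = base570 + (rng.normal(0.0, sd_abs) if sd_abs > 0 else 0.0)
                records.append(
                    PlateRecord(line, drug, float(dose), rep + 1,
                                max(a570, 1e-6), 0.4)
                )
    return records


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    K: KinshipMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Probe x sample intensities with a planted (iFC, oFC) cluster structure.

    Per probe: a cluster (or null) is drawn; its true mean fold-change pair
    is the cluster center plus isotropic scatter (``probe_scatter_sd``).
    Per line: the fold change is the probe mean plus a kinship-correlated
    polygenic deviation (per-probe heritability drawn from ``h2r_range``)
    plus iid noise, totalling variance ``fc_noise_sd**2``.  Untreated
    intensities are lognormal around a per-probe baseline; treated
    intensities equal untreated times 2^FC, so fold changes recomputed from
    the matrix reproduce the generated ones exactly (before normalization).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    line_ids = list(K.ids)
    n_lines = len(line_ids)
    n_probes = config.n_probes

    probs = np.array([config.null_fraction, *config.cluster_fractions])
    cluster = rng.choice(len(probs), size=n_probes, p=probs / probs.sum())
    centers = np.asarray(config.cluster_centers, dtype=float)
    true_means = np.zeros((n_probes, 2))
    planted = cluster > 0
    true_means[planted] = centers[cluster[planted] - 1]
    true_means[planted] += rng.normal(
        0.0, config.probe_scatter_sd, size=(planted.sum(), 2)
    )
    h2r = rng.uniform(*config.h2r_range, size=n_probes)

    fcs = {}
    for d, drug in enumerate(("ifc", "ofc")):
        g = _polygenic_deviates(K, n_probes, rng)  # lines x probes, Var = 2Phi
        e = rng.standard_normal((n_lines, n_probes))
        dev = config.fc_noise_sd * (
            np.sqrt(h2r)[None, :] * g + np.sqrt(1.0 - h2r)[None, :] * e
        )
        fcs[drug] = (true_means[:, d][None, :] + dev).T  # probes x lines

    base = 2.0 ** rng.normal(8.0, 1.5, size=n_probes)
    wobble = 2.0 ** rng.normal(0.0, 0.1, size=(n_probes, n_lines))
    untreated = base[:, None] * wobble
    imat = untreated * 2.0 ** fcs["ifc"]
    omac = untreated * 2.0 ** fcs["ofc"]

    sample_ids, cols = [], []
    for j, line in enumerate(line_ids):
        sample_ids += [f"{line}:untreated", f"{line}:imatinib", f"{line}:omacetaxine"]
        cols += [untreated[:, j], imat[:, j], omac[:, j]]
    matrix = ExpressionMatrix(
        probe_ids=[f"probe{i + 1:05d}" for i in range(n_probes)],
        sample_ids=sample_ids,
        intensities=np.column_stack(cols),
    )
    truth = GroundTruth(
        line_ids=line_ids,
        log_ic50={},
        probe_cluster=cluster,
        true_mean_ifc=true_means[:, 0],
        true_mean_ofc=true_means[:, 1],
        h2r=h2r,
        fc_ifc=fcs["ifc"],
        fc_ofc=fcs["ofc"],
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# qPCR


def simulate_ct(
    fc_truth: pd.DataFrame,
    reference_gene: str = "HPRT1",
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[CTRecord]:
    """CT triplicates consistent with given fold changes.

    ``fc_truth`` has columns sample_id, gene, condition, fc (log2).  The
    target gene's untreated CT is a per-(sample, gene) baseline; its treated
    CT is baseline - fc (perfect doubling), and the reference gene sits at a
    constant CT in every condition, so the noiseless ddCT pipeline returns
    rq = 2^fc exactly.
    """
    if config is None:
        config = SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sd = config.ct_noise_sd
    records: list[CTRecord] = []
    baselines: dict[tuple[str, str], float] = {}
    ref_done: set[tuple[str, str]] = set()

    def emit(sample, gene, condition, ct):
        reps = tuple(float(ct + (rng.normal(0, sd) if sd > 0 else 0.0))
                     for _ in range(3))
        records.append(CTRecord(sample, gene, condition, reps))

    for row in fc_truth.itertuples():
        key = (row.sample_id, row.gene)
        if key not in baselines:
            baselines[key] = float(rng.uniform(22, 28))
            emit(row.sample_id, row.gene, "untreated", baselines[key])
        emit(row.sample_id, row.gene, row.condition, baselines[key] - row.fc)
        for cond in ("untreated", row.condition):
            rkey = (row.sample_id, cond)
            if rkey not in ref_done:
                ref_done.add(rkey)
                emit(row.sample_id, reference_gene, cond, config.ct_reference)
    return records


# ---------------------------------------------------------------------------
# whole study


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate pedigree, plates for both drugs, and expression in one call."""
    from .pedigree import kinship_matrix

    rng = np.random.default_rng(config.seed)
    ped, assayed = simulate_pedigrees(config, rng)
    K_all = kinship_matrix(ped)
    # IC traits are measured on (nearly) all pedigree members
    log_ic50 = {}
    plates = {}
    for drug, h2 in (
        ("imatinib", config.h2_ic_imatinib),
        ("omacetaxine", config.h2_ic_omacetaxine),
    ):
        trait = simulate_polygenic_trait(K_all, h2, rng=rng)
        log_ic50[drug] = (
            config.log_ic50_mean[drug] + config.log_ic50_sd[drug] * trait
        )
        plates[drug] = simulate_plate_data(K_all.ids, log_ic50[drug], drug,
                                           config, rng)
    K_assayed = kinship_matrix(ped, assayed)
    expression, truth = simulate_expression(K_assayed, config, rng)
    # IC truths are indexed over all pedigree members; expression-level
    # truths (line_ids, fc arrays) stay aligned with the assayed subset
    truth.log_ic50 = {
        d: pd.Series(v, index=K_all.ids) for d, v in log_ic50.items()
    }
    return StudyData(
        pedigree=ped,
        assayed_ids=assayed,
        plates=plates,
        expression=expression,
        truth=truth,
    )
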