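"""Maximum-likelihood variance-component models on pedigree data.

Two nested models for a quantitative trait y measured on pedigree members:

  sporadic:   y = m + X beta + e,            e ~ N(0, sigma2_e I)
  polygenic:  y = mu + X beta + g + e,       g ~ N(0, sigma2_g 2*Phi)

where 2*Phi is the relatedness matrix.  The narrow-sense heritability is
h2 = sigma2_g / (sigma2_g + sigma2_e).  Fitting is by full maximum
likelihood: a single eigendecomposition of 2*Phi rotates the model to
independent coordinates, after which (mean, beta, total variance) have
closed-form profile estimates for any candidate h2 and the likelihood is
maximized over h2 alone by a grid plus bounded scalar search.

Heritability is tested by a likelihood-ratio test of the polygenic model
against the sporadic one.  Because sigma2_g = 0 lies on the boundary of the
parameter space, the null distribution of the statistic is the 50:50
mixture of a point mass at zero and chi-square with 1 df, so a statistic of
exactly 0 yields p = 0.5.  Tests of interior parameters (the trait mean, or
the coefficient of a covariate such as differential expression) use the
plain chi-square(1) reference.

Traits are inverse-normal transformed (Blom ranks) before heritability
testing, mirroring standard practice for non-normal cellular phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import KinshipMatrix

__all__ = [
    "TraitVector",
    "CovariateMatrix",
    "VCFit",
    "LRTResult",
    "DegenerateTraitError",
    "PolygenicModel",
    "inverse_normal_transform",
    "covariate_matrix",
    "fit_polygenic",
    "fit_sporadic",
    "lrt",
    "heritability_test",
    "mean_fc_test",
    "fc_sdr_association",
]

#: convergence tolerance on h2 in the 1-D profile search
H2_TOL = 1e-8
#: upper clamp keeping sigma2_e strictly positive
H2_MAX = 1.0 - 1e-6

COVARIATE_COLUMNS = ["age", "sex", "age_sex", "age2", "age2_sex"]


class DegenerateTraitError(ValueError):
    """Trait has (numerically) zero variance; no model can be fitted."""


@dataclass
class TraitVector:
    ids: list[str]
    values: np.ndarray
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait values must be finite")


@dataclass
class CovariateMatrix:
    """Fixed-order study covariates: age, sex, age*sex, age^2, age^2*sex."""

    ids: list[str]
    values: np.ndarray  # shape (n, 5)
    columns: list[str] = field(default_factory=lambda: list(COVARIATE_COLUMNS))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.columns)


@dataclass
class VCFit:
    mean: float
    beta: np.ndarray
    sigma2_g: float
    sigma2_e: float
    loglik: float
    model: str  # "sporadic" | "polygenic"
    n: int
    boundary: bool = False  # h2 estimate pinned at 0 or the upper clamp

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return 0.0 if tot == 0 else self.sigma2_g / tot


@dataclass
class LRTResult:
    statistic: float
    df: int
    boundary: bool
    p: float


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    value -> Phi^-1((rank - 3/8) / (n + 1/4)); ties get average ranks so
    tied inputs map to equal outputs.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two values")
    if np.ptp(values) == 0:
        raise DegenerateTraitError("all trait values identical")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def covariate_matrix(ids, age, sex) -> CovariateMatrix:
    """Build the five-column study covariate matrix.

    ``sex`` is coded 0/1 (1 = male).  Individuals with missing age or sex
    are dropped with a warning.
    """
    ids = list(ids)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    keep = np.isfinite(age) & np.isfinite(sex)
    if not keep.all():
        dropped = [i for i, k in zip(ids, keep) if not k]
        warnings.warn(f"dropping individuals with missing age/sex: {dropped}")
        ids = [i for i, k in zip(ids, keep) if k]
        age, sex = age[keep], sex[keep]
    cols = np.column_stack([age, sex, age * sex, age**2, age**2 * sex])
    return CovariateMatrix(ids=ids, values=cols)


# ---------------------------------------------------------------------------
# profile-likelihood machinery


def _design(
    X: CovariateMatrix | np.ndarray | None,
    n: int,
    include_intercept: bool,
    extra: np.ndarray | None = None,
) -> np.ndarray:
    # Covariate columns are mean-centered at fit time.  This leaves their
    # coefficients and all coefficient tests unchanged but makes the
    # intercept the covariate-adjusted trait mean, so constraining it to
    # zero tests the mean itself.  Uncentered age/age^2 columns nearly span
    # the constant vector and would let the no-intercept model absorb any
    # mean shift.
    blocks = []
    if include_intercept:
        blocks.append(np.ones((n, 1)))
    if X is not None:
        vals = X.values if isinstance(X, CovariateMatrix) else np.asarray(X, float)
        if vals.ndim == 1:
            vals = vals[:, None]
        blocks.append(vals - vals.mean(axis=0))
    if extra is not None:
        ex = np.asarray(extra, float).reshape(n, -1)
        blocks.append(ex - ex.mean(axis=0))
    if not blocks:
        blocks.append(np.zeros((n, 0)))
    M = np.hstack(blocks)
    if M.shape[1] and np.linalg.matrix_rank(M) < M.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    return M


def _profile_loglik(h2: float, yt: np.ndarray, Mt: np.ndarray, lam: np.ndarray):
    """ML log-likelihood at fixed h2, profiling mean/beta/total variance."""
    n = yt.shape[0]
    w = h2 * lam + (1.0 - h2)
    if np.any(w <= 0):
        return -np.inf, None, None
    sw = 1.0 / np.sqrt(w)
    Mw = Mt * sw[:, None]
    yw = yt * sw
    if Mt.shape[1]:
        beta, *_ = np.linalg.lstsq(Mw, yw, rcond=None)
        resid = yw - Mw @ beta
    else:
        beta = np.zeros(0)
        resid = yw
    rss = float(resid @ resid)
    if rss <= 0:
        return -np.inf, None, None
    s2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + np.sum(np.log(w)) + n)
    return ll, beta, s2


class PolygenicModel:
    """Polygenic fitter with the kinship eigendecomposition precomputed.

    Reuse one instance to fit many traits (e.g. per-probe fold changes) on
    the same set of individuals without re-decomposing 2*Phi.
    """

    def __init__(self, K: KinshipMatrix, ids: list[str] | None = None):
        rel = K.relatedness
        if ids is not None:
            idx = [K.ids.index(i) for i in ids]
            rel = rel[np.ix_(idx, idx)]
            self.ids = list(ids)
        else:
            self.ids = list(K.ids)
        lam, U = np.linalg.eigh(rel)
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        self.n = rel.shape[0]
        if np.max(np.abs(rel - np.eye(self.n))) < 1e-12:
            warnings.warn(
                "relatedness matrix is the identity: heritability is not "
                "identifiable", stacklevel=2,
            )

    def fit(
        self,
        y: np.ndarray,
        X: CovariateMatrix | np.ndarray | None = None,
        *,
        include_intercept: bool = True,
        extra: np.ndarray | None = None,
        h2_hint: float | None = None,
    ) -> VCFit:
        y = np.asarray(y, dtype=float)
        if y.shape[0] != self.n:
            raise ValueError("trait length does not match kinship dimension")
        if np.ptp(y) == 0:
            raise DegenerateTraitError("all trait values identical")
        M = _design(X, self.n, include_intercept, extra)
        if self.n <= M.shape[1]:
            raise np.linalg.LinAlgError(
                f"n = {self.n} <= number of fixed effects ({M.shape[1]})"
            )
        yt = self.U.T @ y
        Mt = self.U.T @ M

        def negll(h2):
            return -_profile_loglik(h2, yt, Mt, self.lam)[0]

        # Deterministic local search: coarse grid then bounded refinement in
        # the bracket around the best grid point.  The grid deliberately
        # stops at 0.9; the bracket extends to the upper clamp only when 0.9
        # itself is best, so the estimate can reach the clamp for strongly
        # familial traits.  A singular relatedness matrix (e.g. an exact
        # monozygotic pair) makes the ML surface diverge as h2 -> 1 whenever
        # a fixed effect can interpolate the zero-variance contrast; that
        # clamp-dependent spike is a known ML degeneracy, and this local
        # policy (like reference variance-component tools) does not chase it.
        grid = np.arange(0.0, 1.0, 0.1)
        vals = [negll(h) for h in grid]
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[k + 1] if k + 1 < len(grid) else H2_MAX
        if lo == hi:
            h2_hat, best_negll = float(lo), float(vals[k])
        else:
            res = optimize.minimize_scalar(
                negll, bounds=(lo, hi), method="bounded",
                options={"xatol": H2_TOL},
            )
            if res.fun <= vals[k]:
                h2_hat, best_negll = float(res.x), float(res.fun)
            else:
                h2_hat, best_negll = float(grid[k]), float(vals[k])
        if h2_hint is not None and abs(h2_hint - h2_hat) > H2_TOL:
            # a singular relatedness matrix (e.g. a monozygotic pair) can
            # carve a narrow likelihood mode near h2 = 1 that the coarse
            # grid misses; a hint from a nested companion fit locates it
            hlo = max(0.0, h2_hint - 0.1)
            hhi = min(H2_MAX, h2_hint + 0.1)
            res = optimize.minimize_scalar(
                negll, bounds=(hlo, hhi), method="bounded",
                options={"xatol": H2_TOL},
            )
            cand = min(
                (float(res.fun), float(res.x)),
                (float(negll(h2_hint)), float(h2_hint)),
            )
            if cand[0] < best_negll:
                best_negll, h2_hat = cand[0], cand[1]
        h2_hat = float(np.clip(h2_hat, 0.0, H2_MAX))
        ll, beta, s2 = _profile_loglik(h2_hat, yt, Mt, self.lam)
        mean = float(beta[0]) if include_intercept else 0.0
        coef = beta[1:] if include_intercept else beta
        return VCFit(
            mean=mean,
            beta=np.asarray(coef),
            sigma2_g=h2_hat * s2,
            sigma2_e=(1.0 - h2_hat) * s2,
            loglik=float(ll),
            model="polygenic",
            n=self.n,
            boundary=h2_hat <= H2_TOL or h2_hat >= H2_MAX - H2_TOL,
        )


def _align(y: TraitVector, K: KinshipMatrix) -> PolygenicModel:
    missing = [i for i in y.ids if i not in K.ids]
    if missing:
        raise KeyError(f"trait ids absent from kinship matrix: {missing[:5]}")
    return PolygenicModel(K, ids=y.ids)


def fit_polygenic(
    y: TraitVector,
    X: CovariateMatrix | None,
    K: KinshipMatrix,
    *,
    include_intercept: bool = True,
    extra: np.ndarray | None = None,
) -> VCFit:
    """ML fit of the polygenic model (see module docstring)."""
    model = _align(y, K)
    return model.fit(y.values, X, include_intercept=include_intercept, extra=extra)


def fit_sporadic(
    y: TraitVector,
    X: CovariateMatrix | None,
    *,
    include_intercept: bool = True,
    extra: np.ndarray | None = None,
) -> VCFit:
    """ML fit with independent errors (sigma2_g fixed at zero)."""
    yv = np.asarray(y.values, dtype=float)
    n = yv.shape[0]
    if np.ptp(yv) == 0:
        raise DegenerateTraitError("all trait values identical")
    M = _design(X, n, include_intercept, extra)
    if n <= M.shape[1]:
        raise np.linalg.LinAlgError(f"n = {n} <= number of fixed effects")
    ll, beta, s2 = _profile_loglik(0.0, yv, M, np.ones(n))
    mean = float(beta[0]) if include_intercept else 0.0
    coef = beta[1:] if include_intercept else beta
    return VCFit(
        mean=mean,
        beta=np.asarray(coef),
        sigma2_g=0.0,
        sigma2_e=float(s2),
        loglik=float(ll),
        model="sporadic",
        n=n,
    )


def _nested_polygenic_pair(
    model: PolygenicModel,
    y: np.ndarray,
    X: CovariateMatrix | np.ndarray | None,
    full_kwargs: dict,
    con_kwargs: dict,
) -> tuple[VCFit, VCFit]:
    """Fit a nested full/constrained polygenic pair consistently.

    When the profile likelihood is multimodal (singular relatedness), the
    two fits can land on different modes, inverting the likelihood ordering.
    Each fit's h2 is offered to the other as a search hint until the full
    model dominates.
    """
    full = model.fit(y, X, **full_kwargs)
    con = model.fit(y, X, **con_kwargs)
    if abs(full.h2 - con.h2) > 0.05 or con.loglik > full.loglik:
        c2 = model.fit(y, X, h2_hint=full.h2, **con_kwargs)
        if c2.loglik > con.loglik:
            con = c2
        f2 = model.fit(y, X, h2_hint=con.h2, **full_kwargs)
        if f2.loglik > full.loglik:
            full = f2
    return full, con


def lrt(full: VCFit, constrained: VCFit, *, boundary: bool, df: int = 1) -> LRTResult:
    """Likelihood-ratio test of nested ML fits.

    With ``boundary=True`` the null is the 50:50 mixture of chi2(0) and
    chi2(df); with ``boundary=False`` it is plain chi2(df).
    """
    diff = 2.0 * (full.loglik - constrained.loglik)
    if diff < -1e-6:
        raise RuntimeError(
            f"full-model log-likelihood below constrained ({diff:.3g}): "
            "optimization failure"
        )
    statistic = max(0.0, diff)
    if boundary:
        p = 0.5 * stats.chi2.sf(statistic, df)  # sf(0) = 1 -> p = 0.5
    else:
        p = stats.chi2.sf(statistic, df)
    return LRTResult(statistic=statistic, df=df, boundary=boundary, p=float(p))


def heritability_test(
    y: TraitVector, X: CovariateMatrix | None, K: KinshipMatrix
) -> tuple[float, LRTResult]:
    """Estimate h2 and test it against zero with the boundary mixture.

    The trait is inverse-normal transformed first (unless already flagged
    transformed).
    """
    if not y.transformed:
        y = TraitVector(y.ids, inverse_normal_transform(y.values), transformed=True)
    full = fit_polygenic(y, X, K)
    constrained = fit_sporadic(y, X)
    return full.h2, lrt(full, constrained, boundary=True)


def mean_fc_test(
    fc: TraitVector,
    X: CovariateMatrix | None,
    K: KinshipMatrix,
    *,
    use_kinship: bool = True,
) -> LRTResult:
    """Test whether the covariate-adjusted mean fold change differs from 0.

    The full model estimates the mean freely; the constrained model fixes it
    at zero.  ``use_kinship=True`` (default) fits both under the polygenic
    covariance; ``False`` gives the independent-errors version.
    """
    if use_kinship:
        model = _align(fc, K)
        full, constrained = _nested_polygenic_pair(
            model, fc.values, X,
            {"include_intercept": True}, {"include_intercept": False},
        )
    else:
        full = fit_sporadic(fc, X, include_intercept=True)
        constrained = fit_sporadic(fc, X, include_intercept=False)
    return lrt(full, constrained, boundary=False)


def fc_sdr_association(
    sdr: TraitVector,
    fc: TraitVector,
    X: CovariateMatrix | None,
    K: KinshipMatrix,
) -> tuple[float, LRTResult]:
    """Association of drug sensitivity with differential expression.

    Fold change enters the polygenic model of SDR as an extra covariate;
    its coefficient is tested by constraining it to zero (plain chi2(1)).
    """
    if sdr.ids != fc.ids:
        raise ValueError("sdr and fc must be aligned on the same ids")
    fcv = np.asarray(fc.values, dtype=float)
    if np.ptp(fcv) == 0:
        raise DegenerateTraitError("fold change constant across lines: collinear")
    model = _align(sdr, K)
    full, constrained = _nested_polygenic_pair(
        model, sdr.values, X,
        {"include_intercept": True, "extra": fcv}, {"include_intercept": True},
    )
    coefficient = float(full.beta[-1])
    return coefficient, lrt(full, constrained, boundary=False)
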