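"""alamarBlue viability, 4PL dose-response fitting, IC_x and SDR extraction.

Percent viability is computed from paired 570/600 nm absorbances using the
oxidized-form molar extinction coefficients of alamarBlue (117,216 and
80,586), test wells referenced to untreated wells of the same cell line.
Dose-response curves are four-parameter logistic (4PL) in log10 dose:

    v(x) = bottom + (top - bottom) / (1 + 10^(hill * (x - log_ic50)))

with hill > 0 so that viability decreases with dose.  IC_x is the dose at
which the fitted curve crosses viability 100 - x.  The sensitivity of drug
response (SDR) is the ordinary least-squares slope of viability on log10
dose: more negative means a more sensitive cell line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AssayError",
    "FitError",
    "PlateRecord",
    "ViabilityPoint",
    "DoseResponseFit",
    "SDREstimate",
    "COEF_570",
    "COEF_600",
    "IMATINIB_DOSES",
    "OMACETAXINE_DOSES",
    "percent_viability",
    "average_replicates",
    "viability_table",
    "fit_4pl",
    "four_pl",
    "inhibitory_concentration",
    "sdr",
    "load_plates",
    "ic_table",
]

# molar extinction coefficients of oxidized alamarBlue used in the
# percent-reduction equation (numerator weight on abs570, on abs600)
COEF_570 = 117_216.0
COEF_600 = 80_586.0

# study dose grids (molar)
IMATINIB_DOSES = np.array([2, 10, 50, 75, 100, 150, 200], dtype=float) * 1e-6
OMACETAXINE_DOSES = np.array([5, 10, 25, 50, 75, 100, 500], dtype=float) * 1e-9


class AssayError(ValueError):
    """Unusable absorbance record (e.g. non-positive denominator)."""


class FitError(RuntimeError):
    """Dose-response curve could not be fitted."""


@dataclass(frozen=True)
class PlateRecord:
    line_id: str
    drug: str  # imatinib | omacetaxine | none
    dose: float  # molar, 0 for untreated
    replicate: int
    abs570: float
    abs600: float


@dataclass(frozen=True)
class ViabilityPoint:
    line_id: str
    drug: str
    dose: float
    viability: float  # percent


@dataclass
class DoseResponseFit:
    line_id: str
    drug: str
    bottom: float
    top: float
    log_ic50: float
    hill: float
    residual_sse: float
    converged: bool


@dataclass(frozen=True)
class SDREstimate:
    line_id: str
    drug: str
    slope: float  # percent viability per log10(molar)
    intercept: float
    n_points: int


def percent_viability(
    test570: float, test600: float, untreated570: float, untreated600: float
) -> float:
    """Percent reduction of alamarBlue in a test well relative to untreated."""
    num = COEF_570 * test570 - COEF_600 * test600
    den = COEF_570 * untreated570 - COEF_600 * untreated600
    if den <= 0:
        raise AssayError(f"non-positive untreated-well denominator ({den:.4g})")
    return 100.0 * num / den


def average_replicates(
    treated: list[PlateRecord], untreated: list[PlateRecord]
) -> ViabilityPoint:
    """Average replicate absorbances (before the viability equation).

    ``treated`` must be the replicates of a single (line, drug, dose) and
    ``untreated`` the untreated wells of the same line.
    """
    if not treated:
        raise AssayError("no treated records")
    if not untreated:
        raise AssayError(f"no untreated control wells for line {treated[0].line_id!r}")
    keys = {(r.line_id, r.drug, r.dose) for r in treated}
    if len(keys) != 1:
        raise ValueError(f"treated records span several (line, drug, dose): {keys}")
    line_id, drug, dose = keys.pop()
    if any(r.line_id != line_id for r in untreated):
        raise ValueError("untreated records belong to a different line")
    t570 = float(np.mean([r.abs570 for r in treated]))
    t600 = float(np.mean([r.abs600 for r in treated]))
    u570 = float(np.mean([r.abs570 for r in untreated]))
    u600 = float(np.mean([r.abs600 for r in untreated]))
    return ViabilityPoint(line_id, drug, dose, percent_viability(t570, t600, u570, u600))


def viability_table(records: list[PlateRecord]) -> list[ViabilityPoint]:
    """Collapse a full plate to one viability point per (line, drug, dose)."""
    untreated: dict[str, list[PlateRecord]] = {}
    treated: dict[tuple[str, str, float], list[PlateRecord]] = {}
    for rec in records:
        if rec.drug == "none" or rec.dose == 0:
            untreated.setdefault(rec.line_id, []).append(rec)
        else:
            treated.setdefault((rec.line_id, rec.drug, rec.dose), []).append(rec)
    points = []
    for (line_id, drug, dose), recs in sorted(treated.items()):
        points.append(average_replicates(recs, untreated.get(line_id, [])))
    return points


def four_pl(x: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float):
    """4PL viability at log10 dose ``x``."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - log_ic50)))


_BOUNDS = ([0.0, 50.0, -np.inf, 1e-6], [100.0 - 1e-9, 150.0, np.inf, 10.0])


def fit_4pl(
    points: list[ViabilityPoint], fixed_top: float | None = None
) -> DoseResponseFit:
    """Least-squares 4PL fit over a multi-start grid.

    Starts combine candidate log_ic50 values spanning the observed dose
    range with hill in {0.5, 1, 2}; the best residual wins, so the fit is
    deterministic.  Requires >= 4 distinct positive doses and an actual
    decline in viability.
    """
    pts = [p for p in points if p.dose > 0]
    doses = sorted({p.dose for p in pts})
    if len(doses) < 4:
        raise ValueError(f"need >= 4 distinct doses, got {len(doses)}")
    x = np.log10([p.dose for p in pts])
    y = np.array([p.viability for p in pts])
    if np.ptp(y) < 1e-9:
        raise FitError("constant viability across doses: no inhibition to fit")

    line_id, drug = pts[0].line_id, pts[0].drug

    if fixed_top is None:
        def resid(theta):
            return four_pl(x, *theta) - y
        lo, hi = [list(b) for b in _BOUNDS]
        def pack(b, t, l, h):
            return [b, t, l, h]
    else:
        def resid(theta):
            return four_pl(x, theta[0], fixed_top, theta[1], theta[2]) - y
        lo = [_BOUNDS[0][0], _BOUNDS[0][2], _BOUNDS[0][3]]
        hi = [_BOUNDS[1][0], _BOUNDS[1][2], _BOUNDS[1][3]]
        def pack(b, t, l, h):
            return [b, l, h]

    top0 = fixed_top if fixed_top is not None else min(max(y.max(), 50.0 + 1e-6), 150.0)
    best = None
    for lic50 in np.linspace(x.min() - 1.0, x.max() + 1.0, 7):
        for hill0 in (0.5, 1.0, 2.0):
            theta0 = pack(max(min(y.min(), 99.0), 0.0), top0, lic50, hill0)
            try:
                sol = optimize.least_squares(
                    resid, theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12
                )
            except ValueError:
                continue
            sse = float(np.sum(sol.fun**2))
            if best is None or sse < best[0]:
                best = (sse, sol)
    if best is None:
        raise FitError(f"4PL fit failed for line {line_id!r} / {drug}")
    sse, sol = best
    # unbounded Levenberg-Marquardt polish; kept only if it improves the
    # residual while staying inside the parameter bounds
    try:
        polish = optimize.least_squares(resid, sol.x, method="lm")
        sse_p = float(np.sum(polish.fun**2))
        nb = len(lo)
        in_bounds = all(
            lo[i] - 1e-9 <= polish.x[i] <= hi[i] + 1e-9 for i in range(nb)
        )
        if in_bounds and sse_p <= sse:
            polish.x = np.clip(polish.x, lo, hi)
            sse, sol = sse_p, polish
    except ValueError:
        pass
    if fixed_top is None:
        bottom, top, log_ic50, hill = sol.x
    else:
        bottom, log_ic50, hill = sol.x
        top = fixed_top
    converged = bool(sol.success)
    if not converged:
        raise FitError(
            f"4PL optimizer did not converge for line {line_id!r} / {drug}: "
            f"{sol.message}"
        )
    return DoseResponseFit(
        line_id=line_id,
        drug=drug,
        bottom=float(bottom),
        top=float(top),
        log_ic50=float(log_ic50),
        hill=float(hill),
        residual_sse=sse,
        converged=converged,
    )


def inhibitory_concentration(fit: DoseResponseFit, threshold: float) -> float:
    """Dose (molar) producing ``threshold`` percent inhibition.

    The target viability is 100 - threshold, inverted on the fitted curve;
    targets outside the open interval (bottom, top) are unattainable.
    """
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    target = 100.0 - threshold
    if not fit.bottom < target < fit.top:
        raise FitError(
            f"viability target {target} outside fitted range "
            f"({fit.bottom:.3g}, {fit.top:.3g})"
        )
    ratio = (fit.top - fit.bottom) / (target - fit.bottom) - 1.0
    return 10.0 ** (fit.log_ic50 + np.log10(ratio) / fit.hill)


def sdr(points: list[ViabilityPoint]) -> SDREstimate:
    """OLS slope of percent viability on log10 dose (treated points only)."""
    pts = [p for p in points if p.dose > 0]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 dosed points, got {len(pts)}")
    x = np.log10([p.dose for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("all doses identical: singular design")
    y = [p.viability for p in pts]
    res = stats.linregress(x, y)
    return SDREstimate(
        line_id=pts[0].line_id,
        drug=pts[0].drug,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(pts),
    )


# ---------------------------------------------------------------------------
# tabular I/O


def load_plates(path) -> list[PlateRecord]:
    """Read a plate TSV: line_id, drug, dose_molar, replicate, abs570, abs600."""
    df = pd.read_csv(path, sep="\t")
    return [
        PlateRecord(
            line_id=str(r.line_id),
            drug=str(r.drug),
            dose=float(r.dose_molar),
            replicate=int(r.replicate),
            abs570=float(r.abs570),
            abs600=float(r.abs600),
        )
        for r in df.itertuples()
    ]


def ic_table(
    records: list[PlateRecord],
    thresholds: tuple[int, ...] = tuple(range(10, 100, 10)),
) -> pd.DataFrame:
    """Per (line, drug): IC dose at each inhibition threshold plus the SDR.

    Lines whose curves cannot reach a threshold get NaN for that column.
    """
    points = viability_table(records)
    groups: dict[tuple[str, str], list[ViabilityPoint]] = {}
    for p in points:
        groups.setdefault((p.line_id, p.drug), []).append(p)
    rows = []
    for (line_id, drug), pts in sorted(groups.items()):
        fit = fit_4pl(pts)
        est = sdr(pts)
        row: dict = {"line_id": line_id, "drug": drug, "sdr": est.slope}
        for t in thresholds:
            try:
                row[f"ic{t}"] = inhibitory_concentration(fit, t)
            except FitError:
                row[f"ic{t}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
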