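"""Model fitting: 4PL in vitro potency, naive-pooled two-compartment PK,
effect-compartment PD with fixed PK, and the pooled cross-compound
normalized exposure-response Emax fit.

All fits are naive-pooled nonlinear least squares: observations from all
subjects are stacked and fitted as if they came from a single subject.  PK
is fitted on log concentrations (log-additive residual error); PD and the
pooled exposure-response use additive error on the percent-inhibition
scale.  Standard errors come from the Gauss-Newton approximation
cov = s^2 * (J'J)^-1 at the optimum, and CV% = 100*SE/|estimate|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .core import (
    CompoundRecord,
    ConcentrationSeries,
    DoseRegimen,
    PDParams,
    PDStudy,
    PKParams,
    PKStudy,
    effect_site_concentration,
    emax_effect,
    plasma_concentration,
)

__all__ = [
    "ParamEstimate",
    "FitResult",
    "FourPLFit",
    "PooledERPoint",
    "percent_inhibition_current",
    "percent_inhibition_fmri",
    "geometric_mean_sd",
    "fit_ic50_4pl",
    "fit_pk_naive_pooled",
    "fit_effect_compartment",
    "normalize_exposure",
    "fit_pooled_emax",
]

#: relative change in the objective below which the optimizer is converged
FTOL = 1e-8


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamEstimate:
    estimate: float
    se: float

    @property
    def cv_pct(self) -> float:
        """Coefficient of variation of the estimate, 100*SE/|estimate|."""
        return 100.0 * self.se / abs(self.estimate)


@dataclass
class FitResult:
    """Naive-pooled fit summary: point estimates with SE/CV%, residual
    variance, and a convergence flag."""

    params: Dict[str, ParamEstimate]
    residual_sd: float
    n_obs: int
    converged: bool
    objective: float
    message: str = ""

    def estimate(self, name: str) -> float:
        return self.params[name].estimate

    def se(self, name: str) -> float:
        return self.params[name].se

    def cv_pct(self, name: str) -> float:
        return self.params[name].cv_pct

    def to_dict(self) -> dict:
        out: dict = {
            "residual_sd": self.residual_sd,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "objective": self.objective,
            "message": self.message,
        }
        for name, p in self.params.items():
            out[name] = p.estimate
            out[f"{name}_se"] = p.se
            out[f"{name}_cv_pct"] = p.cv_pct
        return out


@dataclass
class FourPLFit:
    """Four-parameter-logistic potency fit; asymptotes fixed to 0/100 by
    default so only IC50 and the Hill coefficient are estimated."""

    ic50: float
    hill: float
    imin: float
    imax: float
    ic50_se: float
    hill_se: float
    residual_sd: float
    converged: bool
    n_obs: int


@dataclass(frozen=True)
class PooledERPoint:
    """One animal's pooled exposure-response point: the dimensionless
    unbound, potency-normalized exposure Cp*fu_p/IC50 against the mean
    percent inhibition over the infusion hour."""

    compound_id: str
    subject_id: str
    normalized_exposure: float
    mean_effect: float

    def __post_init__(self) -> None:
        if self.normalized_exposure < 0:
            raise ValueError("normalized_exposure must be >= 0")


# ---------------------------------------------------------------------------
# elementary endpoint transforms
# ---------------------------------------------------------------------------


def percent_inhibition_current(i_control: float, i_drug: float) -> float:
    """Percent inhibition of sodium-channel current relative to the
    pre-compound control sweep."""
    if i_control <= 0:
        raise ValueError("control current must be positive")
    return 100.0 * (i_control - i_drug) / i_control


def percent_inhibition_fmri(baseline_responses: Sequence[float], response: float) -> float:
    """Percent inhibition of an fMRI response relative to the mean of the
    pre-dose baseline responses; values beyond the baseline go negative."""
    baseline = np.asarray(baseline_responses, dtype=float)
    if baseline.size == 0:
        raise ValueError("at least one baseline response is required")
    mean_baseline = float(baseline.mean())
    if mean_baseline <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (mean_baseline - response) / mean_baseline


def geometric_mean_sd(values: Sequence[float]) -> Tuple[float, float]:
    """Geometric mean and geometric SD (exp of mean/SD of logs)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    if np.any(v <= 0):
        raise ValueError("geometric statistics require strictly positive values")
    logs = np.log(v)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if v.size > 1 else 1.0
    return gm, gsd


def normalize_exposure(cp: float, compound: CompoundRecord) -> float:
    """Dimensionless exposure: unbound plasma concentration divided by the
    in vitro potency, cp * fu_p / IC50."""
    if cp < 0:
        raise ValueError("cp must be >= 0")
    return cp * compound.fu_p / compound.ic50_invitro


# ---------------------------------------------------------------------------
# shared least-squares machinery
# ---------------------------------------------------------------------------


def _gauss_newton_se(jac: np.ndarray, residuals: np.ndarray, n_params: int) -> np.ndarray:
    """SEs of the fitted parameters from the residual-variance-scaled
    inverse Gramian (J'J)^-1 at the optimum."""
    n = residuals.size
    dof = max(n - n_params, 1)
    s2 = float(residuals @ residuals) / dof
    jtj = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(jtj)
    var = np.clip(np.diag(cov), 0.0, None)
    return np.sqrt(var)


def _multistart_least_squares(
    residual_fn,
    starts: Iterable[np.ndarray],
    bounds: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    n_local: int = 3,
):
    """Rank candidate start points by objective, run a derivative-based
    local solve from the best few, and return the overall best solution."""
    starts = [np.asarray(s, dtype=float) for s in starts]
    scored = []
    for s in starts:
        try:
            r = residual_fn(s)
            scored.append((float(r @ r), s))
        except (ValueError, FloatingPointError):
            continue
    if not scored:
        raise ValueError("no feasible start point")
    scored.sort(key=lambda t: t[0])
    best = None
    kwargs = {"ftol": FTOL, "xtol": 1e-12, "gtol": 1e-12}
    if bounds is not None:
        kwargs["bounds"] = bounds
    for _, s in scored[:n_local]:
        try:
            sol = least_squares(residual_fn, s, **kwargs)
        except (ValueError, FloatingPointError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all local solves failed")
    return best


def _log_grid(center: float, n: int = 5, decades: float = 2.0) -> np.ndarray:
    """n log-spaced values centered on ``center`` spanning +-decades."""
    return center * np.logspace(-decades / 2, decades / 2, n)


# ---------------------------------------------------------------------------
# 4PL potency fit
# ---------------------------------------------------------------------------


def _four_pl(x: np.ndarray, ic50: float, hill: float, imin: float, imax: float) -> np.ndarray:
    return imin + (imax - imin) / (1.0 + (ic50 / x) ** hill)


def fit_ic50_4pl(
    concentrations: Sequence[float],
    inhibitions: Sequence[float],
    fix_asymptotes: bool = True,
    imin: float = 0.0,
    imax: float = 100.0,
) -> FourPLFit:
    """Least-squares 4-parameter-logistic fit of percent inhibition against
    concentration; with asymptotes fixed the free parameters are IC50 and
    the Hill coefficient, both fitted on the log scale.

    Emits a non-convergence warning when the data never cross 50 %
    inhibition, since IC50 is then an extrapolation.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(inhibitions, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and inhibitions must be 1-d, equal length")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if not fix_asymptotes:
        raise NotImplementedError("only fixed-asymptote (Imin=0, Imax=100) fits are supported")

    bracketed = bool(y.min() < (imin + imax) / 2 < y.max())

    def residual(theta: np.ndarray) -> np.ndarray:
        ic50, hill = np.exp(theta)
        return _four_pl(x, ic50, hill, imin, imax) - y

    geo_x = float(np.exp(np.mean(np.log(x))))
    starts = [
        np.log([ic, h])
        for ic in _log_grid(geo_x, n=5, decades=np.log10(x.max() / x.min()) + 2)
        for h in (0.5, 1.0, 2.0)
    ]
    sol = _multistart_least_squares(residual, starts)
    ic50, hill = np.exp(sol.x)
    se_log = _gauss_newton_se(sol.jac, sol.fun, 2)
    n = x.size
    rsd = float(np.sqrt(2 * sol.cost / max(n - 2, 1)))
    converged = bool(sol.success) and bracketed
    if not bracketed:
        warnings.warn(
            "inhibition data do not bracket 50%; IC50 is extrapolated", stacklevel=2
        )
    return FourPLFit(
        ic50=float(ic50),
        hill=float(hill),
        imin=imin,
        imax=imax,
        ic50_se=float(se_log[0] * ic50),
        hill_se=float(se_log[1] * hill),
        residual_sd=rsd,
        converged=converged,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# naive-pooled two-compartment PK fit
# ---------------------------------------------------------------------------


def _pk_predictions(pk: PKParams, studies: Sequence[PKStudy]) -> np.ndarray:
    preds = [
        plasma_concentration(pk, st.regimen, st.series.times).values for st in studies
    ]
    return np.concatenate(preds)


def _naive_pk_init(studies: Sequence[PKStudy]) -> PKParams:
    """Crude moment-based initial values: V from back-extrapolated C0, CL
    from dose over trapezoidal AUC."""
    total_dose = 0.0
    total_auc = 0.0
    cmax = 0.0
    for st in studies:
        total_dose += sum(e.amount * (e.F or 1.0) for e in st.regimen.events)
        t, c = st.series.times, st.series.values
        total_auc += float(np.trapezoid(c, t))
        if c[-1] > 0 and c.size >= 2 and c[-2] > c[-1] > 0:
            lz = np.log(c[-2] / c[-1]) / (t[-1] - t[-2])
            if lz > 0:
                total_auc += float(c[-1] / lz)
        cmax = max(cmax, float(c.max()))
    n = len(studies)
    mean_dose = total_dose / n
    cl = mean_dose / (total_auc / n) if total_auc > 0 else 1.0
    v = mean_dose / cmax if cmax > 0 else 1.0
    return PKParams(CL=max(cl, 1e-6), V=max(v, 1e-6), CL2=max(cl, 1e-6), V2=2 * max(v, 1e-6))


def fit_pk_naive_pooled(
    studies: Sequence[PKStudy],
    init: Optional[PKParams] = None,
) -> FitResult:
    """Fit CL, V, CL2, V2 to pooled plasma observations by minimizing the
    sum of squared log residuals (log-additive error).

    Observations must be strictly positive; below-quantification values are
    excluded upstream.  Multi-start: a 5-point log grid around the initial
    values is scored and the best candidates are polished locally.
    """
    if not studies:
        raise ValueError("need at least one PK study")
    n_obs = sum(st.series.times.size for st in studies)
    if n_obs < 6:
        raise ValueError("need at least 6 pooled observations to fit 4 PK parameters")
    obs = np.concatenate([st.series.values for st in studies])
    if np.any(obs <= 0):
        raise ValueError("all concentrations must be positive (remove BLQ upstream)")
    log_obs = np.log(obs)

    def residual(theta: np.ndarray) -> np.ndarray:
        pk = PKParams(*np.exp(theta))
        pred = _pk_predictions(pk, studies)
        if np.any(pred <= 0):
            # push optimizer away from parameter sets predicting zeros
            pred = np.maximum(pred, 1e-300)
        return np.log(pred) - log_obs

    base = init or _naive_pk_init(studies)
    center = np.log([base.CL, base.V, base.CL2, base.V2])
    grid_1d = np.log(np.array([0.1, 0.316, 1.0, 3.16, 10.0]))
    rng_starts = [center + np.array([a, b, c, d])
                  for a in grid_1d for b in grid_1d for c in grid_1d for d in grid_1d]
    try:
        sol = _multistart_least_squares(residual, [center] + rng_starts, n_local=3)
    except (RuntimeError, ValueError) as exc:
        return FitResult({}, float("nan"), n_obs, False, float("nan"), f"fit failed: {exc}")

    est = np.exp(sol.x)
    se_log = _gauss_newton_se(sol.jac, sol.fun, 4)
    rsd = float(np.sqrt(2 * sol.cost / max(n_obs - 4, 1)))
    names = ("CL", "V", "CL2", "V2")
    params = {
        nm: ParamEstimate(float(e), float(sl * e)) for nm, e, sl in zip(names, est, se_log)
    }
    return FitResult(params, rsd, n_obs, bool(sol.success), float(2 * sol.cost), sol.message)


# ---------------------------------------------------------------------------
# effect-compartment PD fit (fixed PK)
# ---------------------------------------------------------------------------


def _pd_predictions(
    ec50: float, ke0: float, studies: Sequence[PDStudy], e0: float, emax: float
) -> np.ndarray:
    pd = PDParams(EC50=ec50, ke0=ke0, E0=e0, Emax=emax)
    preds = []
    for st in studies:
        ce = effect_site_concentration(st.pk, ke0, st.regimen, st.effects.times).values
        preds.append(emax_effect(pd, ce))
    return np.concatenate(preds)


def fit_effect_compartment(
    pd_studies: Sequence[PDStudy],
    init: Optional[PDParams] = None,
    e0: float = 0.0,
    emax: float = 100.0,
) -> FitResult:
    """Naive-pooled additive-error fit of the effect-compartment Emax model.

    PK parameters are fixed per study (from the satellite PK fit); the free
    parameters are EC50 and ke0, fitted on the log scale, with E0 and Emax
    fixed (0 and 100 % by default).
    """
    if not pd_studies:
        raise ValueError("need at least one PD study")
    obs = np.concatenate([st.effects.values for st in pd_studies])
    n_obs = int(obs.size)
    if float(np.max(obs)) < 10.0:
        warnings.warn(
            "all observed effects are below 10%; EC50 is poorly identified",
            stacklevel=2,
        )

    def residual(theta: np.ndarray) -> np.ndarray:
        ec50, ke0 = np.exp(theta)
        return _pd_predictions(ec50, ke0, pd_studies, e0, emax) - obs

    # data-informed EC50 grid: plateau plasma concentrations set the scale
    cmax = 0.0
    for st in pd_studies:
        cp = plasma_concentration(st.pk, st.regimen, st.effects.times).values
        cmax = max(cmax, float(cp.max()))
    cmax = cmax or 1.0
    ec50_grid = cmax * np.array([0.03, 0.2, 1.0, 5.0, 30.0])
    ke0_grid = np.array([0.1, 0.3, 1.0, 3.0, 10.0])
    starts = [np.log([a, b]) for a in ec50_grid for b in ke0_grid]
    if init is not None:
        starts.insert(0, np.log([init.EC50, init.ke0]))
    try:
        sol = _multistart_least_squares(residual, starts, n_local=3)
    except (RuntimeError, ValueError) as exc:
        return FitResult({}, float("nan"), n_obs, False, float("nan"), f"fit failed: {exc}")

    ec50, ke0 = np.exp(sol.x)
    se_log = _gauss_newton_se(sol.jac, sol.fun, 2)
    rsd = float(np.sqrt(2 * sol.cost / max(n_obs - 2, 1)))
    params = {
        "EC50": ParamEstimate(float(ec50), float(se_log[0] * ec50)),
        "ke0": ParamEstimate(float(ke0), float(se_log[1] * ke0)),
    }
    return FitResult(params, rsd, n_obs, bool(sol.success), float(2 * sol.cost), sol.message)


# ---------------------------------------------------------------------------
# pooled cross-compound exposure-response fit
# ---------------------------------------------------------------------------


def fit_pooled_emax(
    points: Sequence[PooledERPoint],
    e0: float = 0.0,
    emax: float = 100.0,
) -> FitResult:
    """Single-parameter Emax fit of pooled normalized exposure-response.

    The estimated dimensionless EC50 is the in vitro to in vivo scaling
    factor: the multiple of the in vitro IC50 that the unbound plasma
    concentration must reach for a half-maximal response.
    """
    if len(points) < 10:
        raise ValueError("need at least 10 pooled exposure-response points")
    x = np.array([p.normalized_exposure for p in points], dtype=float)
    y = np.array([p.mean_effect for p in points], dtype=float)
    pos = x[x > 0]
    if pos.size == 0 or pos.min() >= 1.0 or pos.max() <= 1.0:
        warnings.warn(
            "normalized exposures do not span unity; scaling factor is poorly identified",
            stacklevel=2,
        )

    def residual(theta: np.ndarray) -> np.ndarray:
        ec50 = float(np.exp(theta[0]))
        return e0 + emax * x / (ec50 + x) - y

    lo = pos.min() / 10 if pos.size else 0.01
    hi = pos.max() * 10 if pos.size else 100.0
    starts = [np.array([v]) for v in np.log(np.geomspace(lo, hi, 9))]
    sol = _multistart_least_squares(residual, starts, n_local=3)
    ec50 = float(np.exp(sol.x[0]))
    se = float(_gauss_newton_se(sol.jac, sol.fun, 1)[0] * ec50)
    n = x.size
    rsd = float(np.sqrt(2 * sol.cost / max(n - 1, 1)))
    return FitResult(
        {"EC50": ParamEstimate(ec50, se)},
        rsd,
        int(n),
        bool(sol.success),
        float(2 * sol.cost),
        sol.message,
    )
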