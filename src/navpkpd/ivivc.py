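"""In vitro - in vivo correlation (IVIVC).

Fitted in vivo total-plasma EC50 values are corrected for plasma protein
binding (unbound EC50 = total EC50 * fu_p), compounds whose EC50 or ke0
estimates are too imprecise are removed by a CV% filter, and the remaining
unbound in vivo potencies are regressed on the intrinsic in vitro IC50s.
A slope near unity with the intercept through zero in log space indicates
that the unbound in vivo potency equals the in vitro potency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["IVIVCPair", "IVIVCResult", "unbound_ec50", "filter_by_cv", "ivivc_regression"]

logger = logging.getLogger(__name__)


def unbound_ec50(ec50_total: float, fu_p: float) -> float:
    """Unbound in vivo potency: total-plasma EC50 times fraction unbound."""
    if ec50_total <= 0 or fu_p <= 0:
        raise ValueError("ec50_total and fu_p must be positive")
    return ec50_total * fu_p


@dataclass(frozen=True)
class IVIVCPair:
    """One compound's in vitro / in vivo potency pair with the CV% of the
    underlying effect-compartment estimates."""

    compound_id: str
    invitro_ic50: float
    invivo_ec50_total: float
    fu_p: float
    ec50_cv: Optional[float] = None
    ke0_cv: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("invitro_ic50", "invivo_ec50_total", "fu_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def invivo_ec50_unbound(self) -> float:
        return unbound_ec50(self.invivo_ec50_total, self.fu_p)


@dataclass(frozen=True)
class IVIVCResult:
    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    included_ids: tuple
    regression_space: str

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
            "included_ids": list(self.included_ids),
            "regression_space": self.regression_space,
        }


def filter_by_cv(fits: pd.DataFrame, threshold: float = 50.0) -> List[str]:
    """Keep compounds whose EC50 and ke0 CV% are both within the threshold.

    ``fits`` needs columns ``compound_id``, ``ec50_cv_pct`` and
    ``ke0_cv_pct`` (the layout of
    :func:`navpkpd.tables.reference_effect_compartment_table`).  The
    comparison is inclusive: a CV printed exactly at the threshold passes.
    Compounds with a missing CV are excluded and the reason is logged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    required = {"compound_id", "ec50_cv_pct", "ke0_cv_pct"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fits table is missing columns: {sorted(missing)}")
    included: List[str] = []
    for row in fits.itertuples(index=False):
        cid = str(row.compound_id)
        cvs = (row.ec50_cv_pct, row.ke0_cv_pct)
        if any(cv is None or (isinstance(cv, float) and math.isnan(cv)) for cv in cvs):
            logger.info("IVIVC filter: compound %s excluded (missing CV%%)", cid)
            continue
        if all(cv <= threshold for cv in cvs):
            included.append(cid)
        else:
            logger.info(
                "IVIVC filter: compound %s excluded (EC50 CV %.3g%%, ke0 CV %.3g%%, limit %g%%)",
                cid, cvs[0], cvs[1], threshold,
            )
    return included


def ivivc_regression(pairs: Sequence[IVIVCPair], space: str = "log10") -> IVIVCResult:
    """Ordinary least squares of unbound in vivo EC50 on in vitro IC50.

    The default log10-log10 space suits potencies spanning more than a
    decade with multiplicative error; linear space is available.  The slope
    SE is the standard OLS estimate, the p value a two-sided t test of zero
    slope on n-2 degrees of freedom, and R^2 the squared Pearson
    correlation.
    """
    if space not in ("log10", "linear"):
        raise ValueError("space must be 'log10' or 'linear'")
    if len(pairs) < 3:
        raise ValueError("need at least 3 compounds for a regression")
    x = np.array([p.invitro_ic50 for p in pairs], dtype=float)
    y = np.array([p.invivo_ec50_unbound for p in pairs], dtype=float)
    if space == "log10":
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the in vitro predictor; regression is degenerate")
    res = stats.linregress(x, y)
    return IVIVCResult(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(pairs),
        included_ids=tuple(p.compound_id for p in pairs),
        regression_space=space,
    )
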