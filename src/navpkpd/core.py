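"""Domain types and analytic forward models.

The disposition model is a linear two-compartment model parameterized by
clearance ``CL``, central volume ``V``, distribution clearance ``CL2`` and
peripheral volume ``V2``::

    V  * dCp/dt = -CL*Cp - CL2*Cp + CL2*C2
    V2 * dC2/dt =  CL2*Cp - CL2*C2

A hypothetical effect-site (biophase) compartment equilibrates with plasma
at a first-order rate ``ke0``::

    dCe/dt = ke0 * (Cp - Ce)

and drives a saturating Emax response ``E = E0 + Emax*Ce/(EC50 + Ce)``.

All solutions here are closed-form: every dosing event contributes a sum of
``c * (t-t0)^p * exp(-lam*(t-t0))`` terms, and the effect-site response of
each such term is again of that form, so arbitrary bolus / infusion /
first-order-absorption regimens superpose exactly.

Units are fixed package-wide: concentrations in uM, doses in umol/kg,
volumes in L/kg, clearances in L/h/kg, rates in 1/h, times in h.  Doses
supplied in mg/kg are converted on input via the compound molecular weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RATE_COINCIDENCE_RTOL",
    "CompoundRecord",
    "PKParams",
    "PDParams",
    "DoseEvent",
    "DoseRegimen",
    "ConcentrationSeries",
    "EffectSeries",
    "PKStudy",
    "PDStudy",
    "MacroConstants",
    "mg_per_kg_to_umol_per_kg",
    "macro_constants",
    "plasma_concentration",
    "effect_site_concentration",
    "emax_effect",
    "loading_infusion_regimen",
]

#: relative tolerance below which two exponential rates are treated as equal
#: and the analytic limit branch (t * exp(-lam*t)) is taken instead of the
#: generic partial-fraction form, which would otherwise lose all precision
RATE_COINCIDENCE_RTOL = 1e-9

ROUTE_IV_BOLUS = "iv_bolus"
ROUTE_IV_INFUSION = "iv_infusion"
ROUTE_EXTRAVASCULAR = "extravascular"
_ROUTES = (ROUTE_IV_BOLUS, ROUTE_IV_INFUSION, ROUTE_EXTRAVASCULAR)


def mg_per_kg_to_umol_per_kg(dose_mg_per_kg: float, mol_weight: float) -> float:
    """Convert a mass dose (mg/kg) to a molar dose (umol/kg)."""
    if mol_weight <= 0:
        raise ValueError("mol_weight must be positive")
    return dose_mg_per_kg / mol_weight * 1000.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """Identity and in vitro properties of one NaV1.7 inhibitor.

    ``fu_p`` is the fraction unbound in plasma (equilibrium dialysis),
    ``ic50_invitro`` the intrinsic patch-clamp IC50 in uM against the
    rhesus channel, and ``mol_weight`` (g/mol) is used for mass <-> molar
    dose conversion.
    """

    compound_id: str
    fu_p: float
    ic50_invitro: float
    hill: Optional[float] = None
    mol_weight: float = 500.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fu_p <= 1.0):
            raise ValueError(
                f"compound {self.compound_id}: fu_p must lie in (0, 1], got {self.fu_p}"
            )
        if self.ic50_invitro <= 0:
            raise ValueError(f"compound {self.compound_id}: ic50_invitro must be positive")
        if self.mol_weight <= 0:
            raise ValueError(f"compound {self.compound_id}: mol_weight must be positive")
        if self.hill is not None and self.hill <= 0:
            raise ValueError(f"compound {self.compound_id}: hill must be positive")


@dataclass(frozen=True)
class PKParams:
    """Two-compartment disposition parameters (L/h/kg and L/kg)."""

    CL: float
    V: float
    CL2: float
    V2: float

    def __post_init__(self) -> None:
        for name in ("CL", "V", "CL2", "V2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PK parameter {name} must be strictly positive")


@dataclass(frozen=True)
class PDParams:
    """Effect-site Emax parameters.

    ``E0`` and ``Emax`` default to 0 and 100 % inhibition and are treated
    as fixed during fitting; only ``EC50`` (uM, total plasma scale) and the
    biophase equilibration rate ``ke0`` (1/h) are estimated.
    """

    EC50: float
    ke0: float
    E0: float = 0.0
    Emax: float = 100.0

    def __post_init__(self) -> None:
        if self.EC50 <= 0:
            raise ValueError("EC50 must be positive")
        if self.ke0 <= 0:
            raise ValueError("ke0 must be positive")
        if not (0.0 <= self.E0 < self.Emax <= 100.0):
            raise ValueError("require 0 <= E0 < Emax <= 100")


@dataclass(frozen=True)
class DoseEvent:
    """One dosing event: IV bolus, constant-rate IV infusion, or a
    first-order extravascular (e.g. SC) dose with bioavailability ``F``."""

    time: float
    route: str
    amount: float
    duration: Optional[float] = None
    ka: Optional[float] = None
    F: Optional[float] = None

    def __post_init__(self) -> None:
        if self.route not in _ROUTES:
            raise ValueError(f"unknown route {self.route!r}; expected one of {_ROUTES}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")
        if self.route == ROUTE_IV_INFUSION:
            if self.duration is None or self.duration <= 0:
                raise ValueError("infusion events require duration > 0")
        elif self.duration is not None:
            raise ValueError(f"duration only valid for infusions, not {self.route}")
        if self.route == ROUTE_EXTRAVASCULAR:
            if self.ka is None or self.ka <= 0:
                raise ValueError("extravascular events require ka > 0")
            if self.F is None or not (0.0 < self.F <= 1.0):
                raise ValueError("extravascular events require F in (0, 1]")
        elif self.ka is not None or self.F is not None:
            raise ValueError(f"ka/F only valid for extravascular, not {self.route}")


@dataclass(frozen=True)
class DoseRegimen:
    """An ordered, non-empty sequence of dose events."""

    events: tuple

    def __init__(self, events: Sequence[DoseEvent]):
        events = tuple(events)
        if not events:
            raise ValueError("a regimen must contain at least one dose event")
        if any(b.time < a.time for a, b in zip(events, events[1:])):
            events = tuple(sorted(events, key=lambda e: e.time))
        object.__setattr__(self, "events", events)

    def scaled(self, factor: float) -> "DoseRegimen":
        """Return a copy with every dose amount multiplied by ``factor``."""
        return DoseRegimen(
            [
                DoseEvent(e.time, e.route, e.amount * factor, e.duration, e.ka, e.F)
                for e in self.events
            ]
        )


def _check_series(times: np.ndarray, values: np.ndarray, what: str) -> None:
    if times.shape != values.shape or times.ndim != 1:
        raise ValueError(f"{what}: times and values must be 1-d and of equal length")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError(f"{what}: times must be strictly increasing")


@dataclass(frozen=True)
class ConcentrationSeries:
    """Concentration-time observations or predictions for one subject."""

    subject_id: str
    times: np.ndarray
    values: np.ndarray
    compartment_tag: str = "plasma"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _check_series(self.times, self.values, "ConcentrationSeries")
        if self.compartment_tag not in ("plasma", "effect_site"):
            raise ValueError("compartment_tag must be 'plasma' or 'effect_site'")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class EffectSeries:
    """Percent-inhibition time course for one subject (noise may make
    individual values negative)."""

    subject_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _check_series(self.times, self.values, "EffectSeries")


@dataclass(frozen=True)
class PKStudy:
    """One subject's plasma observations together with the regimen that
    produced them."""

    series: ConcentrationSeries
    regimen: DoseRegimen


@dataclass(frozen=True)
class PDStudy:
    """One subject's effect observations, the regimen, and the fixed PK
    parameters used to reconstruct that subject's plasma profile."""

    effects: EffectSeries
    regimen: DoseRegimen
    pk: PKParams


# ---------------------------------------------------------------------------
# macro (hybrid) disposition constants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MacroConstants:
    """Biexponential disposition: Cp(t) = D*(A*exp(-alpha*t) + B*exp(-beta*t))
    after an IV bolus of size D, with alpha > beta > 0 and A + B = 1/V."""

    alpha: float
    beta: float
    A: float
    B: float


def macro_constants(pk: PKParams) -> MacroConstants:
    """Hybrid rate constants and unit-bolus coefficients of the
    two-compartment model."""
    k10 = pk.CL / pk.V
    k12 = pk.CL2 / pk.V
    k21 = pk.CL2 / pk.V2
    s = k10 + k12 + k21
    prod = k10 * k21
    disc = math.sqrt(max(s * s - 4.0 * prod, 0.0))
    alpha = 0.5 * (s + disc)
    beta = prod / alpha  # numerically stable Vieta form
    A = (alpha - k21) / (pk.V * (alpha - beta))
    B = (k21 - beta) / (pk.V * (alpha - beta))
    return MacroConstants(alpha=alpha, beta=beta, A=A, B=B)


# ---------------------------------------------------------------------------
# exponential-term algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _ExpTerm:
    """Contribution c * (t-t0)^p * exp(-rate*(t-t0)) for t >= t0."""

    coef: float
    rate: float
    onset: float
    power: int = 0


def _rates_coincide(a: float, b: float) -> bool:
    return abs(a - b) <= RATE_COINCIDENCE_RTOL * max(abs(a), abs(b))


def _bolus_terms(mc: MacroConstants, amount: float, t0: float) -> list:
    return [
        _ExpTerm(amount * mc.A, mc.alpha, t0),
        _ExpTerm(amount * mc.B, mc.beta, t0),
    ]


def _infusion_start_terms(mc: MacroConstants, rate: float, t0: float) -> list:
    """Terms for an infusion switched on at t0 and never switched off."""
    out = []
    for c, lam in ((mc.A, mc.alpha), (mc.B, mc.beta)):
        out.append(_ExpTerm(rate * c / lam, 0.0, t0))
        out.append(_ExpTerm(-rate * c / lam, lam, t0))
    return out


def _extravascular_terms(
    mc: MacroConstants, amount: float, ka: float, F: float, t0: float
) -> list:
    out = []
    for c, lam in ((mc.A, mc.alpha), (mc.B, mc.beta)):
        if _rates_coincide(ka, lam):
            # flip-flop limit ka -> lam: F*D*ka*c * t * exp(-lam t)
            out.append(_ExpTerm(F * amount * ka * c, lam, t0, power=1))
        else:
            k = F * amount * ka * c / (ka - lam)
            out.append(_ExpTerm(k, lam, t0))
            out.append(_ExpTerm(-k, ka, t0))
    return out


def _plasma_terms(pk: PKParams, regimen: DoseRegimen) -> list:
    mc = macro_constants(pk)
    terms: list = []
    for ev in regimen.events:
        if ev.amount == 0:
            continue
        if ev.route == ROUTE_IV_BOLUS:
            terms.extend(_bolus_terms(mc, ev.amount, ev.time))
        elif ev.route == ROUTE_IV_INFUSION:
            rate = ev.amount / ev.duration
            terms.extend(_infusion_start_terms(mc, rate, ev.time))
            terms.extend(_infusion_start_terms(mc, -rate, ev.time + ev.duration))
        else:
            terms.extend(_extravascular_terms(mc, ev.amount, ev.ka, ev.F, ev.time))
    return terms


def _convolve_ke0(term: _ExpTerm, ke0: float) -> list:
    """Effect-site response of one plasma term through
    dCe/dt = ke0*(Cp - Ce), i.e. convolution with ke0*exp(-ke0*t)."""
    mu = ke0 - term.rate
    p = term.power
    if _rates_coincide(ke0, term.rate):
        # resonant limit: c t^p e^{-lam t} -> c ke0 t^{p+1}/(p+1) e^{-ke0 t}
        return [_ExpTerm(term.coef * ke0 / (p + 1), ke0, term.onset, p + 1)]
    # closed form of ke0 * e^{-ke0 tau} * Int_0^tau s^p e^{mu s} ds
    out = []
    fact = math.factorial(p)
    for j in range(p + 1):
        coef = term.coef * ke0 * ((-1.0) ** (p - j)) * fact / math.factorial(j) / mu ** (p - j + 1)
        out.append(_ExpTerm(coef, term.rate, term.onset, j))
    const = term.coef * ke0 * ((-1.0) ** (p + 1)) * fact / mu ** (p + 1)
    out.append(_ExpTerm(const, ke0, term.onset, 0))
    return out


def _effect_site_terms(plasma_terms: Sequence[_ExpTerm], ke0: float) -> list:
    out: list = []
    for t in plasma_terms:
        out.extend(_convolve_ke0(t, ke0))
    return out


def _evaluate_terms(terms: Sequence[_ExpTerm], times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    for t in terms:
        tau = times - t.onset
        active = tau >= 0
        if not np.any(active):
            continue
        tau_a = tau[active]
        contrib = t.coef * np.exp(-t.rate * tau_a)
        if t.power:
            contrib = contrib * tau_a**t.power
        out[active] += contrib
    return out


# ---------------------------------------------------------------------------
# public forward-model operations
# ---------------------------------------------------------------------------


def plasma_concentration(
    pk: PKParams,
    regimen: DoseRegimen,
    times: Sequence[float],
    subject_id: str = "sim",
) -> ConcentrationSeries:
    """Plasma concentration-time profile for an arbitrary regimen.

    The profile is the exact superposition of the closed-form responses to
    each dose event; a bolus contributes a biexponential, an infusion the
    time-shifted integral thereof, and an extravascular dose an F-scaled
    triexponential with absorption rate ka (with the analytic limit taken
    when ka coincides with a disposition exponent).
    """
    values = _evaluate_terms(_plasma_terms(pk, regimen), times)
    # exact solution is non-negative; clip roundoff-level undershoot
    return ConcentrationSeries(subject_id, np.asarray(times, float), np.maximum(values, 0.0), "plasma")


def effect_site_concentration(
    pk: PKParams,
    ke0: float,
    regimen: DoseRegimen,
    times: Sequence[float],
    subject_id: str = "sim",
) -> ConcentrationSeries:
    """Effect-site (biophase) concentration, Ce(0) = 0, obtained by exact
    convolution of the plasma solution with the ke0 equilibration kernel."""
    if ke0 <= 0:
        raise ValueError("ke0 must be positive")
    terms = _effect_site_terms(_plasma_terms(pk, regimen), ke0)
    values = _evaluate_terms(terms, times)
    return ConcentrationSeries(
        subject_id, np.asarray(times, float), np.maximum(values, 0.0), "effect_site"
    )


def emax_effect(pd: PDParams, c):
    """Emax response E = E0 + Emax*c/(EC50 + c); accepts scalars or arrays."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be non-negative")
    out = pd.E0 + pd.Emax * c_arr / (pd.EC50 + c_arr)
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def loading_infusion_regimen(
    total_dose: float,
    pk: PKParams,
    infusion_duration: float = 1.0,
    start_time: float = 1.0,
) -> DoseRegimen:
    """IV bolus plus constant infusion sized to hold plasma roughly flat.

    The total dose D is split so that the target plateau
    Css = D / (V + CL*T) is reached immediately (bolus = Css*V) and then
    maintained for the infusion duration T (rate = Css*CL).  This emulates
    the bolus-plus-1-h-infusion paradigm of the olfaction imaging studies,
    where dosing starts after a 1-h baseline acquisition period.
    """
    if total_dose < 0:
        raise ValueError("total_dose must be >= 0")
    if infusion_duration <= 0:
        raise ValueError("infusion_duration must be positive")
    css = total_dose / (pk.V + pk.CL * infusion_duration)
    bolus = css * pk.V
    infused = css * pk.CL * infusion_duration
    return DoseRegimen(
        [
            DoseEvent(start_time, ROUTE_IV_BOLUS, bolus),
            DoseEvent(start_time, ROUTE_IV_INFUSION, infused, duration=infusion_duration),
        ]
    )
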