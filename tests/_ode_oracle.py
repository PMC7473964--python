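"""Independent numeric oracle: piecewise adaptive integration of the
two-compartment + depot + effect-site ODE system, used to validate the
package's closed-form solutions."""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from navpkpd.core import DoseRegimen, PKParams


def ode_profiles(pk: PKParams, ke0: float, regimen: DoseRegimen, times: np.ndarray):
    """(Cp, Ce) at ``times`` by adaptive ODE integration (rtol 1e-11).

    Integration restarts at every dosing discontinuity; bolus doses and
    depot loads are applied as state jumps.  At a grid point exactly equal
    to a bolus time the post-bolus value is reported, matching the analytic
    convention.
    """
    times = np.asarray(times, dtype=float)
    events = regimen.events
    depots = [e for e in events if e.route == "extravascular"]
    nd = len(depots)

    def rhs(t, y):
        cp, c2 = y[nd], y[nd + 1]
        inflow = 0.0
        dydt = np.zeros_like(y)
        for e in events:
            if e.route == "iv_infusion" and e.time <= t < e.time + e.duration:
                inflow += e.amount / e.duration
        for i, e in enumerate(depots):
            dydt[i] = -e.ka * y[i]
            inflow += e.ka * y[i] * e.F
        dydt[nd] = (inflow - pk.CL * cp - pk.CL2 * cp + pk.CL2 * c2) / pk.V
        dydt[nd + 1] = (pk.CL2 * cp - pk.CL2 * c2) / pk.V2
        dydt[nd + 2] = ke0 * (cp - y[nd + 2])
        return dydt

    knots = {float(times[0]), float(times[-1])}
    for e in events:
        knots.add(e.time)
        if e.route == "iv_infusion":
            knots.add(e.time + e.duration)
    # integration must start no later than the earliest event, even when the
    # output grid begins afterwards
    knots = sorted(t for t in knots if t <= times[-1])

    y = np.zeros(nd + 3)
    cp_out = np.zeros_like(times)
    ce_out = np.zeros_like(times)
    for a, b in zip(knots[:-1], knots[1:]):
        for i, e in enumerate(depots):
            if e.time == a:
                y[i] += e.amount
        for e in events:
            if e.route == "iv_bolus" and e.time == a:
                y[nd] += e.amount / pk.V
        sol = solve_ivp(rhs, (a, b), y, dense_output=True, rtol=1e-11, atol=1e-14)
        mask = (times >= a) & (times <= b)
        if mask.any():
            vals = sol.sol(times[mask])
            cp_out[mask] = vals[nd]
            ce_out[mask] = vals[nd + 2]
        y = sol.y[:, -1]
    return cp_out, ce_out


def random_pk(rng: np.random.Generator) -> PKParams:
    return PKParams(*np.exp(rng.normal(np.log([0.5, 0.5, 0.3, 1.0]), 0.5)))
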