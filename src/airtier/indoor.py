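"""Indoor concentration from the outdoor tier via a dynamic mass balance.

The single-compartment model

    dC_in/dt = P·AER·C_out − (AER + k_d)·C_in

balances penetration of outdoor air (penetration factor P, air exchange rate
AER in h⁻¹) against removal by exchange and first-order deposition (k_d, h⁻¹).
With outdoor concentration and AER held constant within each hour the ODE is
linear with constant coefficients, so the hourly update is solved exactly:

    C_in(t+Δt) = C_ss + (C_in(t) − C_ss)·exp(−(AER + k_d)·Δt),
    C_ss       = P·AER·C_out / (AER + k_d).

The closed form is bit-stable and fast; a stiff numerical integrator serves
as the independent oracle in the test suite, not as the production path.
The first hour starts from C_in = 0; the influence of that choice decays as
exp(−Σ(AER+k_d)Δt) and is negligible after a few hours for typical AER.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import ConcentrationField


@dataclass(frozen=True)
class PollutantParams:
    """Penetration factor and indoor deposition rate for one pollutant."""

    name: str
    penetration: float  # P, dimensionless, 0..1
    deposition: float   # k_d, h⁻¹

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetration <= 1.0:
            raise ValueError("penetration factor must be in [0, 1]")
        if self.deposition < 0.0:
            raise ValueError("deposition rate must be >= 0")


#: Literature values: CO and NOx penetrate fully (gases), NOx deposits on
#: indoor surfaces; PM2.5 and EC lose mass in envelope transport and settle.
DEFAULT_POLLUTANTS = {
    "CO": PollutantParams("CO", 1.0, 0.0),
    "NOx": PollutantParams("NOx", 1.0, 0.5),
    "PM2.5": PollutantParams("PM2.5", 0.84, 0.21),
    "EC": PollutantParams("EC", 0.98, 0.29),
}


def steady_state(c_out, aer, params: PollutantParams):
    """Equilibrium indoor concentration C_ss = P·AER·C_out/(AER + k_d).

    The no-exchange, no-deposition corner (AER = k_d = 0) has no forcing at
    all; by convention the steady state is reported as 0 there (the indoor
    value is simply frozen, which :func:`step_update` honors exactly).
    """
    c_out = np.asarray(c_out, dtype=float)
    aer = np.asarray(aer, dtype=float)
    if np.any(c_out < 0) or np.any(aer < 0):
        raise ValueError("concentration and AER must be >= 0")
    denom = aer + params.deposition
    with np.errstate(invalid="ignore", divide="ignore"):
        css = np.where(denom > 0, params.penetration * aer * c_out / np.where(denom > 0, denom, 1.0), 0.0)
    return float(css) if css.ndim == 0 else css


def step_update(c_in_prev, c_out, aer, params: PollutantParams, dt: float = 1.0):
    """Exact one-step update of the mass balance over an interval of dt hours."""
    c_in_prev = np.asarray(c_in_prev, dtype=float)
    aer = np.asarray(aer, dtype=float)
    loss = aer + params.deposition
    css = steady_state(c_out, aer, params)
    decay = np.exp(-loss * dt)
    out = css + (c_in_prev - css) * decay
    return float(out) if out.ndim == 0 else out


def solve_series(
    c_out: np.ndarray,
    aer: np.ndarray,
    params: PollutantParams,
    c_in0: float | np.ndarray = 0.0,
    dt: float = 1.0,
) -> np.ndarray:
    """March the hourly update along aligned outdoor and AER series.

    ``c_out`` and ``aer`` may be 1-D (one location) or 2-D
    ``(n_blocks, n_hours)``; the returned array has the same shape. Each
    hour's value is the end-of-hour indoor concentration. NaNs in the
    outdoor series propagate to that hour and the march restarts from the
    last finite value.
    """
    c_out = np.atleast_2d(np.asarray(c_out, dtype=float))
    aer = np.atleast_2d(np.asarray(aer, dtype=float))
    if aer.shape[0] == 1 and c_out.shape[0] > 1:
        aer = np.broadcast_to(aer, c_out.shape)
    if c_out.shape != aer.shape:
        raise ValueError(f"outdoor grid {c_out.shape} and AER grid {aer.shape} differ")
    n_b, n_t = c_out.shape
    out = np.empty_like(c_out)
    prev = np.broadcast_to(np.asarray(c_in0, dtype=float), (n_b,)).copy()
    for t in range(n_t):
        cur = step_update(prev, np.nan_to_num(c_out[:, t]), aer[:, t], params, dt)
        bad = ~np.isfinite(c_out[:, t])
        cur = np.where(bad, np.nan, cur)
        out[:, t] = cur
        prev = np.where(bad, prev, cur)  # restart from last finite value
    return out


def indoor_field(
    outdoor: ConcentrationField,
    aer: np.ndarray,
    params: PollutantParams,
    c_in0: float = 0.0,
) -> ConcentrationField:
    """Indoor counterpart of an outdoor tier ("outdoor_x" -> "indoor_x")."""
    if aer.shape != outdoor.values.shape:
        raise ValueError("AER grid does not match the outdoor field grid")
    vals = solve_series(outdoor.values, aer, params, c_in0=c_in0)
    tier = outdoor.tier.replace("outdoor", "indoor") if "outdoor" in outdoor.tier \
        else f"indoor_{outdoor.tier}"
    return outdoor.copy_with(vals, tier=tier)
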