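"""Closed-form and root-finding kinetic quantities of the infection model.

The infection seeded by a single virion is a branching process: the virion
causes a productive cell infection with probability ``P_VI`` and that cell
produces a negative-binomially distributed number of secondary virions (the
burst size).  Extinction probabilities follow from the fixed point of the
burst law's probability generating function; the final size (fraction of
cells consumed) of an established infection follows from a conservation law
of the mean-field equations and is expressed through the principal branch of
the Lambert W function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .params import InfectionParameters, derive_quantities

__all__ = [
    "ExtinctionResult",
    "prob_virion_infects",
    "burst_size_pmf",
    "burst_size_cdf",
    "extinction_prob_single_virion",
    "extinction_prob_single_cell",
    "extinction_prob_inoculum",
    "critical_fraction_uninfected",
    "fraction_consumed",
    "reproductive_number_at",
    "lambert_w_principal",
    "expected_unique_infections",
]

# Numeric root of the extinction fixed point is sought on [0, 1 - _ROOT_GAP]:
# exactly 1 is always a (trivial) fixed point and must be excluded.
_ROOT_GAP = 1e-9


def prob_virion_infects(params: InfectionParameters) -> float:
    """Probability that one virion ever productively infects a cell.

    ``P_VI = gamma / (1 + c/(beta*N_cells/s))`` — the race between successful
    cell entry (rate ``beta*N_cells/s``, success probability ``gamma``) and
    loss of infectivity (rate ``c``), in a fully susceptible population.
    """
    return derive_quantities(params).P_VI


def _nb_params(B: float, n_I: int) -> tuple[int, float]:
    """scipy parameterization (n, p) of the burst-size negative binomial."""
    return n_I, n_I / (n_I + B)


def burst_size_pmf(m, params: InfectionParameters):
    """P(burst size = m): NB(m | r = n_I, p_B = B/(n_I+B)), mean B = p*tau_I.

    A cell produces virions as a Poisson process at rate ``p`` over an
    Erlang(n_I, n_I/tau_I) lifespan; marginalizing the lifespan yields the
    negative binomial.  ``n_I = 1`` gives a geometric law; ``n_I -> inf``
    tends to Poisson(B).
    """
    m = np.asarray(m)
    if np.any(m < 0):
        raise ValueError("burst size m must be non-negative")
    B = params.p * params.tau_I
    n, pr = _nb_params(B, params.n_I)
    out = stats.nbinom.pmf(m, n, pr)
    return float(out) if out.ndim == 0 else out


def burst_size_cdf(m, params: InfectionParameters):
    """P(burst size <= m) under the negative-binomial burst law."""
    B = params.p * params.tau_I
    n, pr = _nb_params(B, params.n_I)
    out = stats.nbinom.cdf(m, n, pr)
    return float(out) if np.ndim(out) == 0 else out


def extinction_prob_single_virion(params: InfectionParameters) -> float:
    """Extinction probability of an infection seeded by one virion.

    Solves the branching-process fixed point

        P = (1 - P_VI) + P_VI * [B*(1-P)/n_I + 1]^(-n_I)

    on [0, 1) by bracketed root finding (the trivial root at exactly 1 is
    excluded from the bracket).  Returns 1.0 when R0 <= 1.  For ``n_I = 1``
    the closed form ``1 - (R0 - 1)/B`` is an exact solution and agrees with
    the numeric root to ~1e-12.
    """
    d = derive_quantities(params)
    if d.R0 <= 1.0:
        return 1.0
    B, nI, P_VI = d.B, params.n_I, d.P_VI

    def f(P: float) -> float:
        return (1.0 - P_VI) + P_VI * (B * (1.0 - P) / nI + 1.0) ** (-nI) - P

    lo, hi = 0.0, 1.0 - _ROOT_GAP
    flo, fhi = f(lo), f(hi)
    if fhi >= 0.0:
        # R0 barely above 1: the non-trivial root is numerically
        # indistinguishable from the trivial root at 1
        return 1.0
    if not flo > 0:
        raise RuntimeError(
            f"extinction root not bracketed: f(0)={flo:.3g}, f(1-eps)={fhi:.3g}, "
            f"R0={d.R0:.6g}"
        )
    root = optimize.brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)
    return float(root)


def extinction_prob_single_cell(params: InfectionParameters) -> float:
    """Extinction probability of an infection seeded by one infectious cell.

    This is the burst-law generating function evaluated at the single-virion
    extinction probability: ``[B*(1 - P_V_ext)/n_I + 1]^(-n_I)``.
    """
    d = derive_quantities(params)
    p_v = extinction_prob_single_virion(params)
    return float((d.B * (1.0 - p_v) / params.n_I + 1.0) ** (-params.n_I))


@dataclass(frozen=True)
class ExtinctionResult:
    """Extinction/establishment probabilities for a given inoculum."""

    p_ext_virion: float
    p_ext_cell: float
    p_ext_inoculum: float
    establishment: float


def extinction_prob_inoculum(
    params: InfectionParameters, V0: int | None = None, I0: int | None = None
) -> ExtinctionResult:
    """Extinction probability for an inoculum of V0 virions and I0 cells.

    Each initial virion or infectious cell founds an independent lineage, so
    the inoculum extinction probability is the product
    ``p_ext_virion**V0 * p_ext_cell**I0``.
    """
    V0 = params.V0 if V0 is None else V0
    I0 = params.I0 if I0 is None else I0
    if V0 < 0 or I0 < 0:
        raise ValueError("V0 and I0 must be non-negative")
    p_v = extinction_prob_single_virion(params)
    p_i = extinction_prob_single_cell(params)
    p_inoc = p_v**V0 * p_i**I0
    return ExtinctionResult(
        p_ext_virion=p_v,
        p_ext_cell=p_i,
        p_ext_inoculum=p_inoc,
        establishment=1.0 - p_inoc,
    )


def critical_fraction_uninfected(params: InfectionParameters) -> float:
    """T*/N_cells: uninfected fraction at which R(t) crosses 1.

    ``T*/N_cells = [c/(beta*N_cells/s)] / (gamma*p*tau_I - 1)``; only defined
    when ``gamma*p*tau_I > 1``.
    """
    d = derive_quantities(params)
    if d.Tstar_frac is None:
        raise ValueError("no interior critical point: gamma*p*tau_I <= 1")
    return d.Tstar_frac


def lambert_w_principal(x: float) -> float:
    """Principal branch W0 of the Lambert W function: w*exp(w) = x, w >= -1.

    Defined for x >= -1/e.  Uses the library implementation and polishes with
    one Halley step if the residual exceeds 1e-12 (contract: residual <= 1e-12
    away from the branch point).
    """
    min_x = -1.0 / math.e
    if x < min_x - 1e-15:
        raise ValueError(f"Lambert W0 undefined for x = {x} < -1/e")
    if x <= min_x + 1e-16:
        return -1.0  # branch point; the library evaluation is unstable here
    w = float(special.lambertw(x, k=0).real)
    resid = w * math.exp(w) - x
    if abs(resid) > 1e-12 and w > -1.0 + 1e-9:
        ew = math.exp(w)
        # Halley iteration step for f(w) = w e^w - x
        f = w * ew - x
        w = w - f / (ew * (w + 1.0) - (w + 2.0) * f / (2.0 * w + 2.0))
    return w


def fraction_consumed(
    params: InfectionParameters, V0: int | None = None, I0: int | None = None
) -> float:
    """Final fraction of cells consumed, 1 - T(inf)/N_cells, of the mean-field
    infection — and, to good approximation, the median among established
    stochastic runs.

        1 - T(inf)/N = 1 + Tf * W0( -exp(-1/Tf)/Tf * exp(-gamma*(beta/s)*(V0 + p*tau_I*I0)/c) )

    with ``Tf = T*/N_cells``.  An inoculum of I0 infectious cells enters as an
    effective ``p*tau_I*I0`` additional initial virions.  Requires
    ``gamma*p*tau_I > 1``; in the V0, I0 -> 0 limit the inoculum factor drops
    out, and for ``Tf << 1`` the result approaches ``1 - exp(-1/Tf)``.
    """
    V0 = params.V0 if V0 is None else V0
    I0 = params.I0 if I0 is None else I0
    Tf = critical_fraction_uninfected(params)
    inoc = params.gamma * (params.beta / params.s) * (V0 + params.p * params.tau_I * I0)
    arg = -math.exp(-1.0 / Tf) / Tf * math.exp(-inoc / params.c)
    if arg < -1.0 / math.e - 1e-12:
        raise AssertionError(
            f"Lambert-W argument {arg} < -1/e; impossible for valid parameters"
        )
    return 1.0 + Tf * lambert_w_principal(arg)


def reproductive_number_at(T_frac: float, R0: float, Tstar_frac: float) -> float:
    """Running reproductive number R(t) as a function of the uninfected
    fraction ``T_frac = T(t)/N_cells``.

        R = R0 * T_frac * (1 - Tf) / [Tf*(R0 - 1) + T_frac*(1 - R0*Tf)]

    Strictly increasing in ``T_frac``; equals R0 at ``T_frac = 1`` and 1 at
    ``T_frac = Tstar_frac``.
    """
    if not (0 < T_frac <= 1):
        raise ValueError("T_frac must lie in (0, 1]")
    if R0 < 1:
        raise ValueError("R0 must be >= 1")
    if not (0 < Tstar_frac < 1):
        raise ValueError("Tstar_frac must lie in (0, 1)")
    Tf = Tstar_frac
    num = R0 * T_frac * (1.0 - Tf)
    den = Tf * (R0 - 1.0) + T_frac * (1.0 - R0 * Tf)
    return num / den


def expected_unique_infections(T: int, V_suc: int) -> float:
    """Expected number of distinct cells infected when V_suc successful
    virions land uniformly at random (with replacement) on T cells.

        E[N_inf] = T * [1 - ((T-1)/T)^V_suc]   (T >= 1), 0 for T = 0.

    Equals V_suc when V_suc << T.
    """
    if T < 0 or V_suc < 0:
        raise ValueError("T and V_suc must be non-negative")
    if T == 0 or V_suc == 0:
        return 0.0
    return T * (1.0 - ((T - 1.0) / T) ** V_suc)
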