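"""Comparison of antiviral modes of action.

Critical efficacies (where R0 drops to 1 and establishment vanishes), the
half-maximal efficacy eps50 (where the establishment probability is half its
drug-free value), and efficacy sweeps of establishment probability and final
size.  A production (p) or post-entry (gamma) inhibitor reaches R0 = 1 at
``eps = 1 - 1/R0``; an entry (beta) inhibitor needs a higher efficacy because
reducing beta also slows virion loss through entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .kinetics import extinction_prob_inoculum, fraction_consumed
from .params import (
    AntiviralIntervention,
    AntiviralMode,
    InfectionParameters,
    apply_antiviral,
    derive_quantities,
)

__all__ = ["EfficacySweep", "critical_efficacy", "epsilon_50", "sweep"]


def _with_efficacy(
    params: InfectionParameters, mode: AntiviralMode | str, eps: float
) -> InfectionParameters:
    return apply_antiviral(params, AntiviralIntervention(mode=mode, efficacy=eps))


def critical_efficacy(params: InfectionParameters, mode: AntiviralMode | str) -> float:
    """Efficacy at which R0 reaches 1 for the given mode of action.

    Closed form ``1 - 1/R0`` for p- and gamma-antivirals (both scale R0
    linearly); root solve for a beta-antiviral.  Returns 0 with a warning if
    the untreated infection already has R0 <= 1.
    """
    mode = AntiviralMode(mode)
    R0 = derive_quantities(params).R0
    if R0 <= 1.0:
        warnings.warn("R0 <= 1 without antivirals; critical efficacy is 0")
        return 0.0
    if mode in (AntiviralMode.reduce_p, AntiviralMode.reduce_gamma):
        return 1.0 - 1.0 / R0

    def f(eps: float) -> float:
        return derive_quantities(_with_efficacy(params, mode, eps)).R0 - 1.0

    hi = 1.0 - 1e-12
    if f(hi) > 0:
        # even a near-total entry block leaves R0 > 1 (gamma*B stays > 1 and
        # ratio stays finite only through eps < 1); signal with eps -> 1
        raise RuntimeError("beta-antiviral cannot bring R0 to 1 for these parameters")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-14))


def _establishment(params: InfectionParameters, V0: int, I0: int = 0) -> float:
    return extinction_prob_inoculum(params, V0=V0, I0=I0).establishment


def epsilon_50(
    params: InfectionParameters, mode: AntiviralMode | str, V0: int = 1, I0: int = 0
) -> float:
    """Efficacy at which the establishment probability for an inoculum of V0
    virions is half its value without antivirals.

    Bracketed between 0 and the critical efficacy (establishment decreases
    monotonically with efficacy and vanishes at the critical point); solved
    to |d eps| <= 1e-8.
    """
    mode = AntiviralMode(mode)
    base = _establishment(params, V0, I0)
    if base <= 0:
        raise ValueError("establishment probability is zero without antivirals")
    target = 0.5 * base

    def f(eps: float) -> float:
        return _establishment(_with_efficacy(params, mode, eps), V0, I0) - target

    eps_c = critical_efficacy(params, mode)
    return float(optimize.brentq(f, 0.0, eps_c - 1e-12, xtol=1e-10))


@dataclass(frozen=True)
class EfficacySweep:
    """Per-efficacy establishment probability, T*/N_cells and final size.

    ``valid[i]`` is True where R0(eps) > 1; elsewhere establishment is 0 and
    ``Tstar_frac``/``fraction_consumed`` are NaN (undefined).
    """

    mode: AntiviralMode
    eps: np.ndarray
    establishment: np.ndarray
    Tstar_frac: np.ndarray
    fraction_consumed: np.ndarray
    valid: np.ndarray
    V0: int = 1
    I0: int = 0


DEFAULT_EPS_GRID = np.linspace(0.0, 0.999, 512)


def sweep(
    params: InfectionParameters,
    mode: AntiviralMode | str,
    eps_grid: np.ndarray | None = None,
    V0: int = 1,
    I0: int = 0,
) -> EfficacySweep:
    """Sweep antiviral efficacy, evaluating establishment and final size."""
    mode = AntiviralMode(mode)
    eps_grid = DEFAULT_EPS_GRID if eps_grid is None else np.asarray(eps_grid, float)
    if np.any((eps_grid < 0) | (eps_grid >= 1)):
        raise ValueError("efficacy grid must lie in [0, 1)")
    n = eps_grid.size
    est = np.zeros(n)
    tf = np.full(n, np.nan)
    frac = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, eps in enumerate(eps_grid):
        q = _with_efficacy(params, mode, float(eps))
        d = derive_quantities(q)
        if d.Tstar_frac is not None:
            tf[i] = d.Tstar_frac
        if d.R0 > 1.0:
            valid[i] = True
            est[i] = _establishment(q, V0, I0)
            if d.Tstar_frac is not None:
                frac[i] = fraction_consumed(q, V0=V0, I0=I0)
    return EfficacySweep(
        mode=mode,
        eps=eps_grid,
        establishment=est,
        Tstar_frac=tf,
        fraction_consumed=frac,
        valid=valid,
        V0=V0,
        I0=I0,
    )
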