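"""Parameterization of the within-host infection model.

The model describes a well-mixed population of ``N_cells`` susceptible target
cells exposed to infectious virions in a compartment of volume ``s``.  Virions
irreversibly commit to cell entry at per-virion rate ``beta*T/s``, lose
infectivity at rate ``c``, and an entry results in a productive cell infection
with probability ``gamma`` (post-entry failure otherwise leaves the cell
untouched).  Newly infected cells traverse an Erlang-distributed eclipse phase
(shape ``n_E``, mean ``tau_E``) followed by an Erlang-distributed infectious
phase (shape ``n_I``, mean ``tau_I``) during which they produce infectious
virions at rate ``p``.

Units are fixed throughout the package: hours, millilitres, counts.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "InfectionParameters",
    "DerivedQuantities",
    "AntiviralMode",
    "AntiviralIntervention",
    "derive_quantities",
    "apply_antiviral",
    "efficacy_for_target_fraction",
]


@dataclass(frozen=True)
class InfectionParameters:
    """Full rate/shape/size parameterization of the infection model.

    Parameters
    ----------
    beta : float
        Virus entry-rate coefficient, mL/(cell*h); enters as ``beta*T*V/s``.
    p : float
        Infectious-virion production rate, IV/(cell*h).
    c : float
        Rate of loss of virion infectivity, 1/h.
    gamma : float
        Probability in (0, 1] that a virion entry yields a productive cell
        infection (cell/IV).
    tau_E, tau_I : float
        Mean eclipse / infectious phase durations, h.
    n_E, n_I : int
        Erlang shape parameters (>= 1) of the two phases.
    N_cells : int
        Initial number of susceptible target cells.
    s : float
        System volume, mL.
    V0, I0 : int
        Initial numbers of infectious virions and infectious cells.
    """

    beta: float
    p: float
    c: float
    gamma: float = 1.0
    tau_E: float = 24 / 5
    tau_I: float = 24 / 0.595
    n_E: int = 1
    n_I: int = 1
    N_cells: int = 40_000
    s: float = 1.0
    V0: int = 1
    I0: int = 0

    def __post_init__(self) -> None:
        for name in ("beta", "p", "c", "tau_E", "tau_I", "s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must lie in (0, 1]")
        for name in ("n_E", "n_I", "N_cells"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1")
        for name in ("V0", "I0"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer")

    @classmethod
    def from_R0(cls, R0: float, **kwargs) -> "InfectionParameters":
        """Build a parameter set fixing ``beta`` from a target ``R0``.

        Inverts ``R0 = gamma*p*tau_I / (1 + c/(beta*N_cells/s))`` for beta:

            beta = s*c*R0 / (N_cells*(gamma*p*tau_I - R0))

        which requires ``gamma*p*tau_I > R0``.  All other fields are passed
        through unchanged.
        """
        probe = cls(beta=1.0, **kwargs)
        denom = probe.gamma * probe.p * probe.tau_I - R0
        if denom <= 0:
            raise ValueError(
                "R0 must be smaller than gamma*p*tau_I for beta to be positive"
            )
        beta = probe.s * probe.c * R0 / (probe.N_cells * denom)
        return cls(beta=beta, **kwargs)

    def replace(self, **kwargs) -> "InfectionParameters":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class DerivedQuantities:
    """Dimensionless quantities derived from an :class:`InfectionParameters`.

    ``B``
        Mean burst size ``p*tau_I`` (IV/cell).
    ``ratio``
        ``c/(beta*N_cells/s)``: loss-of-infectivity rate over entry rate;
        beta and c enter every derived quantity only through this ratio.
    ``P_VI``
        Probability a single virion ever causes a productive cell infection
        in a fully susceptible population: ``gamma/(1 + ratio)``.
    ``R0``
        Basic reproductive number ``B * P_VI``.
    ``Tstar_frac``
        Critical fraction of cells still uninfected when the running
        reproductive number crosses 1: ``ratio/(gamma*p*tau_I - 1)``.
        ``None`` when ``gamma*p*tau_I <= 1`` (no interior critical point).
    """

    B: float
    ratio: float
    P_VI: float
    R0: float
    Tstar_frac: Optional[float]


def derive_quantities(params: InfectionParameters) -> DerivedQuantities:
    B = params.p * params.tau_I
    ratio = params.c / (params.beta * params.N_cells / params.s)
    P_VI = params.gamma / (1.0 + ratio)
    R0 = B * P_VI
    gpt = params.gamma * B
    Tstar_frac = ratio / (gpt - 1.0) if gpt > 1.0 else None
    return DerivedQuantities(B=B, ratio=ratio, P_VI=P_VI, R0=R0, Tstar_frac=Tstar_frac)


class AntiviralMode(str, enum.Enum):
    """Mode of action of a prophylactic antiviral.

    ``reduce_beta``
        Entry inhibitor: ``beta -> (1-eps)*beta``.
    ``reduce_p``
        Production inhibitor: ``p -> (1-eps)*p``.
    ``reduce_gamma``
        Post-entry inhibitor (e.g. endosomal fusion blocker):
        ``gamma -> (1-eps)*gamma``.
    """

    reduce_beta = "reduce_beta"
    reduce_p = "reduce_p"
    reduce_gamma = "reduce_gamma"


_MODE_FIELD = {
    AntiviralMode.reduce_beta: "beta",
    AntiviralMode.reduce_p: "p",
    AntiviralMode.reduce_gamma: "gamma",
}


@dataclass(frozen=True)
class AntiviralIntervention:
    """An antiviral mode of action with efficacy ``efficacy`` in [0, 1)."""

    mode: AntiviralMode
    efficacy: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", AntiviralMode(self.mode))
        if not (0 <= self.efficacy < 1):
            raise ValueError("efficacy must lie in [0, 1); eps = 1 would zero a rate")


def apply_antiviral(
    params: InfectionParameters, iv: AntiviralIntervention
) -> InfectionParameters:
    """Return a copy of ``params`` with the targeted rate scaled by (1 - eps)."""
    field = _MODE_FIELD[AntiviralMode(iv.mode)]
    return params.replace(**{field: getattr(params, field) * (1.0 - iv.efficacy)})


def efficacy_for_target_fraction(
    params: InfectionParameters,
    mode: AntiviralMode | str,
    target_Tstar_frac: float,
) -> float:
    """Solve for the efficacy that puts ``T*/N_cells`` at a target value.

    Figure conditions in the source study are stated exactly this way
    (e.g. "such that T*/N_cells = 0.5"); the quoted efficacies (0.79, 0.86,
    ...) are roundings of the solutions found here.  Closed forms exist for
    every mode because ``T*/N_cells = ratio/(gamma*p*tau_I - 1)``.
    """
    mode = AntiviralMode(mode)
    d = derive_quantities(params)
    gpt = params.gamma * d.B
    if target_Tstar_frac <= 0:
        raise ValueError("target_Tstar_frac must be positive")
    if mode in (AntiviralMode.reduce_p, AntiviralMode.reduce_gamma):
        # ratio / ((1-eps)*gpt - 1) = target
        one_minus_eps = (d.ratio / target_Tstar_frac + 1.0) / gpt
    else:
        # (ratio/(1-eps)) / (gpt - 1) = target
        if gpt <= 1.0:
            raise ValueError("no interior critical point: gamma*p*tau_I <= 1")
        one_minus_eps = d.ratio / (target_Tstar_frac * (gpt - 1.0))
    eps = 1.0 - one_minus_eps
    if not (0 <= eps < 1):
        raise ValueError(
            f"target T*/N_cells = {target_Tstar_frac} not reachable with "
            f"efficacy in [0, 1) for mode {mode.value} (got eps = {eps:.4g})"
        )
    return eps
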