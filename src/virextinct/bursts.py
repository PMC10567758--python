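"""Extinction probability under alternative burst-size distributions.

Earlier branching-process treatments of within-host infection conflated the
*timing* of virion release (continuous over the infectious lifespan vs. a
single burst at death) with the *distribution* of the total number released.
The extinction probability depends only on the latter: each produced virion
founds an independent lineage regardless of when it was released, so the
fixed point

    P = (1 - P_VI) + P_VI * G(P)

in terms of the burst law's probability generating function G fully
determines extinction.  This module evaluates that fixed point for the
geometric, Kronecker-delta, Poisson and negative-binomial burst laws at a
common mean burst size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

from scipy import optimize

__all__ = ["BurstModel", "BurstModelSpec", "extinction_prob_burst"]

_ROOT_GAP = 1e-9

BurstModel = str  # one of "geometric", "delta", "poisson", "negative_binomial"


@dataclass(frozen=True)
class BurstModelSpec:
    """A burst-size law with mean ``B`` and per-virion success probability
    ``P_VI``.

    ``model`` is one of ``geometric``, ``delta``, ``poisson``,
    ``negative_binomial`` (the latter requires ``n_I``).  For the delta model
    with non-integer B the continuous extension ``G(P) = P**B`` of the
    generating function is used.
    """

    model: BurstModel
    B: float
    P_VI: float
    n_I: Optional[int] = None

    def __post_init__(self) -> None:
        if self.model not in ("geometric", "delta", "poisson", "negative_binomial"):
            raise ValueError(f"unknown burst model: {self.model!r}")
        if not self.B > 0:
            raise ValueError("mean burst size B must be positive")
        if not (0 < self.P_VI <= 1):
            raise ValueError("P_VI must lie in (0, 1]")
        if self.model == "negative_binomial":
            if self.n_I is None or self.n_I < 1:
                raise ValueError("negative_binomial requires integer n_I >= 1")

    def pgf(self) -> Callable[[float], float]:
        B = self.B
        if self.model == "geometric":
            return lambda P: 1.0 / (1.0 + B * (1.0 - P))
        if self.model == "delta":
            return lambda P: P**B
        if self.model == "poisson":
            return lambda P: math.exp(-B * (1.0 - P))
        nI = self.n_I
        return lambda P: (B * (1.0 - P) / nI + 1.0) ** (-nI)


def extinction_prob_burst(spec: BurstModelSpec) -> float:
    """Smallest fixed point in [0, 1] of P = (1 - P_VI) + P_VI * G(P).

    Returns exactly 1 in the subcritical/critical regime ``B * P_VI <= 1``
    (the mean offspring number of the embedded branching process).  In the
    supercritical regime the non-trivial root is found by bracketed root
    finding on [0, 1 - 1e-9], excluding the trivial root at 1.
    """
    if spec.B * spec.P_VI <= 1.0:
        return 1.0
    G = spec.pgf()

    def f(P: float) -> float:
        return (1.0 - spec.P_VI) + spec.P_VI * G(P) - P

    lo, hi = 0.0, 1.0 - _ROOT_GAP
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        # P_VI = 1 with G(0) = 0 (delta law): certain first infection and a
        # guaranteed burst make 0 the smallest fixed point
        return 0.0
    if not (flo > 0 > fhi):
        raise RuntimeError(
            f"burst extinction root not bracketed for {spec.model}: "
            f"f(0)={flo:.3g}, f(1-eps)={fhi:.3g}"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16))
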