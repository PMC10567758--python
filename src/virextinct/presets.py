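"""Packaged parameter presets, keyed by the figure they reproduce.

The baseline is the SARS-CoV-2 in-host parameter set of Czuppon et al.
(exponential infectious phase, n_I = 1), with beta fixed from R0 = 7.69:

    p = 11.2/24 IV/(cell h), tau_E = 24/5 h, tau_I = 24/0.595 h,
    c = 10/24 /h, n_E = n_I = 1, N_cells = 4e4, gamma = 1, s = 1 mL, V0 = 1.

Antiviral-treated presets state their exact condition (a target value of
T*/N_cells) rather than the rounded efficacy.
"""

from __future__ import annotations

from .params import (
    AntiviralMode,
    InfectionParameters,
    apply_antiviral,
    AntiviralIntervention,
    efficacy_for_target_fraction,
)

__all__ = ["czuppon_baseline", "treated_preset", "PRESETS"]

BASELINE_R0 = 7.69

_BASELINE_KW = dict(
    p=11.2 / 24,
    c=10 / 24,
    gamma=1.0,
    tau_E=24 / 5,
    tau_I=24 / 0.595,
    n_E=1,
    n_I=1,
    N_cells=40_000,
    s=1.0,
    V0=1,
    I0=0,
)


def czuppon_baseline(**overrides) -> InfectionParameters:
    """Baseline (no-antiviral) parameter set; beta derived from R0 = 7.69."""
    kw = {**_BASELINE_KW, **overrides}
    return InfectionParameters.from_R0(BASELINE_R0, **kw)


def treated_preset(
    target_Tstar_frac: float,
    mode: AntiviralMode | str = AntiviralMode.reduce_p,
    **overrides,
) -> InfectionParameters:
    """Baseline under an antiviral tuned so T*/N_cells hits the target."""
    base = czuppon_baseline(**overrides)
    eps = efficacy_for_target_fraction(base, mode, target_Tstar_frac)
    return apply_antiviral(base, AntiviralIntervention(mode=mode, efficacy=eps))


# Figure-keyed presets: callables returning InfectionParameters.
PRESETS = {
    "fig4_baseline": czuppon_baseline,
    "fig5_p_Tstar0.5": lambda: treated_preset(0.5),
    "fig6a_p_Tstar0.6": lambda: treated_preset(0.6),
    "fig6b_p_Tstar0.7": lambda: treated_preset(0.7),
    "fig6c_p_Tstar0.85": lambda: treated_preset(0.85),
    "fig7_p_Tstar0.85": lambda: treated_preset(0.85),
    "fig10a_beta_eps0.86": lambda: apply_antiviral(
        czuppon_baseline(),
        AntiviralIntervention(mode=AntiviralMode.reduce_beta, efficacy=0.86),
    ),
    "fig17a_beta_eps0.81_V10": lambda: apply_antiviral(
        czuppon_baseline(V0=10),
        AntiviralIntervention(mode=AntiviralMode.reduce_beta, efficacy=0.81),
    ),
}
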