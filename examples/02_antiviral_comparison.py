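"""Comparing antiviral modes of action.

Three prophylactic antivirals at the same efficacy eps act differently:
reducing the entry rate (beta), the production rate (p), or the post-entry
success probability (gamma).  This script prints the critical efficacies
(where establishment vanishes), the half-maximal efficacies eps50, and a
small sweep showing that the gamma-antiviral dominates everywhere.
"""

import numpy as np

import virextinct as vx

base = vx.czuppon_baseline()
modes = ("reduce_gamma", "reduce_beta", "reduce_p")

print("critical efficacy (R0 -> 1):")
for mode in modes:
    print(f"  {mode:13s}: {vx.critical_efficacy(base, mode):.3f}")

print("\neps50 (halves single-virion establishment):")
for mode in modes:
    print(f"  {mode:13s}: {100 * vx.epsilon_50(base, mode, V0=1):.0f}%")

print("\nestablishment probability vs efficacy:")
grid = np.array([0.0, 0.4, 0.8, 0.86])
sweeps = {m: vx.sweep(base, m, grid, V0=1) for m in modes}
print("  eps   " + "  ".join(f"{m:>13s}" for m in modes))
for i, eps in enumerate(grid):
    row = "  ".join(f"{sweeps[m].establishment[i]:13.4f}" for m in modes)
    print(f"  {eps:.2f}  {row}")

# At every efficacy the gamma-antiviral gives the lowest establishment
# probability: it removes virions without letting them re-try entry (unlike
# beta) and blocks all progeny of an entered virion (unlike p).
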