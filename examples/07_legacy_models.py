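"""Derive diet and appetite lines from two earlier leptin models.

The operating-point framework is model-agnostic: any mechanism that makes
steady-state fat rise with controlled intake and ad-libitum intake fall
with fat yields the same geometry.  Here the two curves are derived from
the Tam et al. (2009) and Jacquier et al. (2015) models (with synthetic
representative parameters -- see presets/*_synthetic.yaml) and their
crossings located.
"""

import numpy as np

import adipoint as ap
from adipoint import legacy

F = np.linspace(0.01, 60, 5)

tam = legacy.tam_lines(F, legacy.load_tam_parameters())
print("Tam-derived lines (sampled):")
print(tam.round(3).to_string(index=False))
F_tam, u_tam = legacy.compare_operating_points("tam")
print(f"Tam operating point: F = {F_tam:.3f}, u = {u_tam:.3f}\n")

jac = legacy.jacquier_lines(F, legacy.load_jacquier_parameters())
print("Jacquier-derived lines (sampled):")
print(jac.round(3).to_string(index=False))
F_jac, u_jac = legacy.compare_operating_points("jacquier")
print(f"Jacquier operating point: F = {F_jac:.3f}, u = {u_jac:.3f}\n")

F_op, u_op = legacy.compare_operating_points("operating-point", n=6)
print(f"operating-point model at n=6: F = {F_op:.4f}, u = {u_op:.4f}")

# Both legacy models produce a rising diet curve and a falling appetite
# curve, hence a unique operating point -- but neither predicts the
# quadratic leptin-fat population relation, because their leptin
# production does not depend on recent food intake.
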