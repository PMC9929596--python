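"""Solve the operating point: where the diet and appetite lines cross.

The diet line gives the steady-state fat maintained by a controlled food
intake; the appetite line gives the ad-libitum intake elicited by a given
fat level.  Their intersection -- the operating point -- is the fat/intake
steady state of the individual, and the leptin level there equals the
half-effect concentration KL whenever fat sits above the critical level.
"""

import adipoint as ap

p = ap.load_parameters("default")
op = ap.solve_operating_point(p)

print(f"operating point:  fat = {op.Fst:.4f}, intake = {op.ust:.4f}, "
      f"leptin = {op.Lst:.4f}")
print(f"critical fat Fc = {op.Fc:.4f} (intake locks at umax below this)")
print(f"resistance threshold Kcrit = {op.Kcrit:.4f}; regime: {op.regime}")

# severe leptin resistance pins intake at the satiety cap
resistant = ap.solve_operating_point(p.with_(KL=2 * op.Kcrit))
print(f"\nwith KL = 2*Kcrit: fat = {resistant.Fst:.4f}, "
      f"intake = {resistant.ust:.4f} (= umax), regime: {resistant.regime}")

# Fat above critical -> leptin equals KL exactly; intake varies inversely
# with fat.  In the resistant regime intake is capped and fat is set by the
# diet line alone, so further resistance changes nothing.
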