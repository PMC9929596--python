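# SYNTHETIC representative parameter set for the Tam et al. (2009) model
# variant without an explicit set-point controller.  These values are NOT the
# calibrated constants of the original publication (take those from its
# parameter table for quantitative work); they are chosen so the derived diet
# curve rises, the appetite curve falls, and the two cross once on a fat grid
# of order 0-60 mass units.
alphaL: 1.0      # plasma leptin synthesis per unit fat / blood volume
gammaL_t: 1.0    # renal leptin clearance rate
k1: 2.0          # saturable brain-transport capacity
k2: 1.0          # saturable brain-transport half-point
k3: 0.1          # linear brain-diffusion coefficient
k4: 5.0          # maximal food intake
k5: 1.0          # brain-leptin half-effect on intake
k6: 0.12         # energy-expenditure rate per unit body mass
k7: 0.8          # leptin amplification of expenditure
k8: 1.0          # half-point of the expenditure amplification
rho_food: 3.0    # metabolizable energy density of food
rho_F: 9.0       # energy density of fat
FFM: 20.0        # fat-free mass (held constant)
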