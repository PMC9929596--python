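# SYNTHETIC representative parameter set for the Jacquier et al. (2015) model
# variant with constant leptin-receptor density.  These values are NOT the
# calibrated constants of the original publication (take those from its
# parameter table for quantitative work); they are chosen so the derived diet
# curve rises, the appetite curve falls, and the two cross once on a fat grid
# of order 0-60 mass units.
rho_FFM: 1.8     # caloric density of fat-free mass
rho_F: 9.4       # caloric density of fat
gammaOmega: 0.2  # body-composition function scale
alpha: 1.0       # body-composition exponential weight
kappa: 0.05      # body-composition exponential rate
C: 2.0           # integration constant of the fat-free-mass relation
eta: 0.05        # energy-expenditure rate
xi: 5.0          # basal energy expenditure
cal_density: 3.0 # caloric density of food (the source's gamma_E, renamed)
gammaL_j: 1.0    # leptin production per unit fat
deltaL: 1.0      # leptin degradation rate
phiR: 2.0        # maximal receptor response (phi x fixed receptor density R)
theta: 10.0      # Hill half-point of the receptor response
n_h: 2.0         # Hill exponent of the receptor response
gamma_u: 10.0    # intake production rate
delta_u: 1.0     # intake decay rate
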