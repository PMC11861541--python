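# pestrisk reference table v1: M&L contact fractions (dimensionless)
# Bands on AI concentration in the formulation, % by mass: [0,30) [30,60) [60,80) [80,100].
# Soluble granules share the liquid_concentrate row (alias in the loader).
# Note: the source text ranks powder above liquid concentrate verbally, but the
# printed coefficients rank liquid (0.030-0.090%) above powder (0.003-0.009%);
# the printed table is taken as ground truth here.
formulation,band_lo,band_hi,fraction
soluble_bag,0,30,0
soluble_bag,30,60,0
soluble_bag,60,80,0
soluble_bag,80,100,0
liquid_concentrate,0,30,0.0003
liquid_concentrate,30,60,0.00045
liquid_concentrate,60,80,0.0007
liquid_concentrate,80,100,0.0009
powder,0,30,3e-05
powder,30,60,5e-05
powder,60,80,7e-05
powder,80,100,9e-05
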