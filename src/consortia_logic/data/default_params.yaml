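# Calibrated default parameters for the USC/DSC XOR consortium model
# (consortia-logic/1).  Concentrations are molar; outputs are normalized
# fluorescence-equivalent units.  These are stand-in values anchored to the
# system's qualitative behaviour, not a fit to raw experimental data.
K_ara: 1.0e-4      # P_BAD half-activation (arabinose, M)
h_ara: 1.5
l_ara: 2.0e-3      # P_BAD leakage fraction
K_sal: 1.0e-6      # P_Sal half-activation (salicylate, M)
h_sal: 1.5
l_sal: 2.0e-3
K_ahl: 1.2e-9      # P_lux_rep half-repression (3OC6-HSL, M)
h_ahl: 4.0         # lumped cooperativity of the repressive lux stage
l_ahl: 5.0e-3      # residual P_lux_rep activity at saturating AHL
K_T: 0.5           # T7ptag:supD complementation constant (dimensionless)
sigma: 1.0e-6      # AHL produced per normalized LuxI per unit USC:DSC odds (M)
rbs_attenuation: 10.0   # fold-attenuation of the luxI RBS vs BBa_B0034
phi: 0.25          # USC fraction of the co-culture
beta: 1.0          # output gain
ahl_scaling: odds  # AHL scales with phi/(1-phi); "fraction" uses phi alone
ara_on: 1.0e-2     # saturating arabinose for logic states (M)
sal_on: 1.0e-4     # saturating salicylate for logic states (M)
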