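# 511-keV material constants used by the photon transport model.
#
# mu_511_mm: linear attenuation coefficient at 511 keV in mm^-1, computed
# as (mass attenuation coefficient at 511 keV from standard photon
# cross-section tabulations, coherent scattering excluded) x density:
#   water         0.0958 cm^2/g x 1.000 g/cm^3 = 0.0958 cm^-1
#   polyethylene  0.1005 cm^2/g x 0.960 g/cm^3 = 0.0965 cm^-1
#   aluminium     0.0837 cm^2/g x 2.699 g/cm^3 = 0.2259 cm^-1
#   lung (insert) 0.0958 cm^2/g x 0.300 g/cm^3 = 0.0287 cm^-1
#   air           0.0870 cm^2/g x 0.0012 g/cm^3 = 1.04e-4 cm^-1
#   LYSO          ~0.116 cm^2/g x 7.15 g/cm^3  = 0.829 cm^-1
#   lead          0.1572 cm^2/g x 11.35 g/cm^3 = 1.784 cm^-1
#   carbon fibre  0.0870 cm^2/g x 1.600 g/cm^3 = 0.139 cm^-1
#
# compton_fraction: fraction of 511-keV interactions treated as Compton
# scattering; the remainder is absorbed (photoelectric-equivalent).
air:          {mu_511_mm: 1.04e-5, compton_fraction: 0.999}
water:        {mu_511_mm: 9.58e-3, compton_fraction: 0.998}
polyethylene: {mu_511_mm: 9.65e-3, compton_fraction: 0.999}
aluminium:    {mu_511_mm: 2.259e-2, compton_fraction: 0.993}
lung:         {mu_511_mm: 2.87e-3, compton_fraction: 0.998}
lyso:         {mu_511_mm: 8.29e-2, compton_fraction: 0.68}
lead:         {mu_511_mm: 1.784e-1, compton_fraction: 0.42}
carbon_fibre: {mu_511_mm: 1.39e-2, compton_fraction: 0.999}
vacuum:       {mu_511_mm: 0.0, compton_fraction: 1.0}
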