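# Physical constants per gas species.  Henry solubilities at 298.15 K with
# van 't Hoff temperature dependence; Schmidt number cubic polynomials in
# temperature (deg C) for fresh water.  Edit or shadow this file to swap in
# an alternative parameterization.
CO2:
  henry_ref: 0.034          # mol L-1 atm-1 at 25 C
  henry_vant_hoff: 2400.0   # K
  schmidt_coeffs: [1911.1, -118.11, 3.4527, -0.04132]
CH4:
  henry_ref: 0.0014         # mol L-1 atm-1 at 25 C
  henry_vant_hoff: 1700.0   # K
  schmidt_coeffs: [1897.8, -114.28, 3.2902, -0.039061]
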