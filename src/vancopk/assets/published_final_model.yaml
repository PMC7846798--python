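# Published final covariate model for vancomycin in adult ICU patients.
# CL (L/h) = 0.78 + 0.036*DA - 0.007*Cr - 0.43*Burn_S + 0.067*TBW + 0.41*CRRT_S
# V  (L)   = 46.47 - 0.04*Cr - 0.07*age + 0.16*TBW
# Population means CL 3.16 L/h, V 60.71 L; IIV CV 41.72% (CL), 35.14% (V).
# omega diagonal entries are (CV * mean)^2; the residual-error magnitude was
# not published, so the packaged default is proportional CV 0.15 with a
# 0.5 ug/ml additive floor.
name: published-final
cl_covariates: [DA, Cr, Burn_S, TBW, CRRT_S]
v_covariates: [Cr, age, TBW]
theta_cl: [0.78, 0.036, -0.007, -0.43, 0.067, 0.41]
theta_v: [46.47, -0.04, -0.07, 0.16]
omega:
  - [1.738052, 0.0]
  - [0.0, 455.118]
residual_model: proportional
residual_scale: 0.15
additive_floor: 0.5
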