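# Published basic (covariate-free) model: CL 2.63 L/h, V 55.32 L with
# IIV CV 53.27% (CL) and 43.15% (V); omega diagonal = (CV * mean)^2.
name: published-basic
cl_covariates: []
v_covariates: []
theta_cl: [2.63]
theta_v: [55.32]
omega:
  - [1.962804, 0.0]
  - [0.0, 569.8046]
residual_model: proportional
residual_scale: 0.15
additive_floor: 0.5
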