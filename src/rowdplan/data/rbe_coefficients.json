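{
  "schema_version": 1,
  "description": "Affine RBE_max/RBE_min coefficient sets for phenomenological proton RBE models. RBE_max = intercept + slope_letd_over_abx * LETd / (alpha/beta)_x; RBE_min = intercept + slope_sqrt_abx_letd * sqrt((alpha/beta)_x) * LETd. LETd in keV/um, (alpha/beta)_x in Gy.",
  "models": [
    {
      "model": "MCN",
      "alpha_coeffs": {"intercept": 0.99064, "slope_letd_over_abx": 0.35605},
      "beta_coeffs": {"intercept": 1.1012, "slope_sqrt_abx_letd": -0.0038703},
      "provenance": "McNamara phenomenological proton RBE model fitted to the published in-vitro cell-survival library; dose-averaged-LET formulation."
    },
    {
      "model": "ROR_approx",
      "alpha_coeffs": {"intercept": 1.0, "slope_letd_over_abx": 0.578},
      "beta_coeffs": {"intercept": 1.0, "slope_sqrt_abx_letd": 0.0},
      "provenance": "Dose-averaged-LET approximation of the Rorvik LET-spectrum proton RBE model; RBE_min is fixed at 1 as in the original model. Named *_approx because the full model weights the LET spectrum rather than LETd."
    }
  ]
}
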