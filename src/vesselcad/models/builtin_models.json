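{
  "version": "1.0",
  "RS_deform": {
    "name": "RS_deform",
    "feature_names": ["R_std", "D_max", "D_std", "D_ratio"],
    "beta0": -1.098,
    "betas": [0.663, -1.086, -0.745, 2.395],
    "standardization": null,
    "vessel_class": "vein"
  },
  "RS_tumor": {
    "name": "RS_tumor",
    "feature_names": ["T_flat", "T_sphere"],
    "beta0": 1.526,
    "betas": [7.093, -9.826],
    "standardization": null,
    "vessel_class": null
  }
}
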