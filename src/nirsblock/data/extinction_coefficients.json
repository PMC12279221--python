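{
  "version": "1.0",
  "description": "Molar extinction coefficients of oxy- and deoxy-hemoglobin at the two CW-NIRS wavelengths, from the standard published hemoglobin compendium (base-10 values in 1/(cm*M)), converted here to natural-log units of 1/(uM*mm): eps_e = ln(10) * eps_10 * 1e-7. Swap this file to use a different extinction table.",
  "units": "1/(uM*mm), natural-log optical density",
  "wavelengths_nm": [760.0, 850.0],
  "hbo": [1.349315e-4, 2.436135e-4],
  "hbr": [3.565599e-4, 1.591843e-4]
}
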