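{
  "_comment": "ILLUSTRATIVE fruit-set quadratic, not a calibrated fit. The coefficients interpolate three plausible point values of the fruit-set fraction (0.70 at 14 degC, 0.875 at 18 degC, 0.90 at 30 degC); use your own calibration for real predictions.",
  "fruit_set": {
    "a": -0.56875,
    "b": 0.1270833333333333,
    "c": -0.0026041666666666665
  }
}
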