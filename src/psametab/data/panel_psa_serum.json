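{
  "name": "psa_serum",
  "description": "Published nine-metabolite serum logistic panel discriminating healthy controls (y=1) from active psoriatic arthritis, on relative-concentration units.",
  "positive_class": "HC",
  "intercept": -61.645,
  "coefficients": {
    "leucine": 2.991,
    "serine": 2.08,
    "alanine": 1.735,
    "glucose": 0.394,
    "methionine": 6.134,
    "isoleucine": -0.313,
    "valine": -0.072,
    "glycylproline": 0.256,
    "glutamine": 0.346
  },
  "threshold": 0.38
}
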