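{
  "I": {
    "name": "Index I",
    "markers": ["miR-4736", "miR-6836-3p"],
    "coefficients": [0.90, 0.55],
    "intercept": -11.3,
    "threshold": 0.0
  },
  "II": {
    "name": "Index II",
    "markers": ["miR-4736", "miR-6836-3p", "miR-4281"],
    "coefficients": [0.89, 0.54, 0.043],
    "intercept": -11.6,
    "threshold": 0.0
  },
  "III": {
    "name": "Index III",
    "markers": ["miR-4736", "miR-6836-3p", "miR-4281", "miR-762"],
    "coefficients": [1.00, 0.58, -1.01, 0.91],
    "intercept": -12.5,
    "threshold": 0.0
  },
  "IV": {
    "name": "Index IV",
    "markers": ["miR-4736", "miR-6836-3p", "miR-4281", "miR-762", "miR-658"],
    "coefficients": [0.84, 0.49, -1.30, 1.26, 0.43],
    "intercept": -14.8,
    "threshold": 0.0
  },
  "V": {
    "name": "Index V",
    "markers": ["miR-4736", "miR-6836-3p", "miR-4281", "miR-762", "miR-658", "miR-4649-5p"],
    "coefficients": [0.86, 0.45, -1.13, 1.34, 0.58, -0.25],
    "intercept": -16.0,
    "threshold": 0.0
  },
  "VI": {
    "name": "Index VI",
    "markers": ["miR-4736", "miR-6836-3p", "miR-4281", "miR-762", "miR-658", "miR-4649-5p", "miR-4665-3p"],
    "coefficients": [0.87, 0.52, -1.14, 1.31, 0.59, -0.22, -0.15],
    "intercept": -15.9,
    "threshold": 0.0
  },
  "VII": {
    "name": "Index VII",
    "markers": ["miR-4736", "miR-6836-3p", "miR-4281", "miR-762", "miR-658", "miR-4649-5p", "miR-4665-3p", "miR-663b"],
    "coefficients": [0.87, 0.54, -1.12, 1.28, 0.59, -0.20, -0.15, -0.035],
    "intercept": -15.8,
    "threshold": 0.0
  },
  "VIII": {
    "name": "Index VIII",
    "markers": ["miR-4736", "miR-6836-3p", "miR-4281", "miR-762", "miR-658", "miR-4649-5p", "miR-4665-3p", "miR-663b", "miR-4258"],
    "coefficients": [0.87, 0.55, -1.11, 1.29, 0.60, -0.18, -0.14, -0.038, -0.034],
    "intercept": -16.1,
    "threshold": 0.0
  }
}
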