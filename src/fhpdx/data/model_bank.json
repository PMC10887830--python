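{
  "thresholds": [12, 25, 40],
  "models": {
    "CSA": {
      "blue": {"K": 4.7059, "L1": -0.0041, "L2": -0.4309, "LE": -5, "RE": 50},
      "pink": {"K": 17.0615, "L1": 0.0112, "L2": -0.678, "LE": -5, "RE": 50},
      "red": {"K": 52.0386, "L1": -0.0249, "L2": -1.1452, "LE": -5, "RE": 50}
    },
    "CCA": {
      "blue": {"K": 5.829, "L1": -0.0175, "L2": -0.4254, "LE": 45, "RE": 105},
      "pink": {"K": 15.3719, "L1": 0.0281, "L2": -0.6869, "LE": 45, "RE": 105},
      "red": {"K": 41.0884, "L1": 0.1879, "L2": -1.2028, "LE": 45, "RE": 105}
    },
    "T1S": {
      "blue": {"K": 4.3672, "L1": 0.0187, "L2": -0.429, "LE": -5, "RE": 48},
      "pink": {"K": 17.8022, "L1": -0.0355, "L2": -0.6815, "LE": -5, "RE": 48},
      "red": {"K": 52.2012, "L1": -0.0393, "L2": -1.1483, "LE": -5, "RE": 48}
    },
    "CL": {
      "blue": {"K": 4.3264, "L1": 0.0432, "L2": -0.4527, "LE": -45, "RE": 92},
      "pink": {"K": 17.4075, "L1": 0.0341, "L2": -0.6955, "LE": -45, "RE": 92},
      "red": {"K": 51.7508, "L1": 0.0232, "L2": -1.1564, "LE": -45, "RE": 92}
    },
    "CranT": {
      "blue": {"K": 4.7627, "L1": -0.0175, "L2": -0.4333, "LE": -15, "RE": 35},
      "pink": {"K": 17.7856, "L1": -0.0508, "L2": -0.6855, "LE": -15, "RE": 35},
      "red": {"K": 54.5616, "L1": -0.2062, "L2": -1.1743, "LE": -15, "RE": 35}
    },
    "CervT": {
      "blue": {"K": 4.4493, "L1": 0.0301, "L2": -0.433, "LE": -25, "RE": 50},
      "pink": {"K": 17.3439, "L1": -0.0097, "L2": -0.6775, "LE": -25, "RE": 50},
      "red": {"K": 51.4267, "L1": 0.1307, "L2": -1.1542, "LE": -25, "RE": 50}
    },
    "C7S": {
      "blue": {"K": 4.4401, "L1": 0.0147, "L2": -0.4315, "LE": -25, "RE": 54},
      "pink": {"K": 17.5074, "L1": -0.0172, "L2": -0.6774, "LE": -25, "RE": 54},
      "red": {"K": 50.9228, "L1": 0.0547, "L2": -1.1472, "LE": -25, "RE": 54}
    },
    "TK": {
      "blue": {"K": 5.2067, "L1": -0.0249, "L2": -0.4419, "LE": -5, "RE": 56},
      "pink": {"K": 19.4449, "L1": -0.0732, "L2": -0.7108, "LE": -5, "RE": 56},
      "red": {"K": 55.2256, "L1": -0.0951, "L2": -1.187, "LE": -5, "RE": 56}
    }
  }
}
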