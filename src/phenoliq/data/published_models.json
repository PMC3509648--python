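{
  "equations": {
    "smlr_5": {
      "workflow": "SMLR",
      "descriptors": ["HNar", "GATS2v", "DISPe", "Mor32e", "Ke"],
      "coefficients": [5.527, -3.462, 4.161, -1.386, 1.634],
      "uncertainties": [0.584, 0.348, 0.320, 0.305, 0.514],
      "intercept": -4.451,
      "intercept_uncertainty": 1.012,
      "stats": {"N": 30, "R2": 0.962, "PRESS_int": 0.062, "Q2_int": 0.941, "PRESS_ext": 1.929, "Q2_ext": 0.760}
    },
    "smlr_4": {
      "workflow": "SMLR",
      "descriptors": ["HNar", "GATS2v", "DISPe", "Mor32e"],
      "coefficients": [0.771, -0.326, 0.467, -0.115],
      "uncertainties": [0.581, 0.348, 0.374, 0.356],
      "intercept": -0.686,
      "intercept_uncertainty": 1.092,
      "t_values": [11.19, -8.31, 11.07, -3.71],
      "stats": {"N": 30, "R2": 0.946, "PRESS_int": 0.080, "Q2_int": 0.924, "PRESS_ext": 1.847, "Q2_ext": 0.770}
    },
    "smlr_3": {
      "workflow": "SMLR",
      "descriptors": ["HNar", "GATS2v", "DISPe"],
      "coefficients": [7.574, -2.242, 3.792],
      "uncertainties": [0.615, 0.367, 0.442],
      "intercept": -0.740,
      "intercept_uncertainty": 1.149,
      "stats": {"N": 30, "R2": 0.917, "PRESS_int": 0.116, "Q2_int": 0.890, "PRESS_ext": 2.683, "Q2_ext": 0.666}
    },
    "ufs_smlr_6": {
      "workflow": "UFS-SMLR",
      "descriptors": ["Mp", "IDM", "DISPm", "Mor22v", "Mor28e", "HATS7p"],
      "coefficients": [29.480, 0.208, 0.208, -2.704, -1.650, 4.819],
      "uncertainties": [2.997, 0.056, 0.033, 1.121, 0.445, 1.610],
      "intercept": -18.788,
      "intercept_uncertainty": 1.974,
      "stats": {"N": 30, "R2": 0.912, "PRESS_int": 0.155, "Q2_int": 0.852, "PRESS_ext": 2.293, "Q2_ext": 0.715}
    },
    "ufs_smlr_5": {
      "workflow": "UFS-SMLR",
      "descriptors": ["Mp", "IDM", "DISPm", "Mor22v", "Mor28e"],
      "coefficients": [31.412, 0.216, 0.186, -3.350, -1.707],
      "uncertainties": [3.376, 0.065, 0.037, 1.270, 0.513],
      "intercept": 19.576,
      "intercept_uncertainty": 2.258,
      "t_values": [9.30, 9.30, 5.08, -2.64, -3.33],
      "stats": {"N": 30, "R2": 0.877, "PRESS_int": 0.189, "Q2_int": 0.820, "PRESS_ext": 1.906, "Q2_ext": 0.763}
    }
  },
  "ann": {
    "SMLR-ANN": {
      "n_inputs": 4, "n_hidden": 6, "n_outputs": 1,
      "hidden_weight_decay": 0.01, "output_weight_decay": 0.01,
      "hidden_activation": "tanh", "output_activation": "tanh",
      "PRESS_ext": 1.4841, "Q2_ext": 0.8145,
      "training_error": 0.0013, "test_error": 0.0021, "validation_error": 0.0042
    },
    "UFS-SMLR-ANN": {
      "n_inputs": 5, "n_hidden": 5, "n_outputs": 1,
      "hidden_weight_decay": 0.01, "output_weight_decay": 0.01,
      "hidden_activation": "exponential", "output_activation": "logistic",
      "PRESS_ext": 1.1021, "Q2_ext": 0.8622,
      "training_error": 0.0047, "test_error": 0.0009, "validation_error": 0.0031
    }
  },
  "ufs_selected_descriptors": [
    "IDM", "MATS6p", "Mp", "E1e", "MATS6e", "Mor30m", "AROM", "E3u",
    "Mor22v", "Mor28e", "Mor29m", "DISPm", "PJI3", "G3s", "MATS5e",
    "PJI2", "SIC4", "E2p", "Mor12e", "IVDE", "SPI", "HATS7p"
  ],
  "ufs_r2max": 0.90,
  "mp_values": {"Gallic acid": 0.64, "Gentisic acid": 0.65, "Salicylic acid": 0.67},
  "scrambling_intercepts": {"SMLR": 0.141, "UFS-SMLR": 0.172},
  "settings": {
    "pretreat_min_variance": 0.0005,
    "pretreat_constant_fraction": 0.5,
    "ufs_r2max": 0.90,
    "smlr_f_enter": 6.0,
    "smlr_f_remove": 3.0,
    "ann_n_networks": 500,
    "ann_hidden_range": [3, 8],
    "scrambling_n": 500
  }
}
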