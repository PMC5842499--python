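"""Published test-set performance values for the six packaged classifiers.

Frozen per-model precision/recall/F cells (3-dp), macro-averaged F, and
per-class errors, used by the metric-reproduction tests.
"""

# per model: ({class: (precision, recall, F)}, macro-F)
REFERENCE_METRICS = {
    "LR": (
        {
            "swim": (0.997, 0.998, 0.997), "headshake": (0.485, 0.696, 0.571),
            "rest": (0.973, 0.830, 0.896), "chafe": (0.842, 0.889, 0.865),
            "burst": (0.500, 0.200, 0.286),
        },
        0.723,
    ),
    "ANN": (
        {
            "swim": (0.997, 0.999, 0.998), "headshake": (0.611, 0.478, 0.537),
            "rest": (0.988, 0.920, 0.953), "chafe": (0.957, 0.815, 0.880),
            "burst": (0.533, 0.800, 0.640),
        },
        0.802,
    ),
    "RFG": (
        {
            "swim": (0.999, 0.996, 0.997), "headshake": (0.432, 0.826, 0.567),
            "rest": (1.000, 0.966, 0.983), "chafe": (0.831, 0.907, 0.867),
            "burst": (0.583, 0.700, 0.636),
        },
        0.810,
    ),
    "RFE": (
        {
            "swim": (0.999, 0.995, 0.997), "headshake": (0.375, 0.783, 0.507),
            "rest": (1.000, 0.966, 0.983), "chafe": (0.842, 0.889, 0.865),
            "burst": (0.636, 0.700, 0.667),
        },
        0.804,
    ),
    "GB": (
        {
            "swim": (0.998, 0.999, 0.999), "headshake": (0.889, 0.696, 0.780),
            "rest": (1.000, 0.955, 0.977), "chafe": (0.927, 0.944, 0.936),
            "burst": (0.714, 0.500, 0.588),
        },
        0.856,
    ),
    "VE": (
        {
            "swim": (0.998, 0.999, 0.999), "headshake": (0.850, 0.739, 0.791),
            "rest": (1.000, 0.955, 0.977), "chafe": (0.927, 0.944, 0.936),
            "burst": (0.778, 0.700, 0.737),
        },
        0.888,
    ),
}

# per model: per-class error (1 - recall) in canonical class order
REFERENCE_CLASS_ERRORS = {
    "LR": (0.002, 0.304, 0.170, 0.111, 0.800),
    "ANN": (0.001, 0.522, 0.080, 0.185, 0.200),
    "RFG": (0.004, 0.174, 0.034, 0.093, 0.300),
    "RFE": (0.005, 0.217, 0.034, 0.111, 0.300),
    "GB": (0.001, 0.304, 0.045, 0.056, 0.500),
    "VE": (0.001, 0.261, 0.045, 0.056, 0.300),
}
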