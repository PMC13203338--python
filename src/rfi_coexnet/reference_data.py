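"""Published reference values used as worked examples.

A 20-gene hub validation panel from a shrimp feed-efficiency study:
group-mean TPM in the high- and low-feed-efficiency extreme groups and
the reported per-gene test p-values.  These printed numbers serve as
fixed inputs for the fold-change and multiple-testing worked examples;
the reported p of 0.000 is printed at 3 decimals, so 5e-4 is used as its
upper bound where a positive value is required.

Two eigengene-trait correlations reported by the same study are included
for the Pearson p-value worked examples.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["hub_validation_panel", "PEARSON_EXAMPLES"]

_PANEL = [
    # tissue, module, gene, mean_high, mean_low, reported_log2fc, reported_p, reported_q
    ("intestine", "pink", "LOC113824170", 51.565, 40.647, -0.343, 0.018, 0.089),
    ("intestine", "pink", "LOC113811632", 29.023, 22.238, -0.384, 0.027, 0.091),
    ("intestine", "pink", "LOC113811631", 16.338, 11.489, -0.508, 0.002, 0.018),
    ("intestine", "pink", "LOC113811628", 20.105, 13.041, -0.624, 0.000, 0.007),
    ("intestine", "pink", "LOC113817752", 75.260, 62.011, -0.279, 0.019, 0.089),
    ("hepatopancreas", "darkgreen", "LOC113809216", 389.441, 331.609, -0.232, 0.022, 0.089),
    ("hepatopancreas", "darkgreen", "LOC113820990", 382.343, 313.175, -0.288, 0.034, 0.097),
    ("hepatopancreas", "darkgreen", "LOC113803489", 181.113, 164.899, -0.135, 0.111, 0.222),
    ("hepatopancreas", "darkgreen", "LOC113828445", 224.455, 201.614, -0.155, 0.095, 0.212),
    ("hepatopancreas", "darkgreen", "LOC113826027", 462.543, 431.229, -0.101, 0.264, 0.353),
    ("hepatopancreas", "white", "LOC113826007", 27.325, 23.598, -0.212, 0.184, 0.287),
    ("hepatopancreas", "white", "LOC113812926", 28.091, 24.969, -0.170, 0.187, 0.287),
    ("hepatopancreas", "white", "LOC113823424", 192.442, 166.761, -0.207, 0.368, 0.430),
    ("hepatopancreas", "white", "LOC113823492", 11.326, 13.288, 0.230, 0.221, 0.316),
    ("hepatopancreas", "white", "LOC113816458", 31.138, 24.468, -0.348, 0.318, 0.398),
    ("hepatopancreas", "lightgreen", "LOC113828906", 120.259, 93.283, -0.366, 0.049, 0.123),
    ("hepatopancreas", "lightgreen", "LOC113819214", 134.434, 116.268, -0.209, 0.171, 0.287),
    ("hepatopancreas", "lightgreen", "LOC113812241", 201.062, 182.631, -0.139, 0.402, 0.430),
    ("hepatopancreas", "lightgreen", "LOC113826330", 2424.827, 2692.666, 0.151, 0.408, 0.430),
    ("hepatopancreas", "lightgreen", "LOC113813421", 559.060, 524.247, -0.093, 0.672, 0.672),
]

# (r, n, reported_p): eigengene-vs-RFI and hub-expression-vs-ADG examples.
PEARSON_EXAMPLES = [
    (0.54, 50, 4.0e-5),
    (0.350, 60, 0.006),
]


def hub_validation_panel() -> pd.DataFrame:
    """The 20-gene validation panel as a DataFrame."""
    return pd.DataFrame(
        _PANEL,
        columns=[
            "tissue", "module", "gene_id", "mean_high", "mean_low",
            "reported_log2fc", "reported_p", "reported_q",
        ],
    )
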