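"""Published Brief MDS reference calibrations and sample descriptives.

Final partial-credit-model calibrations of the Brief Model Disability
Survey capacity and performance metrics from the two national
implementations (Chile ENDISC II, N = 12,265; Sri Lanka, N = 3,000),
together with the printed sociodemographic counts of those samples.  They
serve as worked-example fixtures: the location of every item must equal the
mean of its thresholds, recoding strategies illustrate the collapsing
notation, and the descriptive percentages recompute from the counts.

Rows marked ``"Collapsed Testlet"`` are super-items aggregating locally
dependent questions (their member codes are joined with ``&``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# (item, brief_code, recoding_strategy, outfit, infit, location, thresholds)
_CAPACITY = {
    "chile": [
        ("WG1", "B5002", "00122", 1.326, 1.258, -1.326, (-2.387, -0.264)),
        ("WG2", "B5003", "00122", 1.143, 1.153, 0.879, (0.556, 1.203)),
        ("WG3", "B5004", "00122", 0.615, 0.723, 0.060, (-0.320, 0.441)),
        ("WG4", "B5005", "00122", 0.870, 0.927, 0.512, (-0.794, 1.817)),
        ("WG5", "B5006", "00112", 0.370, 0.691, 1.748, (1.220, 2.277)),
        ("I5007", "B5007", "00122", 0.836, 0.918, -0.076, (-0.662, 0.510)),
        ("I5009", "B5008", "00122", 0.591, 0.713, 0.553, (0.351, 0.754)),
        ("I5011", "B5009", "01112", 0.988, 0.950, 0.471, (0.181, 0.761)),
        ("I5013 & I5014", "B5010", "Collapsed Testlet", 0.894, 0.899, -0.640,
         (-2.001, 0.720)),
        ("I5015", "B5011", "00122", 0.943, 1.004, 1.547, (1.110, 1.985)),
        ("I5017", "B5012", "00122", 0.846, 0.835, -1.180, (-2.351, -0.008)),
    ],
    "sri_lanka": [
        ("WG1 & WG2", "B5002 & B5003", "Collapsed Testlet", 1.666, 1.119,
         2.235, (2.235,)),
        ("WG3", "B5004", "00122", 1.005, 1.037, -0.831, (-1.453, -0.209)),
        ("WG4", "B5005", "00122", 1.011, 1.020, 0.137, (-0.761, 1.035)),
        ("WG5", "B5006", "00122", 0.878, 0.871, 1.559, (1.023, 2.096)),
        ("I5007", "B5007", "00122", 1.030, 1.079, 0.352, (-0.239, 0.943)),
        ("I5009", "B5008", "00122", 0.551, 0.654, 0.448, (-0.293, 1.190)),
        ("I5011", "B5009", "00122", 0.641, 0.683, 0.371, (-0.176, 0.919)),
        ("I5013 & I5014", "B5010", "Collapsed Testlet", 0.974, 1.082, 0.108,
         (-0.203, -1.788, 2.467, -0.044)),
        ("I5015", "B5011", "00122", 0.610, 0.717, 0.844, (-0.128, 1.815)),
        ("I5017", "B5012", "00122", 1.028, 1.037, -1.135, (-2.413, 0.143)),
    ],
}

_PERFORMANCE = {
    "chile": [
        ("I4005 & I4007", "B4001 & B4002", "012345678", 0.724, 0.786, -0.479,
         (-0.659, -1.382, -0.743, -0.838, -0.319, -0.435, 0.433, 0.112)),
        ("I4010 & I4012", "B4003 & B4004", "012345678", 0.433, 0.645, 0.594,
         (1.559, -0.661, 0.528, 0.027, 1.159, 0.304, 1.695, 0.142)),
        ("I4014", "B4005", "00122", 0.649, 0.761, 0.527, (0.247, 0.806)),
        ("I4021", "B4006", "01234", 0.998, 1.026, -0.458,
         (-1.903, -0.981, 0.100, 0.953)),
        ("I4031", "B4007", "01112", 0.859, 0.872, 0.588, (-0.798, 1.974)),
        ("I4035", "B4008", "01234", 1.119, 1.163, 0.370,
         (-0.461, 0.135, 0.819, 0.988)),
        ("I4037", "B4009", "00122", 0.680, 0.747, 0.150, (-0.106, 0.407)),
        ("I4040", "B4010", "01112", 1.179, 1.063, 0.083, (-0.263, 0.429)),
        ("I4045 & I4047", "B4011", "Collapsed Testlet", 1.290, 1.282, 2.762,
         (1.186, 1.488, 5.613)),
        ("I4048", "B4012", "01112", 0.880, 0.859, -0.038, (-0.668, 0.591)),
    ],
    "sri_lanka": [
        ("I4005 & I4007", "B4001 & B4002", "012345678", 0.773, 0.797, -0.685,
         (-1.098, -1.679, -1.062, -0.949, -0.476, -0.597, -0.118, 0.501)),
        ("I4010 & I4012", "B4003 & B4004", "012345678", 0.973, 0.953, 0.940,
         (1.395, -0.435, 0.610, 0.915, 1.592, 0.828, 1.536, 1.079)),
        ("I4014", "B4005", "00122", 0.563, 0.665, 1.089, (0.504, 1.673)),
        ("I4021", "B4006", "00122", 0.963, 0.952, -0.881, (-1.506, -0.255)),
        ("I4031", "B4007", "00122", 1.028, 0.957, 0.312, (-0.341, 0.965)),
        ("I4035", "B4008", "00122", 1.160, 1.157, 0.286, (-0.414, 0.987)),
        ("I4037", "B4009", "00122", 0.616, 0.683, 0.104, (-0.350, 0.559)),
        ("I4040", "B4010", "00122", 0.784, 0.801, 0.147, (-0.152, 0.446)),
        ("I4045 & I4047", "B4011", "Collapsed Testlet", 2.311, 1.371, 3.064,
         (1.672, 4.456)),
        ("I4048", "B4012", "00122", 0.986, 0.935, -0.522, (-0.873, -0.171)),
    ],
}

#: Published targeting / reliability / precision summary per country & scale.
TARGETING = {
    ("chile", "capacity"): {"difficulty_mean": 0.232, "difficulty_sd": 1.281,
                            "ability_mean": -1.544, "ability_sd": 1.338,
                            "psi": 0.788, "correlation": 0.984,
                            "explained_variance": 0.969},
    ("sri_lanka", "capacity"): {"difficulty_mean": 0.293, "difficulty_sd": 1.308,
                                "ability_mean": -1.189, "ability_sd": 1.477,
                                "psi": 0.805, "correlation": 0.838,
                                "explained_variance": 0.923},
    ("chile", "performance"): {"difficulty_mean": 0.310, "difficulty_sd": 1.258,
                               "ability_mean": -1.623, "ability_sd": 0.993,
                               "psi": 0.734, "correlation": 0.845,
                               "explained_variance": 0.715},
    ("sri_lanka", "performance"): {"difficulty_mean": 0.289, "difficulty_sd": 1.218,
                                   "ability_mean": -1.394, "ability_sd": 1.208,
                                   "psi": 0.805, "correlation": 0.875,
                                   "explained_variance": 0.792},
}

#: Sample sizes and sociodemographic counts with the published percentages.
SAMPLE_SIZES = {"sri_lanka": 3000, "chile": 12265}

SAMPLE_DESCRIPTIVES = [
    # (characteristic, level, country, count, printed_percent)
    ("gender", "male", "sri_lanka", 2602, 86.73),
    ("gender", "female", "sri_lanka", 398, 13.27),
    ("gender", "male", "chile", 5307, 43.27),
    ("gender", "female", "chile", 6958, 56.73),
    ("marital_status", "never_married", "sri_lanka", 395, 13.17),
    ("marital_status", "married", "sri_lanka", 2248, 74.93),
    ("marital_status", "cohabiting", "sri_lanka", 36, 1.20),
    ("marital_status", "separated_divorced", "sri_lanka", 61, 2.03),
    ("marital_status", "widowed", "sri_lanka", 260, 8.67),
    ("marital_status", "never_married", "chile", 3784, 30.85),
    ("marital_status", "married", "chile", 4324, 35.25),
    ("marital_status", "cohabiting", "chile", 1787, 14.57),
    ("marital_status", "separated_divorced", "chile", 1186, 9.67),
    ("marital_status", "widowed", "chile", 1184, 9.65),
    ("education", "no_schooling", "sri_lanka", 116, 3.87),
    ("education", "elementary", "sri_lanka", 354, 11.80),
    ("education", "vocational", "sri_lanka", 86, 2.87),
    ("education", "secondary", "sri_lanka", 2411, 80.37),
    ("education", "university", "sri_lanka", 16, 0.53),
    ("education", "postgraduate", "sri_lanka", 7, 0.23),
    ("education", "other", "sri_lanka", 10, 0.33),
    ("education", "no_schooling", "chile", 1321, 10.77),
    ("education", "elementary", "chile", 2336, 19.05),
    ("education", "vocational", "chile", 1201, 9.79),
    ("education", "secondary", "chile", 5172, 42.17),
    ("education", "university", "chile", 2013, 16.41),
    ("education", "postgraduate", "chile", 217, 1.77),
    ("education", "other", "chile", 5, 0.04),
    ("work", "working", "sri_lanka", 2699, 89.97),
    ("work", "working", "chile", 7090, 57.81),
]


def reference_calibration(country, scale) -> pd.DataFrame:
    """Reference calibration table for a country ('chile' / 'sri_lanka') and
    scale ('capacity' / 'performance'): one row per final item with its
    recoding strategy, outfit, infit, location and threshold vector."""
    source = {"capacity": _CAPACITY, "performance": _PERFORMANCE}[scale]
    rows = []
    for item, code, strategy, outfit, infit, location, thresholds in source[country]:
        rows.append({
            "item": item, "brief_code": code, "recoding_strategy": strategy,
            "outfit": outfit, "infit": infit, "location": location,
            "thresholds": np.asarray(thresholds, dtype=float),
        })
    return pd.DataFrame(rows)


def sample_descriptives() -> pd.DataFrame:
    """Published sociodemographic counts and percentages, with the
    percentage recomputed from count / sample size."""
    df = pd.DataFrame(SAMPLE_DESCRIPTIVES, columns=[
        "characteristic", "level", "country", "count", "printed_percent"])
    df["recomputed_percent"] = df.apply(
        lambda r: round(100.0 * r["count"] / SAMPLE_SIZES[r["country"]], 2), axis=1)
    return df
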