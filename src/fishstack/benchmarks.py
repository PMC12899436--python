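"""Published comparative benchmark of nuclear-segmentation methods.

A published comparison of segmentation approaches (manual marker counting,
adaptive-threshold segmentation, and the StarDist / NucleAIzer neural
segmenters) on follicular-lymphoma FISH sections reports, per case and
probe type, the genetic-classification detection metrics, the run-to-run
variances of nucleus counts, and per-sample nucleus/spot totals.  Those
printed values are bundled here as inputs for the metric-identity checks
in :mod:`fishstack.evaluation`: the F-measure must be recoverable from the
printed recall/precision pairs, Jaccard from Dice, population variance
from sample variance at the known run count, and the printed per-sample
averages from the printed rows.
"""

from __future__ import annotations

import pandas as pd

#: Per-case detection metrics: (probe, case, method, recall, precision,
#: f_measure, accuracy, dice, jaccard), as printed (2 d.p.).
CLASSIFICATION_METRICS: list[tuple] = [
    ("break_apart", "2261", "MarkerCounter", 0.83, 0.99, 0.90, 0.82, 0.90, 0.82),
    ("break_apart", "2261", "FISHQuant", 0.77, 0.97, 0.86, 0.75, 0.86, 0.75),
    ("break_apart", "2261", "StarDist", 0.92, 0.97, 0.94, 0.89, 0.94, 0.89),
    ("break_apart", "2261", "NucleAIzer", 0.92, 0.96, 0.94, 0.89, 0.94, 0.89),
    ("break_apart", "7170", "MarkerCounter", 0.84, 0.93, 0.88, 0.79, 0.88, 0.79),
    ("break_apart", "7170", "FISHQuant", 0.85, 0.94, 0.89, 0.80, 0.89, 0.80),
    ("break_apart", "7170", "StarDist", 0.90, 0.92, 0.91, 0.83, 0.91, 0.83),
    ("break_apart", "7170", "NucleAIzer", 0.90, 0.93, 0.92, 0.85, 0.92, 0.85),
    ("break_apart", "7168", "MarkerCounter", 0.90, 0.75, 0.82, 0.69, 0.82, 0.69),
    ("break_apart", "7168", "FISHQuant", 0.85, 0.78, 0.81, 0.68, 0.81, 0.68),
    ("break_apart", "7168", "StarDist", 0.92, 0.94, 0.93, 0.86, 0.93, 0.86),
    ("break_apart", "7168", "NucleAIzer", 0.95, 0.91, 0.93, 0.87, 0.93, 0.87),
    ("break_apart", "7166", "MarkerCounter", 0.90, 0.88, 0.89, 0.81, 0.89, 0.81),
    ("break_apart", "7166", "FISHQuant", 0.88, 0.85, 0.87, 0.76, 0.87, 0.76),
    ("break_apart", "7166", "StarDist", 0.92, 0.91, 0.91, 0.84, 0.91, 0.84),
    ("break_apart", "7166", "NucleAIzer", 0.93, 0.93, 0.93, 0.87, 0.93, 0.87),
    ("break_apart", "2910", "MarkerCounter", 0.87, 0.89, 0.88, 0.78, 0.88, 0.78),
    ("break_apart", "2910", "FISHQuant", 0.84, 0.86, 0.85, 0.74, 0.85, 0.74),
    ("break_apart", "2910", "StarDist", 0.92, 0.91, 0.92, 0.84, 0.92, 0.84),
    ("break_apart", "2910", "NucleAIzer", 0.92, 0.94, 0.93, 0.86, 0.93, 0.86),
    ("dual_fusion", "2261", "MarkerCounter", 0.83, 0.88, 0.85, 0.74, 0.85, 0.74),
    ("dual_fusion", "2261", "FISHQuant", 0.88, 0.91, 0.90, 0.82, 0.90, 0.82),
    ("dual_fusion", "2261", "StarDist", 0.95, 0.93, 0.94, 0.88, 0.94, 0.88),
    ("dual_fusion", "2261", "NucleAIzer", 0.95, 0.92, 0.94, 0.88, 0.94, 0.88),
    ("dual_fusion", "7170", "MarkerCounter", 0.90, 0.85, 0.88, 0.78, 0.88, 0.78),
    ("dual_fusion", "7170", "FISHQuant", 0.89, 0.88, 0.88, 0.79, 0.88, 0.79),
    ("dual_fusion", "7170", "StarDist", 0.93, 0.94, 0.93, 0.88, 0.93, 0.88),
    ("dual_fusion", "7170", "NucleAIzer", 0.92, 0.92, 0.92, 0.85, 0.92, 0.85),
    ("dual_fusion", "7168", "MarkerCounter", 0.74, 0.83, 0.78, 0.64, 0.78, 0.64),
    ("dual_fusion", "7168", "FISHQuant", 0.87, 0.89, 0.88, 0.79, 0.88, 0.79),
    ("dual_fusion", "7168", "StarDist", 0.92, 0.94, 0.93, 0.87, 0.93, 0.87),
    ("dual_fusion", "7168", "NucleAIzer", 0.91, 0.92, 0.91, 0.84, 0.91, 0.84),
    ("dual_fusion", "7166", "MarkerCounter", 0.87, 0.89, 0.88, 0.79, 0.88, 0.79),
    ("dual_fusion", "7166", "FISHQuant", 0.89, 0.88, 0.89, 0.79, 0.89, 0.79),
    ("dual_fusion", "7166", "StarDist", 0.93, 0.95, 0.94, 0.88, 0.94, 0.88),
    ("dual_fusion", "7166", "NucleAIzer", 0.94, 0.91, 0.93, 0.87, 0.93, 0.87),
    ("dual_fusion", "2910", "MarkerCounter", 0.85, 0.91, 0.88, 0.78, 0.88, 0.78),
    ("dual_fusion", "2910", "FISHQuant", 0.88, 0.88, 0.88, 0.78, 0.88, 0.78),
    ("dual_fusion", "2910", "StarDist", 0.95, 0.93, 0.94, 0.89, 0.94, 0.89),
    ("dual_fusion", "2910", "NucleAIzer", 0.92, 0.93, 0.92, 0.86, 0.92, 0.86),
]

#: Run-to-run nucleus-count variances per method and probe:
#: (method, probe, sample_variance, population_variance), printed at 2 d.p.
#: The underlying repeated-measurement count is n = 25 (VP/VS = 24/25).
VARIANCE_BENCHMARK: list[tuple] = [
    ("FISHQuant", "dual_fusion", 1339.66, 1286.07),
    ("FISHQuant", "break_apart", 1767.64, 1696.94),
    ("NucleAIzer", "dual_fusion", 1233.41, 1184.07),
    ("NucleAIzer", "break_apart", 559.92, 537.52),
    ("StarDist", "dual_fusion", 12983.58, 12464.24),
    ("StarDist", "break_apart", 14021.91, 13461.03),
]

VARIANCE_RUN_COUNT = 25

#: Per-sample nucleus and spot totals:
#: (case, method, nuclei_df, fitc_df, tritc_df, nuclei_ba, fitc_ba, tritc_ba)
#: where df = dual-fusion probe and ba = break-apart probe.
SPOT_COUNT_BENCHMARK: list[tuple] = [
    ("7166", "Manual", 435, 1479, 1530, 789, 2761, 2781),
    ("7166", "NucleAIzer", 737, 2505, 2556, 743, 2600, 2632),
    ("7166", "StarDist", 709, 2410, 2440, 843, 2950, 2954),
    ("7170", "Manual", 433, 1472, 1511, 640, 2240, 2275),
    ("7170", "NucleAIzer", 638, 2169, 2173, 765, 2677, 2699),
    ("7170", "StarDist", 873, 2968, 2977, 843, 2950, 2931),
    ("2910", "Manual", 491, 1670, 1677, 487, 1704, 1711),
    ("2910", "NucleAIzer", 732, 2488, 2433, 807, 2824, 2899),
    ("2910", "StarDist", 957, 3253, 3221, 940, 3290, 3310),
    ("7168", "Manual", 412, 1400, 1430, 608, 2128, 2201),
    ("7168", "NucleAIzer", 663, 2254, 2310, 781, 2733, 2760),
    ("7168", "StarDist", 685, 2352, 2329, 651, 2267, 2278),
    ("2261", "Manual", 429, 1458, 1421, 334, 1169, 1210),
    ("2261", "NucleAIzer", 735, 2499, 2514, 792, 2762, 2722),
    ("2261", "StarDist", 942, 3199, 3202, 1004, 3544, 3514),
]


def classification_frame() -> pd.DataFrame:
    return pd.DataFrame(
        CLASSIFICATION_METRICS,
        columns=["probe", "case", "method", "recall", "precision", "f_measure", "accuracy", "dice", "jaccard"],
    )


def variance_frame() -> pd.DataFrame:
    return pd.DataFrame(VARIANCE_BENCHMARK, columns=["method", "probe", "vs", "vp"])


def spot_count_frame() -> pd.DataFrame:
    return pd.DataFrame(
        SPOT_COUNT_BENCHMARK,
        columns=["case", "method", "nuclei_df", "fitc_df", "tritc_df", "nuclei_ba", "fitc_ba", "tritc_ba"],
    )
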