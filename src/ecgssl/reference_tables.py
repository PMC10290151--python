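"""Published worked-example tables used as fixed numerical inputs.

Two small tables from the clinical evaluation of a wearable 12-lead ECG
diagnostic system, transcribed as plain data:

* :data:`AF_THRESHOLD_TABLE` — confusion counts for atrial fibrillation on
  a 7000-recording test set at eleven candidate thresholds (plus the
  degenerate 0.004 row), with the published Sen/Spe/Prec/F1 at each.  The
  break-even point sits at threshold 0.528, the optimal-F1 point at 0.603,
  and the clinician fine-tuned point at 0.300 (sensitivity 0.900).
* :data:`ONLINE_CLASS_ROWS` — per-class confusion counts and metrics for a
  selection of diagnostic terms on a 12521-recording online test.

They serve as ground truth for the metric arithmetic and operating-point
selection, independent of any model.
"""

from __future__ import annotations

from .evaluate import ConfusionCounts

#: rows: threshold -> (TP, TN, FP, FN, F1, Sen, Prec, Spe)
AF_THRESHOLD_TABLE: list[tuple[float, int, int, int, int,
                               float, float, float, float]] = [
    (0.004, 380, 4592, 2028, 0, 0.273, 1.000, 0.158, 0.694),
    (0.100, 364, 5984, 636, 16, 0.528, 0.958, 0.364, 0.904),
    (0.201, 352, 6373, 247, 28, 0.719, 0.926, 0.588, 0.963),
    (0.300, 342, 6482, 138, 38, 0.795, 0.900, 0.713, 0.979),
    (0.400, 328, 6531, 89, 52, 0.823, 0.863, 0.787, 0.987),
    (0.528, 318, 6558, 62, 62, 0.837, 0.837, 0.837, 0.991),
    (0.603, 313, 6574, 46, 67, 0.847, 0.824, 0.872, 0.993),
    (0.704, 293, 6587, 33, 87, 0.830, 0.771, 0.899, 0.995),
    (0.802, 277, 6595, 25, 103, 0.812, 0.729, 0.917, 0.996),
    (0.900, 225, 6608, 12, 155, 0.729, 0.592, 0.949, 0.998),
    (0.971, 109, 6612, 8, 271, 0.439, 0.287, 0.932, 0.999),
    (0.998, 1, 6620, 0, 379, 0.005, 0.003, 1.000, 1.000),
]

BREAK_EVEN_THRESHOLD = 0.528
OPTIMAL_F1_THRESHOLD = 0.603
FINE_TUNED_THRESHOLD = 0.300

#: code -> (TP, TN, FP, FN, Sen, Spe, F1) on the online test set
ONLINE_CLASS_ROWS: dict[str, tuple[int, int, int, int,
                                   float, float, float]] = {
    "NECG": (2134, 9111, 764, 512, 0.807, 0.923, 0.770),
    "SR": (9200, 2046, 310, 965, 0.905, 0.868, 0.935),
    "AF": (690, 11368, 379, 84, 0.891, 0.968, 0.749),
    "PVC": (1490, 10392, 573, 66, 0.958, 0.948, 0.823),
    "CLBBB": (85, 12366, 45, 25, 0.773, 0.996, 0.708),
}


def af_curve() -> list[tuple[float, ConfusionCounts]]:
    """The AF threshold table as an operating curve."""
    return [(row[0], ConfusionCounts(tp=row[1], tn=row[2], fp=row[3],
                                     fn=row[4]))
            for row in AF_THRESHOLD_TABLE]
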