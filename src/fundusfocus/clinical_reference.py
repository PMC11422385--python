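"""Reference figures from the source clinical cohorts.

Numeric fixtures this package's arithmetic is checked against: the
development-cohort image counts per disease and split, the per-class
segmentation IoU report with its convex-combination score column, and
the internal-validation confusion-matrix sentences.

Fixture notes
-------------
* ``SEGMENTATION_REPORT``: the "retinal vessel" row as printed is
  internally inconsistent — its validation IoU and score duplicate the
  optic-disc row and do not follow from its own training IoU.  The row
  is kept verbatim and flagged ``consistent=False`` rather than
  silently corrected.
* ``CONFUSION_VALIDATION``: the DR sentence transposes its positive
  count and true-positive count (the printed tp exceeds p); the
  transposed reading reproduces every derived percentage in the
  sentence and is stored here, flagged ``transposed``.  The RVO
  sentence is irreparably inconsistent (its specificity contradicts its
  own counts and its margins do not match the cohort) and is therefore
  excluded from arithmetic checks.
"""

from __future__ import annotations

import pandas as pd

#: Development-cohort image counts (training / validation / internal test),
#: plus the two external test regions.
DATASET_SUMMARY = pd.DataFrame(
    [
        ("GLAU", 20823, 3022, 6003, 827, 446),
        ("AMD", 1594, 203, 443, 988, 319),
        ("RVO", 2859, 411, 860, 515, 429),
        ("DR", 6224, 832, 1697, 1025, 769),
        ("NORM", 41108, 5274, 11433, 976, 2162),
    ],
    columns=["disease", "train", "val", "test", "neimeng", "guangxi"],
)

#: Per-class segmentation IoU report (training IoU, validation IoU, score).
#: Score = 0.4 * training IoU + 0.6 * validation IoU, rounded to 6 decimals.
SEGMENTATION_REPORT = pd.DataFrame(
    [
        ("optic cup", 0.944777, 0.668727, 0.779147, True),
        ("optic disc", 0.988255, 0.847226, 0.903637, True),
        ("retinal vessel", 0.979049, 0.847226, 0.903637, False),
        ("macula", 0.911657, 0.340241, 0.568807, True),
        ("hemorrhage", 0.581202, 0.298246, 0.411429, True),
        ("cotton wool spots", 0.523801, 0.260054, 0.365553, True),
        ("drusen", 0.453724, 0.212842, 0.309194, True),
        ("atrophic arc", 0.423962, 0.362179, 0.386892, True),
        ("choroidal atrophy", 0.490633, 0.280601, 0.364614, True),
        ("choroidal neovascularization", 0.477546, 0.318491, 0.382113, True),
        ("exudation", 0.697246, 0.420536, 0.531220, True),
        ("macular degeneration", 0.537707, 0.085275, 0.266248, True),
        ("geographic atrophy", 0.993020, 0.350863, 0.607726, True),
        ("retinal nerve fiber layer defects", 0.960778, 0.651179, 0.775019, True),
        ("retinal defect", 0.451425, 0.129582, 0.258319, True),
        ("sclera exposure", 0.467256, 0.197711, 0.305529, True),
        ("tessellated fundus", 0.494761, 0.377320, 0.424297, True),
        ("retinal neovascularization", 0.996863, 0.333022, 0.598558, True),
        ("vitreous hemorrhage", 0.604791, 0.298930, 0.421275, True),
        ("retinal detachment", 0.964422, 0.381874, 0.614893, True),
    ],
    columns=["class", "iou_train", "iou_val", "score", "consistent"],
)

#: Internal-validation confusion sentences: positives, true positives,
#: negatives, false positives, and the derived percentages as reported.
CONFUSION_VALIDATION: dict[str, dict] = {
    "GLAU": {
        "p": 2198,
        "tp": 2115,
        "n": 6926,
        "fp": 278,
        "accuracy_pct": 96.04,
        "sensitivity_pct": 96,
        "consistent": True,
    },
    "AMD": {
        "p": 180,
        "tp": 168,
        "n": 8944,
        "fp": 110,
        "accuracy_pct": 98.66,
        "sensitivity_pct": 93,
        "consistent": True,
    },
    "DR": {
        # printed with p and tp transposed (tp 809 > p 727 as published);
        # the swap reproduces sens 90%, spec 97% and accuracy 96.35%
        "p": 809,
        "tp": 727,
        "n": 8315,
        "fp": 251,
        "accuracy_pct": 96.35,
        "sensitivity_pct": 90,
        "consistent": True,
        "transposed": True,
    },
    "RVO": {
        # counts contradict the sentence's own specificity and the cohort
        # margins; excluded from arithmetic checks
        "p": 411,
        "tp": 394,
        "n": 873,
        "fp": 99,
        "consistent": False,
    },
}
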