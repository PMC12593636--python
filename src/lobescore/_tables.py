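"""Reference per-lobe score count tables for the study cohort.

Counts of lobar severity scores (0/1/2) for the two pathologies over 627
examinations, per lobe (six columns: left upper, lingula, left lower, right
upper, right middle, right lower).  These counts define the default score
marginals of the phantom generator, so synthetic cohorts reproduce the
class imbalance the classifier has to cope with (bronchiectasis/wall
thickening dominated by score 1, mucus plugging by scores 0 and 1).
"""

from __future__ import annotations

import numpy as np

LOBE_NAMES = (
    "left_upper",
    "lingula",
    "left_lower",
    "right_upper",
    "right_middle",
    "right_lower",
)
LOBE_LABELS = {name: i + 1 for i, name in enumerate(LOBE_NAMES)}
PATHOLOGIES = ("bronchiectasis_wall", "mucus")

N_EXAMS = 627

# rows = score 0/1/2, columns = lobes in LOBE_NAMES order
SCORE_COUNTS: dict[str, np.ndarray] = {
    "bronchiectasis_wall": np.array(
        [
            [75, 205, 74, 42, 89, 78],
            [496, 374, 515, 465, 464, 511],
            [56, 48, 38, 120, 74, 38],
        ]
    ),
    "mucus": np.array(
        [
            [412, 433, 377, 291, 363, 375],
            [187, 175, 240, 260, 235, 241],
            [28, 19, 10, 76, 29, 11],
        ]
    ),
}

# overall (all-lobe) totals per score, for bookkeeping checks
SCORE_TOTALS: dict[str, np.ndarray] = {
    "bronchiectasis_wall": np.array([563, 2825, 374]),
    "mucus": np.array([2251, 1338, 173]),
}


def default_score_marginals() -> dict[str, np.ndarray]:
    """Per-pathology (6 lobes x 3 scores) probability tables.

    Each row is a lobe's score distribution P(score=0,1,2), i.e. the
    reference counts normalised by the 627-exam column total.
    """
    out = {}
    for pathology, counts in SCORE_COUNTS.items():
        out[pathology] = (counts / counts.sum(axis=0, keepdims=True)).T.copy()
    return out


def validate_score_counts() -> dict[str, bool]:
    """Bookkeeping checks on the reference tables.

    Returns a dict of named boolean checks: per-lobe columns sum to the
    number of examinations, and per-score row sums match the printed
    overall totals.
    """
    checks = {}
    for pathology, counts in SCORE_COUNTS.items():
        checks[f"{pathology}_columns_sum_to_n_exams"] = bool(
            np.all(counts.sum(axis=0) == N_EXAMS)
        )
        checks[f"{pathology}_rows_sum_to_overall"] = bool(
            np.all(counts.sum(axis=1) == SCORE_TOTALS[pathology])
        )
    return checks
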