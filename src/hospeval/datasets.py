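"""Published reference values bundled for cross-checking and reporting.

These numbers come from the printed tables of the original 14-hospital
evaluation study (the raw indicator matrix itself was never deposited):
the weighted-TOPSIS scores of the 14 hospitals and the observed/predicted
pairs of the study's PLSR error analysis.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "HOSPITAL_IDS",
    "published_topsis_scores",
    "published_plsr_pairs",
]

HOSPITAL_IDS = tuple(f"H{i}" for i in range(1, 15))

# hospital id -> (C_i, rank) of the published weighted-TOPSIS evaluation
_TOPSIS = {
    "H1": (0.6436, 2), "H2": (0.6752, 1), "H3": (0.6369, 3), "H4": (0.6257, 4),
    "H5": (0.4945, 9), "H6": (0.4261, 14), "H7": (0.5101, 7), "H8": (0.4923, 10),
    "H9": (0.4913, 11), "H10": (0.4804, 12), "H11": (0.4996, 8),
    "H12": (0.5551, 6), "H13": (0.4621, 13), "H14": (0.5855, 5),
}

# hospital id -> (observed C_i, PLSR prediction) of the published
# error analysis of the linear baseline
_PLSR_PAIRS = {
    "H1": (0.6436, 0.6377), "H2": (0.6752, 0.6242), "H3": (0.6369, 0.6225),
    "H4": (0.6257, 0.5879), "H5": (0.4945, 0.5405), "H6": (0.4261, 0.4526),
    "H7": (0.5101, 0.5374), "H8": (0.4923, 0.5429), "H9": (0.4913, 0.4674),
    "H10": (0.4804, 0.5051), "H11": (0.4996, 0.5619), "H12": (0.5551, 0.5217),
    "H13": (0.4621, 0.4817), "H14": (0.5855, 0.6410),
}


def published_topsis_scores() -> pd.DataFrame:
    """The published per-hospital relative approach degrees and ranks."""
    return pd.DataFrame(
        [(hid, c, rank) for hid, (c, rank) in _TOPSIS.items()],
        columns=["hospital_id", "c", "rank"],
    )


def published_plsr_pairs() -> pd.DataFrame:
    """The published (observed, predicted) pairs of the PLSR baseline."""
    return pd.DataFrame(
        [(hid, obs, pred) for hid, (obs, pred) in _PLSR_PAIRS.items()],
        columns=["hospital_id", "observed", "predicted"],
    )
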