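"""Bundled reference results from the original 98-subject clinical cohort.

The clinical study behind this tool enrolled 49 controls and 49 patients with
fecal incontinence (19 neurogenic, 6 myogenic, 24 idiopathic) and published
the classification performance of three trees:

* tree I   — selected for minimal classification cost (11 decision nodes);
* tree II  — selected for the minimal number of decision nodes (5);
* tree III — the cost/size compromise (7 decision nodes), with a full
  confusion matrix.

These counts are transcribed here so the metric arithmetic (accuracies,
sensitivities, costs, row percentages) can be recomputed and checked without
access to the raw recordings.  For trees I and II only per-class assignment
prose was published; where a full row placement is unknown the record keeps
the per-class correct counts, which suffice for accuracy and cost.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix

GROUP_SIZES = {"control": 49, "neurogenic": 19, "myogenic": 6, "idiopathic": 24}
N_TOTAL = 98


def tree_iii_confusion() -> ConfusionMatrix:
    """Published confusion matrix of tree III (rows observed, columns foreseen)."""
    counts = np.array(
        [
            [44, 1, 0, 4],   # control
            [1, 16, 0, 2],   # neurogenic
            [0, 3, 0, 3],    # myogenic
            [1, 2, 0, 21],   # idiopathic
        ]
    )
    return ConfusionMatrix(counts=counts)


def tree_i_confusion() -> ConfusionMatrix:
    """Tree I assignments reconstructed from the published prose.

    Controls: 46 correct, 1 to neurogenic, 2 to idiopathic.  Neurogenic: 17
    correct, 2 to idiopathic.  Idiopathic: 22 correct, 1 to neurogenic, 1 to
    control.  All 6 myogenic subjects were misassigned; their column placement
    was not published, so this matrix puts them in an arbitrary non-myogenic
    column — only row totals and the diagonal are authoritative.  Metrics that
    depend on the myogenic placement (e.g. specificities) should not be read
    off this matrix.
    """
    counts = np.array(
        [
            [46, 1, 0, 2],
            [0, 17, 0, 2],
            [6, 0, 0, 0],    # placement of the 6 errors unpublished
            [1, 1, 0, 22],
        ]
    )
    return ConfusionMatrix(counts=counts)


#: Published per-class correct counts for trees I and II (row placement of the
#: errors unpublished for tree II except "none correct" for myogenic).
TREE_I_CORRECT = {"control": 46, "neurogenic": 17, "myogenic": 0, "idiopathic": 22}
TREE_II_CORRECT = {"control": 44, "neurogenic": 15, "myogenic": 0, "idiopathic": 18}

#: Published structure of the three trees: (decision nodes, terminal nodes).
TREE_SIZES = {"I": (11, 12), "II": (5, 6), "III": (7, 8)}


def correct_counts_cost(correct: dict[str, int], sizes: dict[str, int] = GROUP_SIZES) -> float:
    """Unit classification cost from per-class correct counts."""
    n = sum(sizes.values())
    miss = sum(sizes[c] - correct[c] for c in sizes)
    return miss / n


def correct_counts_accuracy(correct: dict[str, int], sizes: dict[str, int] = GROUP_SIZES) -> float:
    return 1.0 - correct_counts_cost(correct, sizes)
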