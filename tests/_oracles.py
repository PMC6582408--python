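"""Independent reference implementations used to cross-check the package."""

import math


def naive_neighborhood(values, k, box_size):
    """Scan oracle for the neighborhood box: contiguous rank window of
    target size round(box_size * n), centered with ceil((h-1)/2) ranks
    below the focal cell, shifted inward at the extremes, then expanded
    over boundary-value ties.  Pure-python, O(n log n)."""
    values = list(values)
    n = len(values)
    h = max(1, round(box_size * n))
    order = sorted(range(n), key=lambda j: values[j])  # stable, like argsort
    rank = {j: r for r, j in enumerate(order)}
    lo = rank[k] - math.ceil((h - 1) / 2)
    lo = min(max(lo, 0), n - h)
    hi = lo + h - 1
    lov, hiv = values[order[lo]], values[order[hi]]
    return {j for j in range(n) if lov <= values[j] <= hiv}
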