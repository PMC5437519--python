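"""Independent brute-force oracles shared by the test modules."""

from collections import defaultdict

import numpy as np

from rainplot.congestion import _max_representable_distance
from rainplot.grid import y_to_row


def brute_force_profile(width, height, y_max, total_length, log_base=10.0):
    """Enumerate every integer distance, bucket by grid row, and pack events
    greedily at the row's minimum distance inside a closed bin-width window."""
    d_max = _max_representable_distance(y_max, log_base)
    rows = defaultdict(list)
    for d in range(1, d_max + 1):
        # exact log for base 10 (log(1000)/log(10) is one ulp under 3.0)
        y = np.log10(d) if log_base == 10.0 else np.log(d) / np.log(log_base)
        j = int(y_to_row(y, y_max, height))
        rows[j].append(d)
    bin_width = total_length / width
    distinct = np.zeros(height, dtype=int)
    overlap = np.zeros(height, dtype=int)
    for j, ds in rows.items():
        distinct[j] = len(ds)
        pos, k = 0.0, 1
        while pos + min(ds) <= bin_width:
            pos += min(ds)
            k += 1
        overlap[j] = k
    return distinct, overlap
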