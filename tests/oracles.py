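"""Independent brute-force oracles used to check the alignment core."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_sites(read: str, ref: str, max_mm: int
                      ) -> list[tuple[int, str, int]]:
    """Exhaustive scan: every (start, strand, mismatches) placement of `read`.

    Substitutions only, both strands, windows containing N excluded.  Kept
    deliberately naive (numpy sliding comparison) and independent of the
    package's seed-and-extend path.
    """
    out = []
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    L = len(read)
    if L > len(ref):
        return out
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
    has_n = (windows == ord("N")).any(axis=1)
    for strand, r in (("+", read), ("-", rc(read))):
        r_arr = np.frombuffer(r.encode(), dtype=np.uint8)
        mm = (windows != r_arr).sum(axis=1)
        for s in np.nonzero((mm <= max_mm) & ~has_n)[0]:
            out.append((int(s), strand, int(mm[s])))
    out.sort()
    return out
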