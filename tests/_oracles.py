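"""Independent brute-force oracles shared across test modules."""

import numpy as np

from raydock.pocket import SCAN_DIRECTIONS


def brute_force_psp(P, max_span):
    """Line-scan pocket oracle: walk every scan direction from every solvent
    point and look for flanking protein within max_span steps on both sides."""
    n = P.shape
    psp = np.zeros_like(P)
    for idx in np.argwhere(~P):
        for d in SCAN_DIRECTIONS:
            found = []
            for sign in (1, -1):
                hit = False
                for k in range(1, max_span + 1):
                    j = idx + sign * k * np.array(d)
                    if np.any(j < 0) or np.any(j >= n):
                        break
                    if P[tuple(j)]:
                        hit = True
                        break
                found.append(hit)
            if all(found):
                psp[tuple(idx)] = True
                break
    return psp
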