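"""Independent brute-force oracles used by the test suite."""

import numpy as np


def bresenham_oracle(p0, p1):
    """Nearest-pixel line sampler along the driving axis.

    For each step of the axis with the larger delta, pick the closest
    integer on the other axis (offsets round down at exact half-pixel ties,
    the classic Bresenham convention).
    """
    (r0, c0), (r1, c1) = p0, p1
    dr, dc = r1 - r0, c1 - c0
    n = max(abs(dr), abs(dc))
    if n == 0:
        return [(r0, c0)]
    pts = []
    for t in range(n + 1):
        fr = r0 + dr * t / n
        fc = c0 + dc * t / n
        if abs(dc) >= abs(dr):
            c = c0 + (1 if dc >= 0 else -1) * t
            off = abs(dr) * t / n
            r = r0 + (1 if dr >= 0 else -1) * int(np.ceil(off - 0.5))
        else:
            r = r0 + (1 if dr >= 0 else -1) * t
            off = abs(dc) * t / n
            c = c0 + (1 if dc >= 0 else -1) * int(np.ceil(off - 0.5))
        assert abs(r - fr) <= 0.5 + 1e-9 and abs(c - fc) <= 0.5 + 1e-9
        pts.append((r, c))
    return pts
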