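"""Independent oracles written before the implementations they check."""

import numpy as np


def brute_force_mean_nn(points: np.ndarray, radius: float) -> tuple[float, np.ndarray]:
    """Independent all-pairs nearest-neighbour oracle (plain double loop).

    Written against the distance definition only: geodesic on the unrolled
    cylinder with circumferential wrap.  Deliberately O(n²) and scalar.
    """
    pts = np.asarray(points, float)
    n = pts.shape[0]
    nn = np.full(n, np.inf)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dz = pts[i, 0] - pts[j, 0]
            dth = abs(pts[i, 1] - pts[j, 1]) % (2 * np.pi)
            dth = min(dth, 2 * np.pi - dth)
            d = (dz**2 + (radius * dth) ** 2) ** 0.5
            nn[i] = min(nn[i], d)
    return float(nn.mean()), nn
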