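"""Independent O(n^2) double-loop reference estimators used as oracles."""
import numpy as np

from standpattern.pattern_functions import _isotropic_fraction


def _weight(pt, d, window, correction):
    if correction == "isotropic":
        return float(_isotropic_fraction(pt.reshape(1, 2), np.array([d]), window)[0])
    return 1.0


def brute_force_k(points, window, r_grid, correction="none"):
    pts = np.asarray(points, float)
    n = len(pts)
    out = np.zeros(len(r_grid.r))
    for ri, r in enumerate(r_grid.r):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = float(np.hypot(*(pts[i] - pts[j])))
                if d <= r:
                    total += 1.0 / _weight(pts[i], d, window, correction)
        out[ri] = window.area / n**2 * total
    return out


def brute_force_g(points, window, r_grid, correction="none"):
    pts = np.asarray(points, float)
    n = len(pts)
    h = r_grid.ring_width
    lam = n / window.area
    out = np.zeros(len(r_grid.r))
    for ri, r in enumerate(r_grid.r):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = float(np.hypot(*(pts[i] - pts[j])))
                if r - h / 2 < d <= r + h / 2:
                    total += 1.0 / _weight(pts[i], d, window, correction)
        ring = np.pi * ((r + h / 2) ** 2 - (r - h / 2) ** 2)
        out[ri] = total / (lam * n * ring)
    return out
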