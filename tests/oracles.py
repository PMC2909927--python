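"""Independent brute-force oracles used to cross-check the fast implementations.

These deliberately re-derive results with naive enumeration (explicit loops
over candidates), sharing nothing with the library's vectorized code paths
beyond the documented mathematical definitions.
"""

import math

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.draw import circle_perimeter


def naive_contour_mean(image, cy, cx, r, thetas):
    """Mean of bilinear samples on one circle; None if no sample is valid.

    A sample is valid iff its full 4-pixel interpolation neighborhood lies in
    the image (floor(y) in [0, H-2], floor(x) in [0, W-2]).
    """
    H, W = image.shape
    total, n = 0.0, 0
    for t in thetas:
        y = cy - r * math.sin(t)
        x = cx + r * math.cos(t)
        y0, x0 = math.floor(y), math.floor(x)
        if y0 < 0 or x0 < 0 or y0 > H - 2 or x0 > W - 2:
            continue
        fy, fx = y - y0, x - x0
        val = ((1 - fy) * ((1 - fx) * image[y0, x0] + fx * image[y0, x0 + 1])
               + fy * ((1 - fx) * image[y0 + 1, x0] + fx * image[y0 + 1, x0 + 1]))
        total += val
        n += 1
    return (total / n) if n else None


def brute_force_integrodiff(image, centers, radius_range, sigma, n_angles,
                            arc_mask=()):
    """Exhaustive integrodifferential argmax: loops over every candidate.

    Returns ``((row, col, radius), score)`` under the declared definition:
    forward difference of contour means, 1-D Gaussian smoothing along radius,
    argmax with ties to smaller radius then row-major center order.
    """
    thetas = []
    for a in range(n_angles):
        t = 2 * math.pi * a / n_angles
        deg = math.degrees(t) % 360.0
        if any(lo <= deg <= hi for lo, hi in arc_mask):
            continue
        thetas.append(t)
    r0, r1 = radius_range
    radii = list(range(r0, r1 + 2))
    best = None
    for cy, cx in centers:
        means = [naive_contour_mean(image, cy, cx, r, thetas) for r in radii]
        deriv = np.zeros(len(radii) - 1)
        bad = np.zeros(len(radii) - 1, dtype=bool)
        for k in range(len(radii) - 1):
            if means[k] is None or means[k + 1] is None:
                bad[k] = True
            else:
                deriv[k] = means[k + 1] - means[k]
        smooth = gaussian_filter1d(deriv, sigma, mode="nearest")
        smooth[bad] = -np.inf
        for k in range(len(smooth)):
            cand = (smooth[k], radii[k], cy, cx)
            # strict comparisons implement the tie-break: first maximum wins
            # scanning radii ascending within row-major center order -- but the
            # outer loop is center-major, so compare explicitly:
            if best is None:
                best = cand
                continue
            if cand[0] > best[0]:
                best = cand
            elif cand[0] == best[0]:
                if (cand[1], cand[2], cand[3]) < (best[1], best[2], best[3]):
                    best = cand
    score, r, cy, cx = best
    return (cy, cx, r), score


def brute_force_hough(edges, radius_range):
    """Per-edge-pixel circle-of-centres voting with an explicit accumulator.

    Returns ``((row, col, radius), votes)`` with ties broken by smaller
    radius, then row-major center order.
    """
    H, W = edges.shape
    r0, r1 = radius_range
    radii = list(range(r0, r1 + 1))
    acc = np.zeros((len(radii), H, W), dtype=np.int64)
    ys, xs = np.nonzero(edges)
    for ey, ex in zip(ys, xs):
        for k, r in enumerate(radii):
            rr, cc = circle_perimeter(int(ey), int(ex), r)
            keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            acc[k, rr[keep], cc[keep]] += 1
    flat = acc.reshape(len(radii), -1)
    idx = int(np.argmax(flat))
    k, ci = divmod(idx, flat.shape[1])
    row, col = divmod(ci, W)
    return (row, col, radii[k]), int(flat[k, ci])
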