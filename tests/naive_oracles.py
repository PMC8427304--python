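"""Deliberately slow, independent reference implementations used as
oracles in tests.  These loop per pixel / per pair and share no code
with the package."""

import colorsys
import math
from fractions import Fraction

import numpy as np


def naive_pixel_features(img: np.ndarray) -> np.ndarray:
    """Per-pixel double-loop version of the 17 pixel features."""
    h_, w_, _ = img.shape
    rs, gs, bs, ss, vs = [], [], [], [], []
    bounds = [7, 23, 35, 90, 130, 169]
    names = ["red", "orange", "yellow", "green", "blue", "violet", "red"]
    counts = {c: 0 for c in set(names)}
    for y in range(h_):
        for x in range(w_):
            r, g, b = (float(v) for v in img[y, x])
            rs.append(r)
            gs.append(g)
            bs.append(b)
            _, s01, v01 = colorsys.rgb_to_hsv(r / 255, g / 255, b / 255)
            ss.append(s01 * 255.0)
            vs.append(v01 * 255.0)
            # exact rational hue (degrees) so boundary pixels classify
            # identically to any correctly-rounded float implementation
            ri, gi, bi = (int(v) for v in img[y, x])
            v_i, mn_i = max(ri, gi, bi), min(ri, gi, bi)
            if v_i == mn_i:
                hue = Fraction(0)
            elif v_i == ri:
                hue = Fraction(60 * (gi - bi), v_i - mn_i) % 360
            elif v_i == gi:
                hue = Fraction(60 * (bi - ri), v_i - mn_i) + 120
            else:
                hue = Fraction(60 * (ri - gi), v_i - mn_i) + 240
            hue_half = hue / 2
            k = sum(hue_half >= bd for bd in bounds)
            counts[names[k]] += 1
    n = h_ * w_

    def mv(xs):
        m = sum(xs) / n
        return m, sum((x - m) ** 2 for x in xs) / n

    rm, rv = mv(rs)
    gm, gv = mv(gs)
    bm, bv = mv(bs)
    sm, sv = mv(ss)
    vm, vv = mv(vs)
    shares = {c: counts.get(c, 0) / n
              for c in ("orange", "yellow", "green", "blue", "violet", "red")}
    warm = shares["red"] + shares["orange"] + shares["yellow"]
    return np.array([rm, gm, bm, rv, gv, bv, sm, sv, vm, vv,
                     shares["orange"], shares["yellow"], shares["green"],
                     shares["blue"], shares["violet"], shares["red"], warm])


def naive_gini(x) -> float:
    """Pairwise mean-absolute-difference Gini."""
    x = list(map(float, x))
    n = len(x)
    total = sum(x)
    acc = 0.0
    for a in x:
        for b in x:
            acc += abs(a - b)
    return acc / (2.0 * n * total)


def naive_pearson(x, y) -> float:
    """From-scratch covariance / sd Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)
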