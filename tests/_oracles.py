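"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the library's vectorized code paths: plain
Python loops and textbook formulas only.
"""

import numpy as np

from metalmap import RegionElementRecord


def summarize_oracle(emap, labels, zero_eps=0.0):
    """Per-pixel loop re-computation of the region/element summary table."""
    records = []
    for rid in sorted(labels.label_table):
        if rid == 0:
            continue
        for ci, element in enumerate(emap.channel_names):
            vals = []
            for r in range(emap.shape[0]):
                for c in range(emap.shape[1]):
                    if labels.labels[r, c] != rid:
                        continue
                    if emap.missing_mask[ci, r, c]:
                        continue
                    vals.append(float(emap.data[ci, r, c]))
            if not vals:
                continue
            pos = [v for v in vals if v > zero_eps]
            n = len(vals)
            # selection is the loop's job; the elementary statistics use
            # the standard library definitions on the gathered values
            va = np.array(vals)
            records.append(
                RegionElementRecord(
                    region_label=labels.label_table[rid],
                    element=element,
                    n_pixels=n,
                    n_nonzero=len(pos),
                    detect_frac=len(pos) / n,
                    mean=float(va.mean()),
                    mean_positive=float(np.mean(pos)) if pos else float("nan"),
                    median=float(np.median(vals)),
                    sd=float(va.std(ddof=1)) if n > 1 else float("nan"),
                    q05=float(np.quantile(vals, 0.05)),
                    q95=float(np.quantile(vals, 0.95)),
                )
            )
    return records


def point_in_polygon_evenodd(x, y, rings):
    """Crossing-number even-odd containment over all rings of a polygon."""
    crossings = 0
    for ring in rings:
        v = np.asarray(ring, dtype=float)
        n = len(v)
        for i in range(n):
            x1, y1 = v[i]
            x2, y2 = v[(i + 1) % n]
            if (y1 > y) != (y2 > y):
                xc = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
                if x < xc:
                    crossings += 1
    return crossings % 2 == 1


def rasterize_oracle(aset, shape, pixel_size_um):
    """Last-drawn-wins label raster via the even-odd point test."""
    rows, cols = shape
    out = np.zeros((rows, cols), dtype=int)
    for a in aset.annotations:
        rid = aset.label_table[a.label]
        rings = [a.exterior] + list(a.holes)
        for r in range(rows):
            for c in range(cols):
                if point_in_polygon_evenodd(
                    c * pixel_size_um, r * pixel_size_um, rings
                ):
                    out[r, c] = rid
    return out
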