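"""Summarize abundance per region and compare tumor vs normal tissue.

Per (region, element) the summary reports pixel counts, the detection
fraction (share of pixels above the zero threshold) and location/spread
statistics.  The two-group comparison fits a hurdle-gamma model per
element: the gamma part gives the log ratio of positive-part means, the
logistic part the detection odds ratio, with BH-adjusted q-values
across elements.
"""

import numpy as np

from metalmap import FixtureSpec, compare_groups, make_fixture, summarize_regions

fix = make_fixture(FixtureSpec(seed=7))
labels = fix.truth_labels  # ground-truth transfer; see example 04 for the real path

records = summarize_regions(fix.emap, labels)
print(f"{'region':8s} {'element':7s} {'n_px':>5s} {'detect':>7s} "
      f"{'mean+':>7s} {'median':>7s}")
for r in records:
    if r.element != "Zn66":
        continue
    print(f"{r.region_label:8s} {r.element:7s} {r.n_pixels:5d} "
          f"{r.detect_frac:7.3f} {r.mean_positive:7.2f} {r.median:7.2f}")

comps = compare_groups(
    fix.emap, labels,
    grouping={"Tumor": "tumor", "Stroma": "normal", "Fat": "normal"},
)
print("\ntumor vs normal, per element:")
for c in comps:
    print(f"  {c.element:5s} mean ratio {np.exp(c.log_mean_ratio):5.2f} "
          f"detect OR {c.detect_odds_ratio:5.2f} "
          f"p={c.p_value:.2e} q={c.q_value:.2e}")
# Zn66: tumor pixels carry ~2x the positive-part mean of normal regions
# and higher detection odds — the signal the generator planted.
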