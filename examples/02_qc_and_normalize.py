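"""QC-filter low-count cells with Otsu's method and normalize profiles.

Builds a bimodal population of per-cell totals (a low-count mode of
failed cells and a high-count mode of good cells), finds the cut-off
maximizing between-class variance, filters, then shows the two
normalizations used downstream: percent-of-total and centered log-ratio.
"""

import numpy as np

from glycoseq import (
    CountMatrix,
    clr_normalize,
    filter_cells,
    otsu_threshold,
    percent_normalize,
)

rng = np.random.default_rng(0)
n_lectins = 41
low = rng.lognormal(np.log(2_000), 0.25, size=30)
high = rng.lognormal(np.log(25_000), 0.25, size=60)
profiles = rng.dirichlet(np.ones(n_lectins) * 2, size=90)
totals = np.concatenate([low, high])
counts = CountMatrix(
    [f"cell{i:03d}" for i in range(90)],
    [f"L{j + 1:02d}" for j in range(n_lectins)],
    np.vstack([rng.multinomial(int(t), p) for t, p in zip(totals, profiles)]),
)

threshold = otsu_threshold(counts.totals())
kept, report = filter_cells(counts, threshold)
print(f"Otsu cut-off on total barcode counts: {threshold:,.0f}")
print(f"kept {len(report.kept_cells)} cells, removed {len(report.removed_cells)}")

percent = percent_normalize(kept)
print(f"\npercent profiles: every row sums to {percent.percent.sum(axis=1)[0]:.1f}")
print(f"mean percentage per probe: {percent.percent.mean():.3f}% (= 100/41)")

clr = clr_normalize(percent.to_frame())
print(f"CLR profiles: per-probe means are ~0 (max |mean| = {abs(clr.mean(axis=0)).max():.2e})")
# The cut-off separates the two total-count modes; cells above it keep
# their glycan profile for analysis.  Percent normalization removes depth
# differences between cells; CLR puts each probe on a comparable
# log-ratio scale across cells for PCA/PLS.
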