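"""QC and normalization of glycan count matrices.

Three transforms are used downstream of barcode counting:

* percent normalization — each cell's probe count divided by the cell's
  total panel count, times 100; the assay's native readout.
* CLR — centered log-ratio, ``log1p`` form: y = ln(x+1) − mean(ln(x+1))
  over a margin.  The default margin is per-probe (across cells), the
  convention used for antibody/lectin tag data.
* RNA log-normalization — y = ln(1 + s·x / colsum), s = 10,000 by default.

Low-count cells are removed by thresholding per-cell totals with Otsu's
method: the split over candidate thresholds (the sorted unique totals)
that maximizes between-class variance.  Cells are kept iff their total is
strictly greater than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, GlycanProfileMatrix
from .panel import ProbePanel


class QCError(ValueError):
    pass


def percent_normalize(
    counts: CountMatrix,
    denominator: str = "all_probes",
    panel: ProbePanel | None = None,
) -> GlycanProfileMatrix:
    """Percent-normalize barcode counts per cell.

    percent[c, p] = 100 * counts[c, p] / sum over denominator probes of
    counts[c, .].  With ``denominator="all_probes"`` every row of the
    result sums to 100; ``"lectins_only"`` divides by the lectin subtotal
    (requires ``panel`` to identify controls), in which case control
    probes can push row sums above 100.
    """
    x = counts.counts.astype(float)
    if denominator == "all_probes":
        denom = x.sum(axis=1)
    elif denominator == "lectins_only":
        if panel is None:
            raise QCError("lectins_only denominator requires the probe panel")
        lectin_cols = [
            i for i, p in enumerate(counts.probe_ids) if p in set(panel.lectin_ids)
        ]
        denom = x[:, lectin_cols].sum(axis=1)
    else:
        raise QCError(f"unknown denominator {denominator!r}")
    zero = np.flatnonzero(denom == 0)
    if len(zero):
        bad = [counts.cell_ids[i] for i in zero]
        raise QCError(f"zero-total cells cannot be percent-normalized: {bad}")
    percent = 100.0 * x / denom[:, None]
    return GlycanProfileMatrix(list(counts.cell_ids), list(counts.probe_ids), percent)


def otsu_threshold(totals, bins: int | None = None) -> float:
    """Otsu's threshold on a 1-D sample of per-cell totals.

    Candidates are the sorted unique values (exact mode, default) or
    histogram bin edges when ``bins`` is given.  The returned threshold is
    the largest value of the low class; the between-class variance
    w0·w1·(mu0 − mu1)^2 is maximized over all candidate splits.  Ties are
    broken toward the smaller threshold.
    """
    totals = np.asarray(totals, dtype=float)
    if totals.size < 2 or np.unique(totals).size < 2:
        raise QCError("degenerate histogram: need >= 2 distinct totals")
    if bins is None:
        values = np.sort(totals)
        uniq = np.unique(values)
        best_sigma, best_thr = -np.inf, uniq[0]
        n = values.size
        csum = np.cumsum(values)
        for thr in uniq[:-1]:
            k = np.searchsorted(values, thr, side="right")
            w0 = k / n
            w1 = 1.0 - w0
            mu0 = csum[k - 1] / k
            mu1 = (csum[-1] - csum[k - 1]) / (n - k)
            sigma_b = w0 * w1 * (mu0 - mu1) ** 2
            if sigma_b > best_sigma + 1e-15:
                best_sigma, best_thr = sigma_b, thr
        return float(best_thr)
    # binned mode: classic histogram Otsu, threshold reported as the upper
    # edge of the last low-class bin that contains data
    hist, edges = np.histogram(totals, bins=bins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    w = hist / hist.sum()
    best_sigma, best_thr = -np.inf, edges[1]
    for i in range(1, len(hist)):
        w0 = w[:i].sum()
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (w[:i] * mids[:i]).sum() / w0
        mu1 = (w[i:] * mids[i:]).sum() / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
        if sigma_b > best_sigma + 1e-15:
            low = totals[totals < edges[i]]
            best_sigma = sigma_b
            best_thr = low.max() if low.size else edges[i]
    return float(best_thr)


@dataclass
class QCReport:
    threshold: float
    kept_cells: list[str]
    removed_cells: list[str]
    total_min: float
    total_median: float
    total_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [self.threshold],
                "n_kept": [len(self.kept_cells)],
                "n_removed": [len(self.removed_cells)],
                "total_min": [self.total_min],
                "total_median": [self.total_median],
                "total_max": [self.total_max],
            }
        )


def filter_cells(counts: CountMatrix, threshold: float) -> tuple[CountMatrix, QCReport]:
    """Keep cells with total barcode count strictly greater than threshold."""
    if not np.isfinite(threshold):
        raise QCError("threshold must be finite")
    totals = counts.totals()
    keep = totals > threshold
    kept = [c for c, k in zip(counts.cell_ids, keep) if k]
    removed = [c for c, k in zip(counts.cell_ids, keep) if not k]
    report = QCReport(
        threshold=float(threshold),
        kept_cells=kept,
        removed_cells=removed,
        total_min=float(totals.min()) if totals.size else float("nan"),
        total_median=float(np.median(totals)) if totals.size else float("nan"),
        total_max=float(totals.max()) if totals.size else float("nan"),
    )
    filtered = CountMatrix(
        kept,
        list(counts.probe_ids),
        counts.counts[keep],
        counts.unassigned_per_cell[keep],
    )
    return filtered, report


def clr_normalize(matrix, margin: str = "per_probe"):
    """Centered log-ratio transform, log1p form.

    y = ln(x+1) − mean(ln(x+1)) along the chosen margin.  ``per_probe``
    centers each probe across cells (tag-data convention, Seurat margin 2
    for a cells-in-columns layout); ``per_cell`` centers each cell across
    probes.  Accepts a DataFrame (cells x probes) or array; returns the
    same type.
    """
    df = isinstance(matrix, pd.DataFrame)
    x = matrix.to_numpy(dtype=float) if df else np.asarray(matrix, dtype=float)
    if np.any(x < 0):
        raise QCError("CLR input must be non-negative")
    logx = np.log1p(x)
    if margin == "per_probe":
        y = logx - logx.mean(axis=0, keepdims=True)
    elif margin == "per_cell":
        y = logx - logx.mean(axis=1, keepdims=True)
    else:
        raise QCError(f"unknown margin {margin!r}")
    if df:
        return pd.DataFrame(y, index=matrix.index, columns=matrix.columns)
    return y


def lognormalize_rna(matrix, scale_factor: float = 10_000.0):
    """Log-normalize an RNA matrix (genes x cells).

    y = ln(1 + scale_factor * x / column_sum).  Columns are cells; a
    zero-sum cell is an error.
    """
    df = isinstance(matrix, pd.DataFrame)
    x = matrix.to_numpy(dtype=float) if df else np.asarray(matrix, dtype=float)
    if np.any(x < 0):
        raise QCError("RNA input must be non-negative")
    colsum = x.sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if len(zero):
        bad = [matrix.columns[i] for i in zero] if df else list(zero)
        raise QCError(f"zero-count cells cannot be log-normalized: {bad}")
    y = np.log1p(scale_factor * x / colsum[None, :])
    if df:
        return pd.DataFrame(y, index=matrix.index, columns=matrix.columns)
    return y
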