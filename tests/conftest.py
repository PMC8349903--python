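import numpy as np
import pytest

from glycoseq.panel import BarcodeLayout, ProbeClass, ProbePanel, ProbeSpec
from glycoseq.simulate import generate_panel


@pytest.fixture(scope="session")
def panel41():
    """A full-size 41-probe panel (39 lectins + 2 IgG controls)."""
    return generate_panel(n_probes=41, middle_len=8, min_hamming=3, seed=11)


TOY_LAYOUT = BarcodeLayout(
    trim_prefix_len=3, flank5="ACGTAC", flank3="TTGGCC", middle_len=6, read_len=26
)


def _toy_probe(i, barcode, cls=ProbeClass.LECTIN):
    return ProbeSpec(
        probe_id=f"T{i}",
        protein_name=f"toy_{i}",
        probe_class=cls,
        middle_barcode=barcode,
    )


@pytest.fixture(scope="session")
def toy_panel():
    """4 probes with 6 nt middle barcodes at pairwise Hamming distance >= 3."""
    barcodes = ["AAAAAA", "CCCAAA", "AAACCC", "CCCCCC"]
    probes = [_toy_probe(i + 1, b) for i, b in enumerate(barcodes)]
    return ProbePanel(tuple(probes), layout=TOY_LAYOUT)


@pytest.fixture(scope="session")
def close_panel():
    """2 probes only Hamming distance 2 apart (min_hamming relaxed), so a
    one-mismatch read can sit equidistant between them."""
    probes = [_toy_probe(1, "AAAAAA"), _toy_probe(2, "AACCAA")]
    return ProbePanel(tuple(probes), layout=TOY_LAYOUT, min_hamming=2)


def oracle_decode(read, panel, max_flank_mm=2, max_middle_mm=1):
    """Exhaustive Hamming-distance decoder, independent of the package's
    matcher: enumerates every probe's mismatch counts by direct slicing.

    Returns the assigned probe_id or None.
    """
    lay = panel.layout
    if len(read) < lay.min_read_len:
        return None
    s = lay.trim_prefix_len
    f5 = read[s : s + len(lay.flank5)]
    mid = read[s + len(lay.flank5) : s + len(lay.flank5) + lay.middle_len]
    f3 = read[
        s + len(lay.flank5) + lay.middle_len : s
        + len(lay.flank5)
        + lay.middle_len
        + len(lay.flank3)
    ]
    flank_mm = sum(a != b for a, b in zip(f5, lay.flank5)) + sum(
        a != b for a, b in zip(f3, lay.flank3)
    )
    if flank_mm > max_flank_mm:
        return None
    dists = {
        p.probe_id: sum(a != b for a, b in zip(mid, p.middle_barcode)) for p in panel
    }
    best = min(dists.values())
    if best > max_middle_mm:
        return None
    winners = [pid for pid, d in dists.items() if d == best]
    return winners[0] if len(winners) == 1 else None


def oracle_otsu(totals):
    """Brute-force Otsu: maximize between-class variance over every split
    at the sorted unique totals; threshold = largest low-class value."""
    totals = np.asarray(totals, dtype=float)
    uniq = np.unique(totals)
    best, best_thr = -np.inf, None
    for thr in uniq[:-1]:
        low = totals[totals <= thr]
        high = totals[totals > thr]
        w0, w1 = len(low) / len(totals), len(high) / len(totals)
        sigma = w0 * w1 * (low.mean() - high.mean()) ** 2
        if sigma > best + 1e-15:
            best, best_thr = sigma, thr
    return float(best_thr)
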