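"""Read-to-(cell, probe) assignment: the barcode counting stage.

Each 26 bp read is trimmed of its first ``trim_prefix_len`` bases and
sliced into observed 5' flank, middle barcode, and 3' flank.  A read is
assigned to the probe minimizing middle-barcode mismatches, with ties
broken by fewer flank mismatches, and accepted only if the middle
mismatches and the combined (5' + 3') flank mismatches are within the
policy maxima (defaults: 1 middle, 2 flank, both inclusive).  Equal-cost
ties across distinct probes are discarded as ambiguous by default.

Indels are not modeled; matching is substitution-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import CountMatrix, PairStreamStats, read_fastq_pairs
from .panel import BarcodeLayout, CellIndexMap, ProbePanel, hamming, min_pairwise_hamming


class MatchReason(str, Enum):
    OK = "ok"
    EXCEEDS_MIDDLE = "exceeds_middle"
    EXCEEDS_FLANK = "exceeds_flank"
    AMBIGUOUS = "ambiguous"
    MALFORMED = "malformed"


class AmbiguityRule(str, Enum):
    DISCARD = "discard"
    BEST_UNIQUE = "best_unique"


@dataclass(frozen=True)
class MatchPolicy:
    """Mismatch budgets for probe assignment.

    ``max_flank_mismatches`` is the budget shared across both flanks by
    default; set ``per_flank=True`` to apply it to each flank separately.
    """

    max_flank_mismatches: int = 2
    max_middle_mismatches: int = 1
    ambiguity_rule: AmbiguityRule = AmbiguityRule.DISCARD
    per_flank: bool = False

    def __post_init__(self) -> None:
        if self.max_flank_mismatches < 0 or self.max_middle_mismatches < 0:
            raise ValueError("mismatch maxima must be >= 0")


@dataclass(frozen=True)
class MatchResult:
    probe_id: str | None
    flank_mismatches: int | None
    middle_mismatches: int | None
    reason: MatchReason

    def __post_init__(self) -> None:
        assert (self.probe_id is not None) == (self.reason is MatchReason.OK)


UNASSIGNED_MALFORMED = MatchResult(None, None, None, MatchReason.MALFORMED)


def trim_and_partition(
    read_sequence: str, layout: BarcodeLayout
) -> tuple[str, str, str] | None:
    """Slice a read into (flank5_obs, middle_obs, flank3_obs).

    Returns None for reads too short for the layout (malformed).  Extra
    3' bases beyond the layout are ignored.
    """
    if len(read_sequence) < layout.min_read_len:
        return None
    start = layout.trim_prefix_len
    f5_end = start + len(layout.flank5)
    mid_end = f5_end + layout.middle_len
    f3_end = mid_end + len(layout.flank3)
    return (
        read_sequence[start:f5_end],
        read_sequence[f5_end:mid_end],
        read_sequence[mid_end:f3_end],
    )


class _PanelMatcher:
    """Vectorized middle-barcode distance computation for one panel."""

    def __init__(self, panel: ProbePanel):
        self.panel = panel
        self.layout = panel.layout
        self._codes = np.frombuffer(
            "".join(panel.middle_barcodes).encode(), dtype=np.uint8
        ).reshape(len(panel), self.layout.middle_len)

    def middle_distances(self, middle_obs: str) -> np.ndarray:
        obs = np.frombuffer(middle_obs.encode(), dtype=np.uint8)
        return (self._codes != obs).sum(axis=1)


def _flank_ok(f5_mm: int, f3_mm: int, policy: MatchPolicy) -> bool:
    if policy.per_flank:
        return f5_mm <= policy.max_flank_mismatches and f3_mm <= policy.max_flank_mismatches
    return f5_mm + f3_mm <= policy.max_flank_mismatches


def _match(
    read_sequence: str, matcher: _PanelMatcher, policy: MatchPolicy
) -> MatchResult:
    parts = trim_and_partition(read_sequence, matcher.layout)
    if parts is None:
        return UNASSIGNED_MALFORMED
    f5_obs, mid_obs, f3_obs = parts
    f5_mm = hamming(f5_obs, matcher.layout.flank5)
    f3_mm = hamming(f3_obs, matcher.layout.flank3)
    flank_mm = f5_mm + f3_mm
    if not _flank_ok(f5_mm, f3_mm, policy):
        return MatchResult(None, flank_mm, None, MatchReason.EXCEEDS_FLANK)
    dists = matcher.middle_distances(mid_obs)
    best = int(dists.min())
    if best > policy.max_middle_mismatches:
        return MatchResult(None, flank_mm, best, MatchReason.EXCEEDS_MIDDLE)
    winners = np.flatnonzero(dists == best)
    if len(winners) > 1:
        # Flanks are shared across probes, so flank mismatches cannot break
        # an equal-middle-distance tie; both ambiguity rules discard here.
        return MatchResult(None, flank_mm, best, MatchReason.AMBIGUOUS)
    return MatchResult(
        matcher.panel.probes[winners[0]].probe_id, flank_mm, best, MatchReason.OK
    )


def match_probe(
    read_sequence: str, panel: ProbePanel, policy: MatchPolicy | None = None
) -> MatchResult:
    """Assign one read to a probe under the trim-and-mismatch rule."""
    policy = policy or MatchPolicy()
    if policy.ambiguity_rule is AmbiguityRule.BEST_UNIQUE:
        mh = min_pairwise_hamming(panel.middle_barcodes)
        if policy.max_middle_mismatches >= mh:
            raise ValueError(
                f"best_unique requires max_middle_mismatches < panel minimum "
                f"pairwise distance ({mh})"
            )
    return _match(read_sequence, _PanelMatcher(panel), policy)


@dataclass
class DecodeReport:
    """Per-run tallies of the decoding outcome.

    Conservation: assigned + unassigned + unindexed + malformed = total,
    where unassigned = exceeds_middle + exceeds_flank + ambiguous.
    """

    total: int = 0
    assigned: int = 0
    exceeds_middle: int = 0
    exceeds_flank: int = 0
    ambiguous: int = 0
    malformed: int = 0
    unindexed: int = 0
    skipped_short: int = 0

    @property
    def unassigned(self) -> int:
        return self.exceeds_middle + self.exceeds_flank + self.ambiguous

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total", self.total),
            ("assigned", self.assigned),
            ("unassigned", self.unassigned),
            ("exceeds_middle", self.exceeds_middle),
            ("exceeds_flank", self.exceeds_flank),
            ("ambiguous", self.ambiguous),
            ("malformed", self.malformed),
            ("unindexed", self.unindexed),
            ("skipped_short", self.skipped_short),
        ]
        return pd.DataFrame(rows, columns=["category", "reads"])


def count_barcodes(
    read_tuples: Iterable[tuple[str, str, str]],
    index_map: CellIndexMap,
    panel: ProbePanel,
    policy: MatchPolicy | None = None,
) -> tuple[CountMatrix, DecodeReport]:
    """Count decoded barcodes per (cell, probe) from a read-tuple stream.

    ``read_tuples`` yields (read1_sequence, i5, i7), e.g. from
    :func:`glycoseq.io.read_fastq_pairs`.  Reads whose index pair is not in
    the map are tallied as unindexed; reads whose probe decoding fails are
    tallied per reason and in the cell's unassigned count.  The result is
    deterministic and independent of input order.
    """
    policy = policy or MatchPolicy()
    matcher = _PanelMatcher(panel)
    cells = index_map.cell_ids
    cell_pos = {c: i for i, c in enumerate(cells)}
    probe_pos = {p: i for i, p in enumerate(panel.probe_ids)}
    counts = np.zeros((len(cells), len(panel)), dtype=np.int64)
    unassigned = np.zeros(len(cells), dtype=np.int64)
    report = DecodeReport()

    for seq, i5, i7 in read_tuples:
        report.total += 1
        cell = index_map.lookup(i5, i7)
        if cell is None:
            report.unindexed += 1
            continue
        result = _match(seq, matcher, policy)
        if result.reason is MatchReason.OK:
            counts[cell_pos[cell], probe_pos[result.probe_id]] += 1
            report.assigned += 1
        else:
            unassigned[cell_pos[cell]] += 1
            if result.reason is MatchReason.EXCEEDS_MIDDLE:
                report.exceeds_middle += 1
            elif result.reason is MatchReason.EXCEEDS_FLANK:
                report.exceeds_flank += 1
            elif result.reason is MatchReason.AMBIGUOUS:
                report.ambiguous += 1
            else:
                report.malformed += 1

    if report.total == 0:
        import warnings

        warnings.warn("empty input: no reads to count", stacklevel=2)
    return CountMatrix(cells, panel.probe_ids, counts, unassigned), report


def count_fastq(
    path_r1: str | Path,
    path_r2: str | Path,
    index_map: CellIndexMap,
    panel: ProbePanel,
    policy: MatchPolicy | None = None,
    index_r1: str | Path | None = None,
    index_r2: str | Path | None = None,
) -> tuple[CountMatrix, DecodeReport]:
    """Convenience wrapper: decode a FASTQ pair straight to a CountMatrix."""
    stats = PairStreamStats()
    stream = read_fastq_pairs(
        path_r1,
        path_r2,
        index_r1=index_r1,
        index_r2=index_r2,
        min_read_len=panel.layout.min_read_len,
        stats=stats,
    )
    matrix, report = count_barcodes(stream, index_map, panel, policy)
    report.skipped_short = stats.skipped_short
    return matrix, report
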