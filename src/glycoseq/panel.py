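"""Probe-panel model for DNA-barcoded lectin profiling.

A panel is an ordered set of probes (glycan-binding lectins plus IgG
negative controls), each identified by a unique "middle" barcode embedded
between two constant flank sequences shared by every probe.  Reads are 26 bp
amplicons: a short prefix that is trimmed, the 5' flank, the variable middle
barcode, and the 3' flank.  Unambiguous decoding under a one-mismatch middle
budget requires the middle barcodes to be pairwise Hamming distance >= 3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

DNA_ALPHABET = frozenset("ACGT")

PANEL_COLUMNS = [
    "probe_id",
    "protein_name",
    "probe_class",
    "middle_barcode",
    "specificity_tag",
]


class PanelError(ValueError):
    """Raised when a probe panel violates a structural invariant."""


class PanelCollisionError(PanelError):
    """Two probes share a middle barcode, or probe ids are duplicated."""


class AmbiguousPanelError(PanelError):
    """Middle barcodes closer than the minimum Hamming distance."""


class AlphabetError(PanelError):
    """A sequence contains characters outside {A, C, G, T}."""


class ProbeClass(str, Enum):
    LECTIN = "lectin"
    CONTROL = "control"


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _check_dna(seq: str, what: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"alphabet error: {what} contains non-ACGT characters {sorted(bad)}"
        )


@dataclass(frozen=True)
class BarcodeLayout:
    """Positional layout of a barcode read.

    Reads are sliced as: [trim_prefix_len][flank5][middle][flank3][ignored].
    Defaults give a 26 bp read with a 3-base trimmed prefix, 6 nt flanks and
    an 8 nt middle barcode.
    """

    trim_prefix_len: int = 3
    flank5: str = "ACGTAC"
    flank3: str = "TTGGCC"
    middle_len: int = 8
    read_len: int = 26

    def __post_init__(self) -> None:
        if self.trim_prefix_len < 0:
            raise PanelError("trim_prefix_len must be >= 0")
        _check_dna(self.flank5, "flank5")
        _check_dna(self.flank3, "flank3")
        if self.min_read_len > self.read_len:
            raise PanelError(
                f"layout needs {self.min_read_len} bases but read_len is {self.read_len}"
            )

    @property
    def min_read_len(self) -> int:
        return (
            self.trim_prefix_len + len(self.flank5) + self.middle_len + len(self.flank3)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BarcodeLayout":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**{k: cfg[k] for k in cfg if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class ProbeSpec:
    probe_id: str
    protein_name: str
    probe_class: ProbeClass
    middle_barcode: str
    specificity_tag: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.middle_barcode, f"middle barcode of {self.probe_id}")


@dataclass(frozen=True)
class ProbePanel:
    """An ordered, validated collection of DNA-barcoded probes.

    Invariants enforced at construction: unique probe ids, unique middle
    barcodes of uniform length equal to ``layout.middle_len``, and pairwise
    middle-barcode Hamming distance >= ``min_hamming`` (default 3, which
    guarantees unambiguous decoding at <= 1 middle mismatch).
    """

    probes: tuple[ProbeSpec, ...]
    layout: BarcodeLayout = field(default_factory=BarcodeLayout)
    min_hamming: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "probes", tuple(self.probes))
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelCollisionError(f"panel collision: duplicate probe ids {dups}")
        barcodes = [p.middle_barcode for p in self.probes]
        if len(set(barcodes)) != len(barcodes):
            dups = sorted({b for b in barcodes if barcodes.count(b) > 1})
            raise PanelCollisionError(
                f"panel collision: duplicate middle barcodes {dups}"
            )
        for p in self.probes:
            if len(p.middle_barcode) != self.layout.middle_len:
                raise PanelError(
                    f"middle barcode of {p.probe_id} has length "
                    f"{len(p.middle_barcode)}, layout expects {self.layout.middle_len}"
                )
        for a, b in itertools.combinations(self.probes, 2):
            d = hamming(a.middle_barcode, b.middle_barcode)
            if d < self.min_hamming:
                raise AmbiguousPanelError(
                    f"ambiguous panel: probes {a.probe_id} and {b.probe_id} have "
                    f"middle-barcode Hamming distance {d} < {self.min_hamming}"
                )

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def middle_barcodes(self) -> list[str]:
        return [p.middle_barcode for p in self.probes]

    @property
    def lectin_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes if p.probe_class is ProbeClass.LECTIN]

    @property
    def control_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes if p.probe_class is ProbeClass.CONTROL]

    def designed_read(self, probe: ProbeSpec, prefix: str = "", filler: str = "") -> str:
        """The error-free read sequence for a probe under this layout."""
        lay = self.layout
        pre = (prefix or "A" * lay.trim_prefix_len)[: lay.trim_prefix_len]
        body = pre + lay.flank5 + probe.middle_barcode + lay.flank3 + filler
        return body[: lay.read_len]


@dataclass(frozen=True)
class CellIndexMap:
    """Maps (i5, i7) index-sequence pairs to cell ids."""

    mapping: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        cells = list(self.mapping.values())
        if len(set(cells)) != len(cells):
            raise PanelError("cell ids in index map must be unique")
        for i5, i7 in self.mapping:
            _check_dna(i5, "i5 index")
            _check_dna(i7, "i7 index")

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.mapping.values())

    def lookup(self, i5: str, i7: str) -> str | None:
        return self.mapping.get((i5, i7))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CellIndexMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"i5", "i7", "cell_id"}
        if not required.issubset(df.columns):
            raise PanelError(f"index map needs columns {sorted(required)}")
        return cls({(r.i5, r.i7): r.cell_id for r in df.itertuples()})

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {"i5": i5, "i7": i7, "cell_id": cid}
            for (i5, i7), cid in self.mapping.items()
        ]
        pd.DataFrame(rows, columns=["i5", "i7", "cell_id"]).to_csv(
            path, sep="\t", index=False
        )


def read_panel(
    path: str | Path,
    layout: BarcodeLayout | None = None,
    min_hamming: int = 3,
) -> ProbePanel:
    """Read a probe panel from a tab-separated table.

    The table must have header columns probe_id, protein_name, probe_class,
    middle_barcode, specificity_tag.  The barcode layout is supplied
    separately (companion YAML config or a :class:`BarcodeLayout`); defaults
    are used when omitted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"panel table missing columns {missing}")
    probes = [
        ProbeSpec(
            probe_id=r.probe_id,
            protein_name=r.protein_name,
            probe_class=ProbeClass(r.probe_class),
            middle_barcode=r.middle_barcode,
            specificity_tag=r.specificity_tag,
        )
        for r in df.itertuples()
    ]
    return ProbePanel(tuple(probes), layout=layout or BarcodeLayout(), min_hamming=min_hamming)


def write_panel(panel: ProbePanel, path: str | Path) -> None:
    rows = [
        {
            "probe_id": p.probe_id,
            "protein_name": p.protein_name,
            "probe_class": p.probe_class.value,
            "middle_barcode": p.middle_barcode,
            "specificity_tag": p.specificity_tag,
        }
        for p in panel
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def min_pairwise_hamming(barcodes: Iterable[str]) -> int:
    """Smallest pairwise Hamming distance among a set of barcodes."""
    bcs = list(barcodes)
    if len(bcs) < 2:
        raise ValueError("need at least two barcodes")
    return min(hamming(a, b) for a, b in itertools.combinations(bcs, 2))
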