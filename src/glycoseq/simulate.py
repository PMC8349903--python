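"""Synthetic data with the statistical structure the pipeline assumes.

Two generators are provided:

* read-level — DNA-barcode amplicon reads for a probe panel, with
  per-probe PCR-efficiency bias (deterministic ``(1+e)^cycles`` fold
  factors, mean-normalized) and iid per-base substitution errors, written
  as a paired FASTQ plus truth tables.  Defaults emulate the assay's
  evaluation conditions: a 41-probe panel (39 lectins + 2 IgG controls),
  26 bp reads, 20 PCR cycles, and an efficiency spread calibrated so the
  per-probe fold deviation from the mean percentage stays within two PCR
  cycles (i.e. inside [0.25, 4]).

* matrix-level — paired glycan/RNA matrices for two cell populations
  (a pluripotent-like and a progenitor-like state, 48 cells each by
  default), with a marker probe elevated in population 1, planted
  low-rank gene-lectin association blocks driven by shared latent
  factors, and planted pseudotime-dynamic features (sigmoid or linear
  trends).  RNA counts are negative-binomial around per-cell means.

All outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix
from .panel import (
    BarcodeLayout,
    CellIndexMap,
    PanelError,
    ProbeClass,
    ProbePanel,
    ProbeSpec,
    hamming,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SimulationError(ValueError):
    pass


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


# ---------------------------------------------------------------------------
# panel generation


def generate_panel(
    n_probes: int = 41,
    middle_len: int = 8,
    min_hamming: int = 3,
    seed: int = 0,
    n_controls: int = 2,
    layout: BarcodeLayout | None = None,
    max_tries: int = 200_000,
) -> ProbePanel:
    """Generate a random probe panel satisfying the distance constraint.

    Barcodes are drawn by rejection sampling; a candidate is kept only if
    its Hamming distance to every accepted barcode is >= ``min_hamming``.
    The last ``n_controls`` probes are flagged as IgG controls.
    """
    if min_hamming > middle_len:
        raise SimulationError(
            f"infeasible: min_hamming {min_hamming} exceeds middle length {middle_len}"
        )
    if 4**middle_len < n_probes:
        raise SimulationError(
            f"infeasible: 4^{middle_len} < {n_probes} requested barcodes"
        )
    rng = np.random.default_rng(seed)
    layout = layout or BarcodeLayout(middle_len=middle_len)
    if layout.middle_len != middle_len:
        raise SimulationError("layout.middle_len must equal middle_len")
    accepted: list[str] = []
    for _ in range(max_tries):
        cand = _random_seq(rng, middle_len)
        if all(hamming(cand, b) >= min_hamming for b in accepted):
            accepted.append(cand)
            if len(accepted) == n_probes:
                break
    else:
        raise SimulationError(
            f"infeasible: could not place {n_probes} barcodes at distance "
            f">= {min_hamming} in {max_tries} tries"
        )
    n_lectins = n_probes - n_controls
    probes = [
        ProbeSpec(
            probe_id=f"L{i + 1:02d}",
            protein_name=f"lectin_{i + 1:02d}",
            probe_class=ProbeClass.LECTIN,
            middle_barcode=accepted[i],
            specificity_tag="synthetic",
        )
        for i in range(n_lectins)
    ] + [
        ProbeSpec(
            probe_id=f"IgG{j + 1}",
            protein_name=f"IgG_control_{j + 1}",
            probe_class=ProbeClass.CONTROL,
            middle_barcode=accepted[n_lectins + j],
            specificity_tag="negative control",
        )
        for j in range(n_controls)
    ]
    return ProbePanel(tuple(probes), layout=layout, min_hamming=min_hamming)


def generate_index_map(n_cells: int, seed: int = 0, index_len: int = 8) -> CellIndexMap:
    """Random unique (i5, i7) pairs for ``n_cells`` cells."""
    rng = np.random.default_rng(seed)
    pairs: dict[tuple[str, str], str] = {}
    while len(pairs) < n_cells:
        pair = (_random_seq(rng, index_len), _random_seq(rng, index_len))
        if pair not in pairs:
            pairs[pair] = f"cell{len(pairs) + 1:03d}"
    return CellIndexMap(pairs)


# ---------------------------------------------------------------------------
# read-level simulation


@dataclass
class SimulationTruth:
    """Ground truth for a read-level simulation.

    ``true_profile`` maps population label -> per-probe relative
    abundances (sum 1); ``pcr_efficiency`` holds per-probe efficiencies
    in [0.5, 1] applied over ``pcr_cycles`` cycles and mean-normalized.
    """

    panel: ProbePanel
    index_map: CellIndexMap
    population_of_cell: dict[str, str]
    true_profile: dict[str, np.ndarray]
    pcr_efficiency: np.ndarray
    pcr_cycles: int = 20
    substitution_rate: float = 0.0
    reads_per_cell: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for pop, prof in self.true_profile.items():
            prof = np.asarray(prof, dtype=float)
            if np.any(prof < 0) or not np.isclose(prof.sum(), 1.0):
                raise SimulationError(f"profile for {pop} must be >= 0 and sum to 1")
            self.true_profile[pop] = prof
        self.pcr_efficiency = np.asarray(self.pcr_efficiency, dtype=float)
        if np.any((self.pcr_efficiency < 0.5) | (self.pcr_efficiency > 1.0)):
            raise SimulationError("pcr efficiencies must lie in [0.5, 1]")

    def bias_factors(self) -> np.ndarray:
        """Mean-normalized per-probe amplification factors (1+e)^cycles."""
        b = (1.0 + self.pcr_efficiency) ** self.pcr_cycles
        return b / b.mean()


def equimolar_truth(
    panel: ProbePanel,
    n_cells: int = 4,
    reads_per_cell: int = 20_000,
    substitution_rate: float = 0.0,
    efficiency_low: float = 0.875,
    efficiency_high: float = 1.0,
    uniform_efficiency: bool = False,
    pcr_cycles: int = 20,
    seed: int = 0,
) -> SimulationTruth:
    """Truth for the equimolar-mix evaluation: equal abundance of every
    panel barcode per cell.

    The default efficiency spread U(0.875, 1.0) over 20 cycles keeps
    every probe's fold deviation from the mean percentage within two PCR
    cycles of amplification at the mean efficiency, i.e. inside
    [0.25, 4]; ``uniform_efficiency=True`` switches the bias off.
    """
    rng = np.random.default_rng(seed)
    k = len(panel)
    if uniform_efficiency:
        eff = np.full(k, 0.95)
    else:
        eff = rng.uniform(efficiency_low, efficiency_high, size=k)
    return SimulationTruth(
        panel=panel,
        index_map=generate_index_map(n_cells, seed=seed + 1),
        population_of_cell={f"cell{i + 1:03d}": "mix" for i in range(n_cells)},
        true_profile={"mix": np.full(k, 1.0 / k)},
        pcr_efficiency=eff,
        pcr_cycles=pcr_cycles,
        substitution_rate=substitution_rate,
        reads_per_cell=reads_per_cell,
        seed=seed,
    )


def _apply_substitutions(
    seqs: list[str], rate: float, rng: np.random.Generator
) -> list[str]:
    if rate <= 0 or not seqs:
        return seqs
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).copy()
    L = len(seqs[0])
    hit = rng.random(arr.size) < rate
    if hit.any():
        # substitute with one of the three other bases, uniformly
        idx = np.flatnonzero(hit)
        cur = arr[idx]
        offsets = rng.integers(1, 4, size=idx.size)
        code = np.zeros(arr.max() + 1, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            code[b] = i
        new = _BASES[(code[cur] + offsets) % 4]
        arr[idx] = new
    joined = arr.tobytes().decode()
    return [joined[i * L : (i + 1) * L] for i in range(len(seqs))]


@dataclass
class ReadSimulationResult:
    r1_path: Path
    r2_path: Path
    molecule_counts: CountMatrix
    truth_table_path: Path
    index_map_path: Path
    n_reads: int


def simulate_reads(truth: SimulationTruth, out_dir: str | Path) -> ReadSimulationResult:
    """Write a paired FASTQ for the truth, plus molecule-count and index
    truth tables.

    Per cell, molecule counts are multinomial(reads_per_cell, profile x
    PCR-bias, normalized); each molecule becomes one read (random trimmed
    prefix + flank5 + middle + flank3 + random filler), with iid per-base
    substitutions at ``substitution_rate``.  Read 2 is reverse-complement
    filler; indexes are encoded in the read-1 header as ``i5+i7``.
    Deterministic under the truth's seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    panel, layout = truth.panel, truth.panel.layout
    cells = truth.index_map.cell_ids
    pair_of_cell = {cid: pair for pair, cid in truth.index_map.mapping.items()}
    bias = truth.bias_factors()

    counts = np.zeros((len(cells), len(panel)), dtype=np.int64)
    r1_path, r2_path = out_dir / "reads_R1.fastq", out_dir / "reads_R2.fastq"
    read_no = 0
    filler_len = layout.read_len - layout.min_read_len
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for ci, cell in enumerate(cells):
            profile = truth.true_profile[truth.population_of_cell[cell]]
            probs = profile * bias
            probs = probs / probs.sum()
            mol = rng.multinomial(truth.reads_per_cell, probs)
            counts[ci] = mol
            i5, i7 = pair_of_cell[cell]
            seqs: list[str] = []
            for pi, n_mol in enumerate(mol):
                probe = panel.probes[pi]
                core = layout.flank5 + probe.middle_barcode + layout.flank3
                for _ in range(n_mol):
                    prefix = _random_seq(rng, layout.trim_prefix_len)
                    filler = _random_seq(rng, filler_len)
                    seqs.append(prefix + core + filler)
            seqs = _apply_substitutions(seqs, truth.substitution_rate, rng)
            # shuffle within cell so file order carries no probe signal
            order = rng.permutation(len(seqs))
            for j in order:
                read_no += 1
                seq = seqs[j]
                qual = "I" * len(seq)
                f1.write(f"@r{read_no} {i5}+{i7}\n{seq}\n+\n{qual}\n")
                rc = seq.translate(_COMPLEMENT)[::-1]
                f2.write(f"@r{read_no} {i5}+{i7}\n{rc}\n+\n{qual}\n")

    molecule_counts = CountMatrix(list(cells), panel.probe_ids, counts)
    truth_path = out_dir / "molecule_counts.tsv"
    molecule_counts.to_frame().to_csv(truth_path, sep="\t")
    index_path = out_dir / "index_map.tsv"
    truth.index_map.write_tsv(index_path)
    return ReadSimulationResult(
        r1_path=r1_path,
        r2_path=r2_path,
        molecule_counts=molecule_counts,
        truth_table_path=truth_path,
        index_map_path=index_path,
        n_reads=read_no,
    )


# ---------------------------------------------------------------------------
# matrix-level (multimodal) simulation


@dataclass
class AssociationBlock:
    """A planted gene-lectin association: a shared latent factor loads on
    ``gene_idx`` and ``lectin_idx`` with the given strength (in units of
    the feature noise SD, i.e. the block's SNR)."""

    gene_idx: tuple[int, ...]
    lectin_idx: tuple[int, ...]
    snr: float = 2.0


@dataclass
class DynamicFeature:
    """A planted pseudotime trend on one lectin: ``kind`` is "sigmoid" or
    "linear"; ``amplitude`` is in units of the noise SD; negative
    amplitude gives a decreasing trend."""

    lectin_idx: int
    kind: str = "sigmoid"
    amplitude: float = 2.0


@dataclass
class MultimodalTruth:
    """Ground truth for the paired glycan/RNA simulation."""

    n_cells_per_pop: int = 48
    n_genes: int = 200
    n_lectins: int = 41
    marker_lectin: int = 0  # pluripotency-like probe, high in population 1
    marker_shift: float = 2.0  # log-scale elevation in population 1
    blocks: list[AssociationBlock] = field(
        default_factory=lambda: [AssociationBlock(tuple(range(10)), (2, 3, 4))]
    )
    dynamic_features: list[DynamicFeature] = field(
        default_factory=lambda: [
            DynamicFeature(0, "sigmoid", -2.0),  # marker decreasing along pseudotime
            DynamicFeature(5, "sigmoid", 2.0),
            DynamicFeature(6, "linear", 2.0),
        ]
    )
    glycan_noise_sd: float = 0.35  # log-scale cell-to-cell noise
    rna_noise_sd: float = 0.4
    nb_dispersion: float = 0.2  # negative-binomial overdispersion (1/size)
    glycan_reads_per_cell: int = 10_000
    rna_depth: int = 50_000
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return 2 * self.n_cells_per_pop


@dataclass
class MultimodalData:
    glycan_counts: pd.DataFrame  # cells x lectins, integer
    rna_counts: pd.DataFrame  # genes x cells, integer
    pseudotime: pd.Series  # per cell, in [0, 1]
    labels: pd.Series  # population per cell
    association_truth: pd.DataFrame  # genes x lectins planted pattern
    dynamic_truth: pd.Series  # bool per lectin
    latent_factors: np.ndarray  # cells x blocks


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-10.0 * (t - 0.5)))


def simulate_multimodal(truth: MultimodalTruth) -> MultimodalData:
    """Generate paired glycan/RNA matrices with planted structure.

    Cells come from two populations laid out along a pseudotime in
    [0, 1] (population 1 early, population 2 late).  Log-scale glycan
    signal = probe baseline + marker elevation (population 1) + planted
    dynamic trends + latent-factor block loadings + Gaussian noise;
    counts are multinomial per cell.  RNA log-mean = gene baseline +
    latent-factor block loadings + noise; counts are negative-binomial
    at multinomial-assigned depth.  The planted association pattern is
    the sum of unit-norm outer products a_block b_block', one per block.
    """
    rng = np.random.default_rng(truth.seed)
    n, m, p = truth.n_cells, truth.n_genes, truth.n_lectins
    half = truth.n_cells_per_pop
    cells = [f"cell{i + 1:03d}" for i in range(n)]
    genes = [f"gene{i + 1:04d}" for i in range(m)]
    lectins = [f"L{i + 1:02d}" for i in range(p)]
    labels = pd.Series(
        ["iPSC-like"] * half + ["NPC-like"] * half, index=cells, name="population"
    )
    # pseudotime: population 1 early, population 2 late, slight overlap
    t = np.concatenate(
        [
            np.sort(rng.uniform(0.0, 0.55, size=half)),
            np.sort(rng.uniform(0.45, 1.0, size=half)),
        ]
    )
    pseudotime = pd.Series(t, index=cells, name="pseudotime")

    # latent factors, one per association block, shared by both modalities
    z = rng.standard_normal((n, len(truth.blocks)))

    # glycan log-signal
    glycan_base = rng.normal(0.0, 0.8, size=p)
    log_sig = np.tile(glycan_base, (n, 1))
    log_sig[:half, truth.marker_lectin] += truth.marker_shift
    dyn_flags = np.zeros(p, dtype=bool)
    for dynf in truth.dynamic_features:
        dyn_flags[dynf.lectin_idx] = True
        trend = _sigmoid(t) if dynf.kind == "sigmoid" else t
        # trend in [0, 1]: full swing = amplitude x noise SD on the log scale
        log_sig[:, dynf.lectin_idx] += (
            dynf.amplitude * truth.glycan_noise_sd * (trend - trend.mean())
        )
    assoc = np.zeros((m, p))
    for b, block in enumerate(truth.blocks):
        # every planted feature carries the factor at the block's SNR
        a_ind = np.zeros(m)
        a_ind[list(block.gene_idx)] = 1.0
        b_ind = np.zeros(p)
        b_ind[list(block.lectin_idx)] = 1.0
        assoc += np.outer(a_ind / np.linalg.norm(a_ind), b_ind / np.linalg.norm(b_ind))
        log_sig += np.outer(z[:, b], b_ind) * (block.snr * truth.glycan_noise_sd)
    log_sig += rng.normal(0.0, truth.glycan_noise_sd, size=(n, p))
    probs = np.exp(log_sig)
    probs /= probs.sum(axis=1, keepdims=True)
    glycan_counts = np.vstack(
        [rng.multinomial(truth.glycan_reads_per_cell, probs[i]) for i in range(n)]
    )

    # RNA log-mean
    rna_base = rng.normal(1.0, 1.0, size=m)
    log_mu = np.tile(rna_base, (n, 1))
    for b, block in enumerate(truth.blocks):
        a_ind = np.zeros(m)
        a_ind[list(block.gene_idx)] = 1.0
        log_mu += np.outer(z[:, b], a_ind) * (block.snr * truth.rna_noise_sd)
    log_mu += rng.normal(0.0, truth.rna_noise_sd, size=(n, m))
    rel = np.exp(log_mu)
    rel /= rel.sum(axis=1, keepdims=True)
    mu = rel * truth.rna_depth
    size = 1.0 / truth.nb_dispersion
    rna_counts = rng.negative_binomial(size, size / (size + mu)).T  # genes x cells

    return MultimodalData(
        glycan_counts=pd.DataFrame(glycan_counts, index=cells, columns=lectins),
        rna_counts=pd.DataFrame(rna_counts, index=genes, columns=cells),
        pseudotime=pseudotime,
        labels=labels,
        association_truth=pd.DataFrame(assoc, index=genes, columns=lectins),
        dynamic_truth=pd.Series(dyn_flags, index=lectins, name="dynamic"),
        latent_factors=z,
    )


# ---------------------------------------------------------------------------
# simple Gaussian association benchmark (used for recovery checks)


def simulate_association_gaussian(
    n_cells: int = 96,
    n_genes: int = 50,
    n_lectins: int = 10,
    gene_block: tuple[int, ...] = tuple(range(8)),
    lectin_block: tuple[int, ...] = (0, 1, 2),
    snr: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian planted-association benchmark.

    Every planted feature carries the shared latent factor z at
    signal-to-noise ratio ``snr`` against unit-variance noise:
    X[:, j] = snr * z + E[:, j] for block genes, likewise for block
    lectins.  Returns (X, Y, A_true) with A_true the unit-norm outer
    product of the block indicators."""
    rng = np.random.default_rng(seed)
    a = np.zeros(n_genes)
    a[list(gene_block)] = 1.0
    b = np.zeros(n_lectins)
    b[list(lectin_block)] = 1.0
    z = rng.standard_normal(n_cells)
    X = np.outer(z, a) * snr + rng.standard_normal((n_cells, n_genes))
    Y = np.outer(z, b) * snr + rng.standard_normal((n_cells, n_lectins))
    a_n = a / np.linalg.norm(a)
    b_n = b / np.linalg.norm(b)
    return X, Y, np.outer(a_n, b_n)
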