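"""Synthetic clonal single-cell DNA datasets with full ground truth.

The simulator emulates the inputs of a shallow single-cell DNA-seq study of
a clonally structured tissue: a small multi-contig reference genome, a few
cell clones with known karyotypes (one of them typically near-diploid, the
"chromosomally stable" analog; the others carrying segmental gains/losses),
sparse per-cell genome coverage (defaults 0.5-1% of the genome per cell),
germline SNPs shared by all cells, and clonal somatic SNVs whose
trinucleotide channels are drawn from stated mixtures of signature
probability vectors.

Counts are simulated at the bin level (no reads): each cell's total read
count is lognormal around the configured mean, distributed over bins with
expectation proportional to clone copy number times bin weight, with
negative-binomial noise.  Variant observation in a cell is Bernoulli with
that cell's covered genome fraction.  Everything derives deterministically
from the one seed in :class:`SimConfig`, split into independent substreams
for the reference, the cell table, the counts and the variants, so the
operations can be invoked separately yet stay mutually consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .catalog import SignatureCatalog, proxy_catalog
from .channels import BASES, SBS96_LABELS, revcomp
from .grid import BinGrid
from .io import variant_key

_B2C = {b: i for i, b in enumerate(BASES)}

# RNG substream tags (SeedSequence spawn keys)
_STREAM_REFERENCE = 0
_STREAM_CELLS = 1
_STREAM_COUNTS = 2
_STREAM_VARIANTS = 3


@dataclass
class CloneSpec:
    """A cell clone: karyotype, somatic burden and signature mixture.

    ``karyotype`` is a list of (contig, start, end, copy_number) segments
    that must tile each contig without overlap; copy numbers are integers in
    {0,1,2,3,4}.  ``signature_mixture`` maps signature names (resolved in a
    catalog) to non-negative weights summing to one.  A clone whose segments
    are all copy-number 2 is the chromosomally stable (CS) analog.
    """

    name: str
    karyotype: list[tuple[str, int, int, int]]
    n_somatic: int
    signature_mixture: dict[str, float]

    def validate(self, contig_lengths: dict[str, int]) -> None:
        weights = np.array(list(self.signature_mixture.values()), dtype=float)
        if (weights < 0).any():
            raise ValueError(f"clone {self.name}: negative mixture weight")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"clone {self.name}: mixture weights sum to {weights.sum()}, not 1")
        if self.n_somatic < 0:
            raise ValueError(f"clone {self.name}: negative n_somatic")
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end, cn in self.karyotype:
            if cn not in (0, 1, 2, 3, 4):
                raise ValueError(f"clone {self.name}: copy number {cn} outside 0..4")
            if contig not in contig_lengths:
                raise ValueError(f"clone {self.name}: unknown contig {contig}")
            by_contig.setdefault(contig, []).append((start, end))
        for contig, length in contig_lengths.items():
            segs = sorted(by_contig.get(contig, []))
            if not segs:
                raise ValueError(f"clone {self.name}: contig {contig} not covered by karyotype")
            cursor = 0
            for start, end in segs:
                if start != cursor or end <= start:
                    raise ValueError(
                        f"clone {self.name}: karyotype gap/overlap on {contig} at {start}"
                    )
                cursor = end
            if cursor != length:
                raise ValueError(f"clone {self.name}: karyotype ends at {cursor} != {length} on {contig}")

    def is_diploid(self) -> bool:
        return all(cn == 2 for *_, cn in self.karyotype)


def _default_clones(contig_lengths: dict[str, int]) -> list[CloneSpec]:
    """Default two-clone 'patient': a diploid CS clone with clock-like/flat
    somatic variants and a CIN clone dominated by the SBS17 proxies."""
    names = list(contig_lengths)
    diploid = [(c, 0, contig_lengths[c], 2) for c in names]
    # whole-contig gain, a half-contig loss and a half-contig gain; enough of
    # the genome stays diploid that per-cell medians sit on the diploid state
    cin: list[tuple[str, int, int, int]] = []
    for i, c in enumerate(names):
        length = contig_lengths[c]
        half = length // 2
        if i == 0:
            cin.append((c, 0, length, 3))
        elif i == 1:
            cin.append((c, 0, half, 1))
            cin.append((c, half, length, 2))
        elif i == len(names) - 1 and len(names) >= 3:
            cin.append((c, 0, half, 2))
            cin.append((c, half, length, 4))
        else:
            cin.append((c, 0, length, 2))
    return [
        CloneSpec(
            name="CS",
            karyotype=diploid,
            n_somatic=1000,
            signature_mixture={"clocklike-proxy": 0.7, "flat-proxy": 0.3},
        ),
        CloneSpec(
            name="CIN",
            karyotype=cin,
            n_somatic=2000,
            signature_mixture={
                "SBS17a-proxy": 0.45,
                "SBS17b-proxy": 0.45,
                "flat-proxy": 0.10,
            },
        ),
    ]


@dataclass
class SimConfig:
    """Full parameterization of a synthetic dataset (one 'patient')."""

    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 10_000_000
    bin_size: int = 500_000
    gc_fraction: float = 0.41
    clones: list[CloneSpec] | None = None
    n_cells_per_clone: list[int] = field(default_factory=lambda: [50, 50])
    mean_reads_per_cell: int = 100_000
    coverage_fraction_range: tuple[float, float] = (0.005, 0.01)
    n_germline: int = 500
    overdispersion: float = 10.0
    reads_lognorm_sigma: float = 0.25
    low_mq_fraction: float = 0.05
    mq_high: float = 60.0
    mq_low: float = 10.0

    def __post_init__(self):
        lo, hi = self.coverage_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("coverage_fraction_range must satisfy 0 <= low <= high <= 1")
        if self.bin_size <= 0 or self.contig_length < self.bin_size:
            raise ValueError("need 0 < bin_size <= contig_length")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0,1)")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive (use math.inf for Poisson)")
        if self.clones is None:
            self.clones = _default_clones(self.contig_lengths)
        if len(self.n_cells_per_clone) != len(self.clones):
            raise ValueError("n_cells_per_clone must match clones")
        for clone in self.clones:
            clone.validate(self.contig_lengths)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.contig_length for i in range(self.n_contigs)}

    def grid(self) -> BinGrid:
        return BinGrid.from_contigs(self.contig_lengths, self.bin_size)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class TruthSet:
    """Ground truth of a simulated dataset.

    ``cells``: barcode, clone, total_reads, covered_fraction (one row per
    cell).  ``variants``: one row per emitted variant with its key, clone
    ("germline" variants belong to all clones), SBS channel (somatic only),
    germline flag, MQ and realized number of observing cells.
    """

    cells: pd.DataFrame
    variants: pd.DataFrame | None = None
    clone_karyotypes: dict[str, list] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "cells": self.cells.to_dict(orient="list"),
            "clone_karyotypes": {
                name: [list(seg) for seg in segs] for name, segs in self.clone_karyotypes.items()
            },
        }
        if self.variants is not None:
            out["variants"] = self.variants.to_dict(orient="list")
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSet":
        return cls(
            cells=pd.DataFrame(d["cells"]),
            variants=pd.DataFrame(d["variants"]) if "variants" in d else None,
            clone_karyotypes={k: [tuple(s) for s in v] for k, v in d.get("clone_karyotypes", {}).items()},
        )


# --- reference --------------------------------------------------------------

def make_reference(
    seed: int,
    n_contigs: int,
    contig_length: int,
    gc_fraction: float = 0.41,
) -> dict[str, str]:
    """Generate a random reference genome as {contig: sequence}.

    Base composition follows ``gc_fraction``.  For contigs of at least 10 kb
    the sequence is resampled (bounded retries) until every pyrimidine-
    centered trinucleotide occurs at least once, so any SBS channel has
    placement sites.  Deterministic given the seed.
    """
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0,1)")
    if contig_length < 100:
        raise ValueError("contig_length too small to be useful (<100 bp)")
    rng = np.random.default_rng([int(seed), _STREAM_REFERENCE])
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    reference = {}
    for i in range(n_contigs):
        for _attempt in range(20):
            codes = rng.choice(4, size=contig_length, p=p)
            if contig_length < 10_000 or _all_pyr_trinucs_present(codes):
                break
        else:
            raise RuntimeError("could not realize all pyrimidine-centered trinucleotides")
        reference[f"chr{i + 1}"] = lut[codes].tobytes().decode("ascii")
    return reference


def _all_pyr_trinucs_present(codes: np.ndarray) -> bool:
    tri = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
    central = codes[1:-1]
    pyr = (central == 1) | (central == 3)  # C or T
    return np.unique(tri[pyr]).size == 32


# --- cells & counts ---------------------------------------------------------

def cell_table(config: SimConfig) -> pd.DataFrame:
    """Deterministic per-cell table: barcode, clone, total_reads, covered_fraction.

    Cells are shuffled before barcoding so barcode order carries no clone
    information.
    """
    rng = config.rng(_STREAM_CELLS)
    clones = []
    for clone, n in zip(config.clones, config.n_cells_per_clone):
        clones.extend([clone.name] * n)
    clones = np.array(clones, dtype=object)
    order = rng.permutation(len(clones))
    clones = clones[order]
    width = max(4, len(str(max(len(clones) - 1, 0))))
    barcodes = [f"cell_{i:0{width}d}" for i in range(len(clones))]
    mu = math.log(config.mean_reads_per_cell) - config.reads_lognorm_sigma**2 / 2
    total_reads = np.maximum(
        1, np.round(rng.lognormal(mu, config.reads_lognorm_sigma, size=len(clones)))
    ).astype(int)
    lo, hi = config.coverage_fraction_range
    covered = rng.uniform(lo, hi, size=len(clones)) if hi > lo else np.full(len(clones), lo)
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "clone": clones,
            "total_reads": total_reads,
            "covered_fraction": covered,
        }
    )


def simulate_cells(
    config: SimConfig, grid: BinGrid | None = None
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate the bins x cells read-count matrix.

    Expected counts per bin are proportional to clone copy number times bin
    weight, scaled to the cell's total read count; noise is negative binomial
    with the configured dispersion (``math.inf`` gives Poisson).  Returns the
    count matrix (columns = barcodes, grid row order) and the ground truth.
    """
    grid = grid or config.grid()
    cells = cell_table(config)
    rng = config.rng(_STREAM_COUNTS)
    cn_by_clone = {c.name: grid.copy_number_vector(c.karyotype) for c in config.clones}
    weights = grid.weights
    counts = np.zeros((len(grid), len(cells)), dtype=np.int64)
    for j, row in enumerate(cells.itertuples()):
        expected = cn_by_clone[row.clone] * weights
        total = expected.sum()
        if total <= 0:
            raise ValueError(f"clone {row.clone} has zero expected coverage on the grid")
        expected = expected / total * row.total_reads
        if math.isinf(config.overdispersion):
            counts[:, j] = rng.poisson(expected)
        else:
            r = config.overdispersion
            with np.errstate(divide="ignore", invalid="ignore"):
                pnb = np.where(expected > 0, r / (r + expected), 1.0)
            counts[:, j] = rng.negative_binomial(r, pnb)
    counts_df = pd.DataFrame(counts, columns=cells["barcode"].tolist())
    truth = TruthSet(
        cells=cells,
        clone_karyotypes={c.name: list(map(list, c.karyotype)) for c in config.clones},
    )
    return counts_df, truth


# --- variants ---------------------------------------------------------------

def _context_positions(seq_codes: np.ndarray) -> dict[int, np.ndarray]:
    """Map collapsed pyrimidine-context trinucleotide code -> 0-based positions
    of the central base (first/last positions excluded so flanks exist)."""
    tri = seq_codes[:-2] * 16 + seq_codes[1:-1] * 4 + seq_codes[2:]
    central = seq_codes[1:-1]
    # reverse-complement lookup for 64 trinucleotide codes
    rc = np.empty(64, dtype=np.int64)
    comp = np.array([3, 2, 1, 0])
    for t in range(64):
        a, b, c = t // 16, (t // 4) % 4, t % 4
        rc[t] = comp[c] * 16 + comp[b] * 4 + comp[a]
    collapsed = np.where((central == 1) | (central == 3), tri, rc[tri])
    out: dict[int, np.ndarray] = {}
    order = np.argsort(collapsed, kind="stable")
    sorted_codes = collapsed[order]
    boundaries = np.searchsorted(sorted_codes, np.arange(65))
    for code in np.unique(sorted_codes):
        out[int(code)] = order[boundaries[code] : boundaries[code + 1]] + 1
    return out


def _channel_context_code(label: str) -> tuple[int, str]:
    """(collapsed context trinucleotide code, pyrimidine-strand alt base)."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    code = _B2C[five] * 16 + _B2C[ref] * 4 + _B2C[three]
    return code, alt


def simulate_variants(
    config: SimConfig,
    reference: dict[str, str],
    cells: pd.DataFrame | None = None,
    catalog: SignatureCatalog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Simulate germline and clonal somatic SNVs.

    Somatic variants are drawn channel-first: per clone, a multinomial over
    the 96 channels of its signature mixture, then uniform placement among
    reference sites whose (strand-collapsed) trinucleotide context matches,
    without collisions.  Germline variants are placed uniformly and belong to
    all clones.  A cell observes a variant carried by its clone with
    probability equal to its covered genome fraction.

    Returns ``(variants, presence, truth)``: per-variant metadata (contig,
    1-based pos, ref, alt, mq), the site x cell 0/1 presence matrix indexed
    by variant key, and the ground truth.
    """
    catalog = catalog or proxy_catalog()
    cells = cells if cells is not None else cell_table(config)
    rng = config.rng(_STREAM_VARIANTS)
    contigs = list(reference)
    seq_codes = {
        c: np.frombuffer(
            reference[c].upper().encode("ascii"), dtype=np.uint8
        )
        for c in contigs
    }
    code_lut = np.full(256, -1, dtype=np.int8)
    for base, i in _B2C.items():
        code_lut[ord(base)] = i
    seq_codes = {c: code_lut[v] for c, v in seq_codes.items()}
    ctx_pos = {c: _context_positions(seq_codes[c]) for c in contigs}
    used = {c: np.zeros(len(reference[c]), dtype=bool) for c in contigs}

    records: list[dict] = []

    def _place_channel(label: str, count: int, clone: str) -> None:
        code, alt_pyr = _channel_context_code(label)
        pools = [(c, ctx_pos[c].get(code, np.empty(0, dtype=np.int64))) for c in contigs]
        sizes = np.array([len(p) for _, p in pools])
        if sizes.sum() < count:
            raise ValueError(
                f"clone {clone}: only {sizes.sum()} reference sites match channel "
                f"{label}, need {count}"
            )
        placed = 0
        # sample with rejection against already-used positions
        while placed < count:
            pick = rng.integers(sizes.sum())
            ci = int(np.searchsorted(np.cumsum(sizes), pick, side="right"))
            contig, pool = pools[ci]
            pos0 = int(pool[pick - (np.cumsum(sizes)[ci - 1] if ci else 0)])
            if used[contig][pos0]:
                continue
            used[contig][pos0] = True
            central = "ACGT"[seq_codes[contig][pos0]]
            if central in "CT":
                ref_base, alt_base = central, alt_pyr
            else:
                ref_base, alt_base = central, revcomp(alt_pyr)
            records.append(
                {
                    "contig": contig,
                    "pos": pos0 + 1,
                    "ref": ref_base,
                    "alt": alt_base,
                    "clone": clone,
                    "channel": label,
                    "germline": False,
                }
            )
            placed += 1

    for clone in config.clones:
        mixture = np.zeros(96)
        for name, w in clone.signature_mixture.items():
            if name not in catalog:
                raise KeyError(f"clone {clone.name}: signature {name} not in catalog")
            mixture += w * catalog[name]
        mixture = mixture / mixture.sum()
        channel_counts = rng.multinomial(clone.n_somatic, mixture)
        for ch_idx in np.flatnonzero(channel_counts):
            _place_channel(SBS96_LABELS[ch_idx], int(channel_counts[ch_idx]), clone.name)

    # germline SNPs: uniform over interior positions, any substitution
    placed = 0
    total_interior = sum(len(reference[c]) - 2 for c in contigs)
    if config.n_germline > total_interior:
        raise ValueError("n_germline exceeds available interior positions")
    while placed < config.n_germline:
        contig = contigs[int(rng.integers(len(contigs)))]
        pos0 = int(rng.integers(1, len(reference[contig]) - 1))
        if used[contig][pos0]:
            continue
        central = "ACGT"[seq_codes[contig][pos0]]
        if central not in "ACGT":
            continue
        alt_base = rng.choice([b for b in "ACGT" if b != central])
        used[contig][pos0] = True
        records.append(
            {
                "contig": contig,
                "pos": pos0 + 1,
                "ref": central,
                "alt": str(alt_base),
                "clone": "germline",
                "channel": "",
                "germline": True,
            }
        )
        placed += 1

    variants = pd.DataFrame(records)
    variants["mq"] = np.where(
        rng.uniform(size=len(variants)) < config.low_mq_fraction, config.mq_low, config.mq_high
    )
    variants["key"] = [
        variant_key(r.contig, r.pos, r.ref, r.alt) for r in variants.itertuples()
    ]
    variants = variants.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)

    # observation: Bernoulli(covered fraction) per carrying cell
    barcodes = cells["barcode"].tolist()
    cov = cells["covered_fraction"].to_numpy()
    clone_of_cell = cells["clone"].to_numpy()
    presence = np.zeros((len(variants), len(cells)), dtype=np.int8)
    for i, row in enumerate(variants.itertuples()):
        carrier = np.ones(len(cells), dtype=bool) if row.germline else clone_of_cell == row.clone
        obs = (rng.uniform(size=len(cells)) < cov) & carrier
        presence[i] = obs.astype(np.int8)
    presence_df = pd.DataFrame(presence, index=variants["key"].tolist(), columns=barcodes)
    variants["n_observed"] = presence.sum(axis=1)

    truth = TruthSet(
        cells=cells,
        variants=variants[
            ["key", "contig", "pos", "ref", "alt", "clone", "channel", "germline", "mq", "n_observed"]
        ].copy(),
        clone_karyotypes={c.name: list(map(list, c.karyotype)) for c in config.clones},
    )
    return variants, presence_df, truth


# --- whole-dataset convenience ---------------------------------------------

@dataclass
class SimDataset:
    """An in-memory simulated dataset (see :func:`simulate_dataset`)."""

    config: SimConfig
    reference: dict[str, str]
    grid: BinGrid
    counts: pd.DataFrame
    variants: pd.DataFrame
    presence: pd.DataFrame
    truth: TruthSet


def simulate_dataset(config: SimConfig, catalog: SignatureCatalog | None = None) -> SimDataset:
    """Run the full simulation (reference, counts, variants) for one config."""
    reference = make_reference(
        config.seed, config.n_contigs, config.contig_length, config.gc_fraction
    )
    grid = config.grid()
    counts, truth_cells = simulate_cells(config, grid)
    variants, presence, truth = simulate_variants(config, reference, cells=truth_cells.cells, catalog=catalog)
    return SimDataset(
        config=config,
        reference=reference,
        grid=grid,
        counts=counts,
        variants=variants,
        presence=presence,
        truth=truth,
    )
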