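"""Trinucleotide spectra, baseline subtraction and signature refitting.

This module carries the quantitative core of the analysis: building
96-channel pyrimidine-centered SNV spectra from variant sets on a reference,
normalizing them to a common sequencing effort (100,000 reads per cell and
1% genome coverage), subtracting the chromosomally stable (CS) cluster's
spectrum channel-wise with negatives clipped to zero, computing cosine
similarity against a signature catalog, and refitting spectra as
non-negative combinations of selected signatures (reconstitution).  A
compact INDEL context classifier covers the homopolymer / repeat-stretch
patterns relevant to the ID1/ID2-like events seen in unstable epithelium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .catalog import SignatureCatalog
from .channels import (
    INDEL_INDEX,
    INDEL_LABELS,
    SBS96_LABELS,
    hp_bin,
    rep_bin,
    sbs96_label,
)


def _fetch(reference, contig: str, start0: int, end0: int) -> str:
    """Reference slice [start0, end0), upper-case; works for dicts of strings
    and pyfaidx.Fasta objects."""
    seq = reference[contig]
    return str(seq[start0:end0]).upper()


@dataclass
class TrinucleotideSpectrum:
    """A 96-channel SNV spectrum (counts or normalized counts)."""

    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if (self.values < 0).any():
            raise ValueError("spectrum channels must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(SBS96_LABELS), name=self.meta.get("name"))

    def scale(self) -> str:
        return self.meta.get("scale", "raw")


def classify_snv_context(
    contig: str, pos: int, ref: str, alt: str, reference
) -> int:
    """Channel index (0..95) of an SNV at 1-based ``pos``.

    The reference base at ``pos`` must match ``ref``; purine-reference
    variants are strand-collapsed.  Raises ``ValueError`` on a reference
    mismatch (naming the position) or an ambiguous (N) context base.
    """
    tri = _fetch(reference, contig, pos - 2, pos + 1)
    if len(tri) != 3:
        raise ValueError(f"{contig}:{pos}: flanking bases unavailable")
    if tri[1] != ref.upper():
        raise ValueError(
            f"{contig}:{pos}: reference has {tri[1]!r}, variant claims {ref!r}"
        )
    label = sbs96_label(ref, alt, tri[0], tri[2])
    return SBS96_LABELS.index(label)


def build_spectrum(
    variants: pd.DataFrame, reference, meta: dict | None = None
) -> TrinucleotideSpectrum:
    """Count a variant set (columns contig, pos, ref, alt) into a spectrum.

    Variants with an ambiguous (N) context base are skipped and counted in
    ``meta['n_skipped']``; the channel sum equals the number of classified
    SNVs.
    """
    values = np.zeros(96)
    skipped = 0
    for row in variants.itertuples():
        try:
            values[classify_snv_context(row.contig, int(row.pos), row.ref, row.alt, reference)] += 1
        except ValueError as exc:
            if "ambiguous" in str(exc):
                skipped += 1
                continue
            raise
    out_meta = dict(meta or {})
    out_meta.setdefault("scale", "raw")
    out_meta["n_classified"] = int(values.sum())
    out_meta["n_skipped"] = skipped
    return TrinucleotideSpectrum(values=values, meta=out_meta)


def normalize_spectrum(
    spectrum: TrinucleotideSpectrum,
    reads_per_cell: float,
    covered_fraction: float,
    target_reads: float = 100_000.0,
    target_coverage: float = 0.01,
) -> TrinucleotideSpectrum:
    """Rescale channel counts to a common sequencing effort.

    The counts are multiplied by (target_reads / reads_per_cell) x
    (target_coverage / covered_fraction), i.e. projected onto 100,000 reads
    per cell and 1% genome coverage by default.  Both input means are kept
    in the metadata.
    """
    if reads_per_cell <= 0:
        raise ValueError("reads_per_cell must be positive")
    if not 0 < covered_fraction <= 1:
        raise ValueError("covered_fraction must be in (0, 1]")
    factor = (target_reads / reads_per_cell) * (target_coverage / covered_fraction)
    meta = dict(spectrum.meta)
    meta.update(
        scale="normalized",
        reads_per_cell=float(reads_per_cell),
        covered_fraction=float(covered_fraction),
        norm_factor=float(factor),
    )
    return TrinucleotideSpectrum(values=spectrum.values * factor, meta=meta)


def to_proportions(spectrum: TrinucleotideSpectrum) -> TrinucleotideSpectrum:
    """Rescale a spectrum to sum to one (proportion mode)."""
    total = spectrum.total
    if total <= 0:
        raise ValueError("cannot convert an empty spectrum to proportions")
    meta = dict(spectrum.meta, scale="proportion")
    return TrinucleotideSpectrum(values=spectrum.values / total, meta=meta)


def subtract_baseline(
    spectrum: TrinucleotideSpectrum, baseline: TrinucleotideSpectrum
) -> TrinucleotideSpectrum:
    """Channel-wise ``max(spectrum - baseline, 0)``.

    Both spectra must be on the same normalization scale; a mismatch raises.
    """
    if spectrum.scale() != baseline.scale():
        raise ValueError(
            f"scale mismatch: spectrum is {spectrum.scale()!r}, baseline {baseline.scale()!r}"
        )
    meta = dict(spectrum.meta, baseline_subtracted=True)
    return TrinucleotideSpectrum(
        values=np.clip(spectrum.values - baseline.values, 0.0, None), meta=meta
    )


def pooled_cs_baseline(
    spectra: list[TrinucleotideSpectrum], n_cells: list[int] | None = None
) -> TrinucleotideSpectrum:
    """Cell-count-weighted mean of normalized CS-cluster spectra.

    Pooling across samples smooths the sampling noise of individual CS
    clusters before subtraction.  ``n_cells`` defaults to each spectrum's
    ``meta['n_cells']`` (or 1).
    """
    if not spectra:
        raise ValueError("no CS spectra available for pooling")
    scales = {s.scale() for s in spectra}
    if len(scales) > 1:
        raise ValueError(f"CS spectra on mixed scales: {sorted(scales)}")
    if n_cells is None:
        n_cells = [int(s.meta.get("n_cells", 1)) for s in spectra]
    w = np.asarray(n_cells, dtype=float)
    if (w <= 0).any():
        raise ValueError("cell counts must be positive")
    stacked = np.stack([s.values for s in spectra])
    pooled = (stacked * w[:, None]).sum(axis=0) / w.sum()
    return TrinucleotideSpectrum(
        values=pooled,
        meta={"scale": spectra[0].scale(), "name": "pooled_CS", "n_cells": int(w.sum())},
    )


def cosine_similarity_profile(
    spectrum: TrinucleotideSpectrum, catalog: SignatureCatalog
) -> pd.Series:
    """Cosine similarity of the spectrum to every catalog signature.

    Values lie in [0, 1] for non-negative vectors and are invariant to
    positive scaling of the spectrum.  A zero spectrum raises.
    """
    s = spectrum.values
    norm_s = np.linalg.norm(s)
    if norm_s == 0:
        raise ValueError("cosine similarity undefined for an all-zero spectrum")
    M = catalog.matrix()
    sims = (M.T @ s) / (np.linalg.norm(M, axis=0) * norm_s)
    return pd.Series(sims, index=catalog.names).sort_values(ascending=False)


@dataclass
class RefitResult:
    """Non-negative refit of a spectrum on a signature subset."""

    contributions: dict[str, float]
    reconstructed: TrinucleotideSpectrum
    cosine_to_observed: float
    fraction_explained: float

    def to_dict(self) -> dict:
        return {
            "contributions": self.contributions,
            "cosine_to_observed": self.cosine_to_observed,
            "fraction_explained": self.fraction_explained,
        }


def refit_signatures(
    spectrum: TrinucleotideSpectrum,
    catalog: SignatureCatalog,
    subset: list[str],
) -> RefitResult:
    """Non-negative least-squares refit of a spectrum on selected signatures.

    ``fraction_explained`` = sum(reconstructed)/sum(observed) clipped to
    [0, 1]; the cosine between observed and reconstructed is reported
    alongside.  An all-zero spectrum yields zero contributions and
    fraction_explained 0 by contract.
    """
    if not subset:
        raise ValueError("signature subset must be non-empty")
    M = catalog.matrix(list(subset))
    s = spectrum.values
    total = s.sum()
    if total <= 0:
        zero = TrinucleotideSpectrum(np.zeros(96), meta={"scale": spectrum.scale()})
        return RefitResult(
            contributions={name: 0.0 for name in subset},
            reconstructed=zero,
            cosine_to_observed=0.0,
            fraction_explained=0.0,
        )
    coef, _ = nnls(M, s)
    recon = M @ coef
    norm_r = np.linalg.norm(recon)
    cos = float(recon @ s / (norm_r * np.linalg.norm(s))) if norm_r > 0 else 0.0
    frac = float(np.clip(recon.sum() / total, 0.0, 1.0))
    return RefitResult(
        contributions={name: float(c) for name, c in zip(subset, coef)},
        reconstructed=TrinucleotideSpectrum(recon, meta={"scale": spectrum.scale()}),
        cosine_to_observed=cos,
        fraction_explained=frac,
    )


# --- INDEL context classification ------------------------------------------

@dataclass
class IndelSpectrum:
    """Counts over the compact INDEL context channels."""

    values: np.ndarray = field(default_factory=lambda: np.zeros(len(INDEL_LABELS)))

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(INDEL_LABELS))

    def add(self, label: str) -> None:
        self.values[INDEL_INDEX[label]] += 1


def _run_around(reference, contig: str, left0: int, right0: int, base: str) -> int:
    """Length of the run of ``base`` touching the interval: scans left from
    ``left0`` (inclusive, going 5') and right from ``right0`` (inclusive)."""
    n = 0
    i = left0
    while i >= 0 and _fetch(reference, contig, i, i + 1) == base:
        n += 1
        i -= 1
    j = right0
    length = len(reference[contig])
    while j < length and _fetch(reference, contig, j, j + 1) == base:
        n += 1
        j += 1
    return n


def classify_indel(contig: str, pos: int, ref: str, alt: str, reference) -> str:
    """Classify a VCF-style left-anchored INDEL into an INDEL channel label.

    1-bp insertions/deletions are collapsed to the pyrimidine base (A->T,
    G->C) and binned by the homopolymer run length of the event base
    adjacent to (and, for deletions, including) the event site.  Multi-base
    insertions are checked for a tandem-repeat context: the number of copies
    of the inserted unit immediately 5' of the insertion point sets the
    repeat bin; with no preceding copy they fall into ``other_ins``.
    Multi-base deletions are ``other_del``.  The reference allele must match
    the reference sequence.
    """
    ref, alt = ref.upper(), alt.upper()
    observed = _fetch(reference, contig, pos - 1, pos - 1 + len(ref))
    if observed != ref:
        raise ValueError(f"{contig}:{pos}: reference has {observed!r}, variant claims {ref!r}")
    if len(ref) > 1 and len(alt) == 1:  # deletion
        if ref[0] != alt:
            raise ValueError(f"{contig}:{pos}: non-left-anchored indel {ref}>{alt}")
        deleted = ref[1:]
        if len(deleted) == 1:
            base = deleted
            # run containing the deleted base (0-based position pos-1+1)
            del0 = pos  # 0-based index of deleted base
            run = _run_around(reference, contig, del0 - 1, del0 + 1, base) + 1
            pyr = {"A": "T", "G": "C"}.get(base, base)
            return f"1bp_del_{pyr}_hp{hp_bin(run)}"
        return "other_del"
    if len(alt) > 1 and len(ref) == 1:  # insertion
        if alt[0] != ref:
            raise ValueError(f"{contig}:{pos}: non-left-anchored indel {ref}>{alt}")
        inserted = alt[1:]
        anchor0 = pos - 1  # insertion between anchor0 and anchor0+1
        if len(inserted) == 1:
            base = inserted
            run = _run_around(reference, contig, anchor0, anchor0 + 1, base)
            pyr = {"A": "T", "G": "C"}.get(base, base)
            return f"1bp_ins_{pyr}_hp{hp_bin(max(run, 1))}"
        unit = inserted
        copies = 0
        end = anchor0 + 1
        while end - len(unit) >= 0 and _fetch(reference, contig, end - len(unit), end) == unit:
            copies += 1
            end -= len(unit)
        if copies >= 1:
            return f"ins_rep_{rep_bin(copies)}"
        return "other_ins"
    raise ValueError(f"{contig}:{pos}: {ref}>{alt} is not a simple indel")


def build_indel_spectrum(indels: pd.DataFrame, reference) -> IndelSpectrum:
    """Classify a table of INDELs (contig, pos, ref, alt) into a spectrum."""
    spec = IndelSpectrum()
    for row in indels.itertuples():
        spec.add(classify_indel(row.contig, int(row.pos), row.ref, row.alt, reference))
    return spec


# --- plotting (optional convenience) ----------------------------------------

def plot_spectrum(spectrum: TrinucleotideSpectrum, ax=None, title: str | None = None):
    """Basic 96-channel bar plot, colored by substitution class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    colors = ["#03bcee", "#010101", "#e32926", "#cac9c9", "#a1ce63", "#ebc6c4"]
    bar_colors = [colors[i // 16] for i in range(96)]
    ax.bar(range(96), spectrum.values, color=bar_colors, width=0.8)
    ax.set_xticks(range(0, 96, 16))
    ax.set_xticklabels([s for s in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")])
    ax.set_ylabel("count")
    if title:
        ax.set_title(title)
    return ax


def spectrum_from_series(series: pd.Series, meta: dict | None = None) -> TrinucleotideSpectrum:
    """Build a spectrum from a Series indexed by channel labels."""
    if set(series.index) != set(SBS96_LABELS):
        raise ValueError("series index must be the 96 channel labels")
    return TrinucleotideSpectrum(series.loc[list(SBS96_LABELS)].to_numpy(), meta=dict(meta or {}))
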