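"""Somatic variant filtering and per-cluster Fisher-exact enrichment.

Without a matched germline control, candidate somatic variants from shallow
single-cell data are cleaned by a fixed cascade: drop low-mapping-quality
sites (MQ strictly > threshold; 20 for scDNA, 60 for bulk WGS where a VAF
> 0.3 filter also applies), remove exact matches against a germline
blacklist (dbSNP-style), remove variant keys observed in every patient,
remove anything supported by at least one cell of the chromosomally stable
cluster, and finally test each remaining variant for enrichment in each
cell cluster with a one-sided Fisher exact test.

Each step returns a new :class:`VariantMatrix` with an appended history
entry, so attrition through the cascade is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cnv import ClusterAssignment
from .io import split_key, write_vcf


@dataclass
class VariantMatrix:
    """Site x cell presence matrix with per-variant metadata.

    ``presence``: 0/1 DataFrame indexed by variant key (``contig:pos:ref:alt``)
    with one column per cell barcode.  ``meta``: per-variant contig, pos,
    ref, alt, mq (and optionally vaf), same index.  ``history`` is an
    append-only list of (step, n_before, n_after).
    """

    presence: pd.DataFrame
    meta: pd.DataFrame
    history: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.presence.index.equals(self.meta.index):
            self.meta = self.meta.loc[self.presence.index]
        if self.presence.index.has_duplicates:
            dup = self.presence.index[self.presence.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate variant keys: {dup}")

    def __len__(self) -> int:
        return len(self.presence)

    @property
    def barcodes(self) -> list[str]:
        return list(self.presence.columns)

    @classmethod
    def from_frames(cls, variants: pd.DataFrame, presence: pd.DataFrame) -> "VariantMatrix":
        """Build from a variant table (with or without a 'key' column) and a
        presence matrix keyed by variant."""
        meta = variants.copy()
        if "key" not in meta.columns:
            meta["key"] = [
                f"{r.contig}:{int(r.pos)}:{r.ref}:{r.alt}" for r in meta.itertuples()
            ]
        meta = meta.set_index("key")
        keep = [c for c in ("contig", "pos", "ref", "alt", "mq", "vaf") if c in meta.columns]
        meta = meta[keep]
        missing = presence.index.difference(meta.index)
        if len(missing):
            raise ValueError(f"presence rows without metadata: {missing[:3].tolist()}")
        meta = meta.loc[presence.index]
        return cls(presence=presence.astype(np.int8), meta=meta)

    def _step(self, name: str, keep: pd.Index) -> "VariantMatrix":
        out = VariantMatrix(
            presence=self.presence.loc[keep],
            meta=self.meta.loc[keep],
            history=self.history + [(name, len(self), len(keep))],
        )
        return out

    def support_counts(self, barcodes: list[str] | None = None) -> pd.Series:
        cols = barcodes if barcodes is not None else self.presence.columns
        return self.presence[list(cols)].sum(axis=1)


def filter_mq(matrix: VariantMatrix, threshold: float = 20.0) -> VariantMatrix:
    """Keep variants with MQ strictly greater than ``threshold``.

    Variants with missing MQ are treated as unqualifiable and dropped, with
    a warning carrying the count.
    """
    if threshold < 0:
        raise ValueError("MQ threshold must be >= 0")
    mq = pd.to_numeric(matrix.meta.get("mq"), errors="coerce")
    missing = mq.isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} variant(s) with missing MQ", stacklevel=2)
    keep = matrix.meta.index[(~missing) & (mq > threshold)]
    return matrix._step(f"mq>{threshold:g}", keep)


def filter_vaf(matrix: VariantMatrix, threshold: float = 0.3) -> VariantMatrix:
    """Keep variants with VAF strictly greater than ``threshold`` (WGS mode)."""
    if "vaf" not in matrix.meta.columns or matrix.meta["vaf"].isna().all():
        raise ValueError(
            "VAF filtering requires per-variant allele fractions (bulk WGS mode); "
            "single-cell presence matrices carry no VAF"
        )
    vaf = pd.to_numeric(matrix.meta["vaf"], errors="coerce")
    keep = matrix.meta.index[vaf > threshold]
    return matrix._step(f"vaf>{threshold:g}", keep)


def remove_blacklisted(matrix: VariantMatrix, blacklist: set[str]) -> VariantMatrix:
    """Remove exact-key (contig,pos,ref,alt) matches against the blacklist.

    A blacklist entry at the same position with a different alternate allele
    does not remove the variant.
    """
    keep = matrix.meta.index[~matrix.meta.index.isin(blacklist)]
    return matrix._step("blacklist", keep)


def remove_ubiquitous(matrices: dict[str, VariantMatrix]) -> dict[str, VariantMatrix]:
    """Remove variant keys observed (>= 1 supporting cell) in every patient.

    With a single patient this is the identity, with a warning.  Keys seen in
    a strict subset of patients are retained everywhere.
    """
    if len(matrices) < 2:
        warnings.warn("only one patient: shared-variant filter is a no-op", stacklevel=2)
        return {
            p: m._step("ubiquitous", m.meta.index) for p, m in matrices.items()
        }
    observed = []
    for m in matrices.values():
        support = m.support_counts()
        observed.append(set(support.index[support > 0]))
    shared = set.intersection(*observed)
    return {
        p: m._step("ubiquitous", m.meta.index[~m.meta.index.isin(shared)])
        for p, m in matrices.items()
    }


def remove_cs_supported(matrix: VariantMatrix, assignment: ClusterAssignment) -> VariantMatrix:
    """Remove variants supported by >= 1 cell of the CS cluster.

    Variants with zero supporting cells anywhere are also dropped (they are
    unobserved).  Raises if no CS cluster is flagged.
    """
    if assignment.cs_cluster is None:
        raise ValueError("no chromosomally stable cluster flagged; cannot apply CS filter")
    cs_cells = [c for c in assignment.cells_of(assignment.cs_cluster) if c in matrix.presence.columns]
    cs_support = matrix.support_counts(cs_cells)
    any_support = matrix.support_counts()
    keep = matrix.meta.index[(cs_support == 0) & (any_support > 0)]
    return matrix._step("cs_overlap", keep)


# --- Fisher enrichment ------------------------------------------------------

def fisher_one_sided_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the table [[a, b], [c, d]].

    a = cells in cluster with the variant, b = in cluster without,
    c = outside with, d = outside without.  Equals the upper hypergeometric
    tail P(X >= a) with population a+b+c+d, successes a+c, draws a+b.
    """
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


@dataclass
class EnrichmentResult:
    """Per (variant, cluster) Fisher tables, p-values and enrichment flags."""

    table: pd.DataFrame  # variant, cluster, a, b, c, d, p, (q), enriched
    p_threshold: float

    def enriched_keys(self, cluster: str) -> list[str]:
        sub = self.table[(self.table["cluster"] == cluster) & self.table["enriched"]]
        return sub["variant"].tolist()


def fisher_cluster_enrichment(
    matrix: VariantMatrix,
    assignment: ClusterAssignment,
    p_threshold: float = 0.05,
    alternative: str = "greater",
    bh: bool = False,
) -> EnrichmentResult:
    """Test each variant for enrichment in each cluster.

    For every (variant, cluster) the 2x2 table [cells in cluster with /
    without, cells outside with / without] is evaluated with a one-sided
    Fisher exact test by default (``alternative="two-sided"`` doubles-tails
    via scipy).  A variant is enriched in a cluster iff p < ``p_threshold``
    (or BH-adjusted q < threshold when ``bh=True``).
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0,1)")
    clusters = assignment.clusters
    if len(clusters) < 2:
        raise ValueError("need at least two clusters for enrichment")
    sizes = assignment.sizes()
    if (sizes == 0).any():
        raise ValueError("empty cluster in assignment")
    barcodes = [b for b in matrix.barcodes if b in assignment.labels.index]
    if len(barcodes) < len(matrix.barcodes):
        warnings.warn(
            f"{len(matrix.barcodes) - len(barcodes)} cell(s) without cluster label ignored",
            stacklevel=2,
        )
    pres = matrix.presence[barcodes].to_numpy()
    labels = assignment.labels.loc[barcodes].to_numpy()
    total_with = pres.sum(axis=1)
    n_cells = len(barcodes)
    frames = []
    for cluster in clusters:
        in_mask = labels == cluster
        n_in = int(in_mask.sum())
        a = pres[:, in_mask].sum(axis=1)
        b = n_in - a
        c = total_with - a
        d = n_cells - n_in - c
        if alternative == "greater":
            p = hypergeom.sf(a - 1, n_cells, total_with, n_in)
        elif alternative == "two-sided":
            from scipy.stats import fisher_exact

            p = np.array(
                [fisher_exact([[ai, bi], [ci, di]], alternative="two-sided")[1]
                 for ai, bi, ci, di in zip(a, b, c, d)]
            )
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        frames.append(
            pd.DataFrame(
                {
                    "variant": matrix.meta.index,
                    "cluster": cluster,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "p": np.clip(p, 0.0, 1.0),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["variant", "cluster", "a", "b", "c", "d", "p"]
    )
    if bh and len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["enriched"] = table["q"] < p_threshold
    else:
        table["enriched"] = table["p"] < p_threshold
    return EnrichmentResult(table=table, p_threshold=p_threshold)


def export_enriched_vcf(
    result: EnrichmentResult,
    matrix: VariantMatrix,
    cluster: str,
    path,
    contig_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Write the cluster's significantly enriched variants to a minimal VCF.

    INFO fields: MQ, CLUSTER, FISHER_P, CELLS_IN (supporting cells in the
    cluster), CELLS_OUT.  Records are sorted by contig then position.
    Returns the exported variant table.
    """
    sub = result.table[(result.table["cluster"] == cluster) & result.table["enriched"]]
    rows = []
    for r in sub.itertuples():
        contig, pos, ref, alt = split_key(r.variant)
        rows.append(
            {
                "contig": contig,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "mq": float(matrix.meta.loc[r.variant, "mq"]),
                "cluster": cluster,
                "fisher_p": float(r.p),
                "cells_in": int(r.a),
                "cells_out": int(r.c),
            }
        )
    df = pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "mq", "cluster", "fisher_p", "cells_in", "cells_out"]
    )
    extra = [
        '##INFO=<ID=CLUSTER,Number=1,Type=String,Description="Enriched cell cluster">',
        '##INFO=<ID=FISHER_P,Number=1,Type=Float,Description="One-sided Fisher exact p-value">',
        '##INFO=<ID=CELLS_IN,Number=1,Type=Integer,Description="Supporting cells inside the cluster">',
        '##INFO=<ID=CELLS_OUT,Number=1,Type=Integer,Description="Supporting cells outside the cluster">',
    ]
    write_vcf(
        df,
        path,
        contig_lengths=contig_lengths,
        extra_info=extra,
        info_cols={
            "cluster": "CLUSTER",
            "fisher_p": "FISHER_P",
            "cells_in": "CELLS_IN",
            "cells_out": "CELLS_OUT",
        },
    )
    return df
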