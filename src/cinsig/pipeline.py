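"""End-to-end pipeline orchestration.

Stage order mirrors the analysis workflow: normalize binned counts to
copy-number profiles, cluster cells (k chosen by the user per sample),
segment each cluster's mean profile by CBS, flag the chromosomally stable
(CS) cluster, derive CIN regions; then run the variant-filter cascade
(MQ > threshold, germline blacklist, cross-patient shared variants, CS
overlap) and per-cluster Fisher enrichment; finally build per-cluster
trinucleotide spectra, normalize them to 100,000 reads per cell and 1%
coverage, subtract the CS baseline (negatives clipped at zero) and refit
against the signature catalog.

All stage outputs are plain text (TSV/BED/VCF/JSON) under one output
directory; re-running with the same config and seed reproduces them
byte-identically.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cnv, io, sigcore, varfilter
from .catalog import load_catalog
from .grid import BinGrid
from .simdata import SimConfig, simulate_dataset

log = logging.getLogger("cinsig")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run (one sample/patient)."""

    outdir: str
    reference: str
    counts: str
    cells: str
    variants_vcf: str
    presence: str
    blacklist: str
    catalog: str = "bundled-proxy"
    k: int = 2
    cn_delta: float = 0.5
    cs_max_aberrant: float = 0.05
    mq_min: float = 20.0
    p_threshold: float = 0.05
    cbs_alpha: float = 0.01
    cbs_permutations: int = 1000
    cbs_min_width: int = 2
    subset: list[str] = field(default_factory=lambda: ["SBS17a-proxy", "SBS17b-proxy"])
    baseline: str = "per-sample"  # per-sample | pooled | none
    spectra_from: str = "supported"  # supported | enriched
    proportions: bool = False
    one_sided: bool = True
    bh: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("reference", "counts", "cells", "variants_vcf", "presence", "blacklist"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} path does not exist: {path}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0,1)")
        if self.baseline not in ("per-sample", "pooled", "none"):
            raise ValueError(f"unknown baseline mode {self.baseline!r}")
        if self.spectra_from not in ("supported", "enriched"):
            raise ValueError(f"unknown spectra_from mode {self.spectra_from!r}")
        if str(self.catalog) != "bundled-proxy" and not Path(self.catalog).exists():
            raise FileNotFoundError(f"catalog path does not exist: {self.catalog}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    @classmethod
    def for_dataset(cls, datadir: str | Path, outdir: str | Path, **overrides) -> "RunConfig":
        """Point a config at the files written by :func:`run_simulate`."""
        d = Path(datadir)
        return cls(
            outdir=str(outdir),
            reference=str(d / "reference.fa"),
            counts=str(d / "counts.tsv"),
            cells=str(d / "cells.tsv"),
            variants_vcf=str(d / "variants.vcf"),
            presence=str(d / "presence.tsv"),
            blacklist=str(d / "blacklist.tsv"),
            **overrides,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --- simulate ----------------------------------------------------------------

def run_simulate(config: SimConfig, outdir: str | Path) -> dict:
    """Simulate a dataset and write it to ``outdir``.

    Files: reference.fa, counts.tsv (bins x cells with contig/start/end
    columns), cells.tsv (QC: total reads and covered fraction per cell),
    variants.vcf, presence.tsv, blacklist.tsv (germline keys, the dbSNP
    analog) and truth.json.  Deterministic per seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    io.write_fasta(ds.reference, outdir / "reference.fa")
    io.write_bin_counts(ds.counts, ds.grid, outdir / "counts.tsv")
    ds.truth.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    io.write_vcf(
        ds.variants,
        outdir / "variants.vcf",
        contig_lengths={c: len(s) for c, s in ds.reference.items()},
    )
    io.write_presence(ds.presence, outdir / "presence.tsv")
    io.write_blacklist(ds.variants[ds.variants["germline"]], outdir / "blacklist.tsv")
    io.write_json(ds.truth.to_dict(), outdir / "truth.json")
    summary = {
        "n_cells": len(ds.truth.cells),
        "n_variants": len(ds.variants),
        "n_germline": int(ds.variants["germline"].sum()),
        "n_somatic": int((~ds.variants["germline"]).sum()),
        "outdir": str(outdir),
    }
    io.write_json(summary, outdir / "simulate_summary.json")
    return summary


# --- pipeline stages ---------------------------------------------------------

def stage_cnv(config: RunConfig):
    """Normalize, cluster, segment and label the CS cluster; write outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, grid_df = io.read_bin_counts(config.counts)
    grid = BinGrid(grid_df)
    profiles = cnv.normalize_counts(counts, grid)
    out = pd.concat([grid.df[["contig", "start", "end"]], profiles], axis=1)
    out.to_csv(outdir / "cn_matrix.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    assignment = cnv.cluster_cells(profiles, config.k)
    suggestion = _silhouette_suggestion(profiles)
    if suggestion is not None:
        log.info("silhouette-score suggestion for k: %d (user k=%d, kept)", suggestion, config.k)

    mean_profiles = pd.DataFrame(
        {
            cluster: profiles[assignment.cells_of(cluster)].mean(axis=1)
            for cluster in assignment.clusters
        }
    )
    segments = cnv.cbs_segment(
        mean_profiles,
        grid,
        alpha=config.cbs_alpha,
        n_perm=config.cbs_permutations,
        min_width=config.cbs_min_width,
        seed=config.seed,
    )
    assignment = cnv.label_cs_cluster(
        segments, assignment, grid, cn_delta=config.cn_delta, cs_max_aberrant=config.cs_max_aberrant
    )
    regions = cnv.call_cin_regions(segments, cn_delta=config.cn_delta)

    assignment.to_frame().to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    seg_df = segments.to_frame()
    for cluster in assignment.clusters:
        sub = seg_df[seg_df["cluster"] == cluster].rename(columns={"cluster": "name", "mean_cn": "score"})
        io.write_bed(sub, outdir / f"segments_{cluster}.bed")
    reg_df = regions.to_frame()
    for cluster in assignment.clusters:
        sub = reg_df[reg_df["cluster"] == cluster].rename(columns={"direction": "name"})
        io.write_bed(sub[["contig", "start", "end", "name"]], outdir / f"cin_regions_{cluster}.bed")
    seg_df.to_csv(outdir / "segments.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    reg_df.to_csv(outdir / "cin_regions.tsv", sep="\t", index=False)
    return grid, profiles, assignment, segments, regions, suggestion


def _silhouette_suggestion(profiles: pd.DataFrame, k_max: int = 8) -> int | None:
    from scipy.cluster.hierarchy import fcluster, linkage
    from sklearn.metrics import silhouette_score

    X = profiles[sorted(profiles.columns)].to_numpy(dtype=float).T
    n = X.shape[0]
    if n < 3 or np.allclose(X.std(axis=0), 0):
        return None
    Z = linkage(X, method="ward")
    best_k, best_s = None, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def stage_filter(config: RunConfig, assignment: cnv.ClusterAssignment):
    """Run the variant-filter cascade and Fisher enrichment; write outputs.

    Returns (matrix_pre_cs, matrix_post_cs, enrichment).  The pre-CS matrix
    is kept because the CS cluster's own baseline spectrum must be built
    before the CS-overlap filter removes every CS-supported variant.
    """
    outdir = Path(config.outdir)
    variants = io.read_vcf(config.variants_vcf)
    presence = io.read_presence(config.presence)
    matrix = varfilter.VariantMatrix.from_frames(variants, presence)
    matrix = varfilter.filter_mq(matrix, config.mq_min)
    blacklist = io.read_blacklist(config.blacklist)
    matrix = varfilter.remove_blacklisted(matrix, blacklist)
    matrix = varfilter.remove_ubiquitous({"sample": matrix})["sample"]
    matrix_pre_cs = matrix
    matrix_post_cs = varfilter.remove_cs_supported(matrix, assignment)
    enrichment = varfilter.fisher_cluster_enrichment(
        matrix_post_cs,
        assignment,
        p_threshold=config.p_threshold,
        alternative="greater" if config.one_sided else "two-sided",
        bh=config.bh,
    )
    io.write_presence(matrix_post_cs.presence, outdir / "filtered_presence.tsv")
    enrichment.table.to_csv(outdir / "fisher.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    contig_lengths = None
    for cluster in assignment.clusters:
        varfilter.export_enriched_vcf(
            enrichment, matrix_post_cs, cluster, outdir / f"enriched_{cluster}.vcf", contig_lengths
        )
    return matrix_pre_cs, matrix_post_cs, enrichment


def _cluster_variant_table(matrix: varfilter.VariantMatrix, cells: list[str]) -> pd.DataFrame:
    support = matrix.support_counts(cells)
    keys = support.index[support > 0]
    meta = matrix.meta.loc[keys]
    return meta.reset_index().rename(columns={"key": "variant", "index": "variant"})


def stage_spectra(
    config: RunConfig,
    assignment: cnv.ClusterAssignment,
    matrix_pre_cs: varfilter.VariantMatrix,
    matrix_post_cs: varfilter.VariantMatrix,
    enrichment: varfilter.EnrichmentResult,
):
    """Build, normalize, baseline-subtract and refit per-cluster spectra."""
    outdir = Path(config.outdir)
    import pyfaidx

    reference = pyfaidx.Fasta(config.reference, sequence_always_upper=True)
    catalog = load_catalog(config.catalog)
    cells_df = pd.read_csv(config.cells, sep="\t").set_index("barcode")

    def cluster_means(cluster: str) -> tuple[float, float, int]:
        cells = [c for c in assignment.cells_of(cluster) if c in cells_df.index]
        sub = cells_df.loc[cells]
        return float(sub["total_reads"].mean()), float(sub["covered_fraction"].mean()), len(cells)

    spectra_norm: dict[str, sigcore.TrinucleotideSpectrum] = {}
    cs = assignment.cs_cluster
    for cluster in assignment.clusters:
        if cluster == cs:
            source = matrix_pre_cs
            table = _cluster_variant_table(source, assignment.cells_of(cluster))
        elif config.spectra_from == "enriched":
            keys = enrichment.enriched_keys(cluster)
            meta = matrix_post_cs.meta.loc[matrix_post_cs.meta.index.intersection(keys)]
            table = meta.reset_index()
        else:
            table = _cluster_variant_table(matrix_post_cs, assignment.cells_of(cluster))
        reads, cov, n_cells = cluster_means(cluster)
        spec = sigcore.build_spectrum(
            table, reference, meta={"name": cluster, "n_cells": n_cells}
        )
        spec = sigcore.normalize_spectrum(spec, reads, cov)
        if config.proportions and spec.total > 0:
            spec = sigcore.to_proportions(spec)
        spectra_norm[cluster] = spec

    baseline = None
    if config.baseline != "none" and cs is not None:
        if config.baseline == "per-sample":
            baseline = spectra_norm[cs]
        else:  # pooled (single sample degenerates to its own CS spectrum)
            baseline = sigcore.pooled_cs_baseline([spectra_norm[cs]])
            baseline.meta["scale"] = spectra_norm[cs].scale()

    spectra_sub: dict[str, sigcore.TrinucleotideSpectrum] = {}
    for cluster, spec in spectra_norm.items():
        spectra_sub[cluster] = (
            sigcore.subtract_baseline(spec, baseline) if baseline is not None else spec
        )

    refits = {}
    cosines_raw, cosines_sub = {}, {}
    for cluster in assignment.clusters:
        raw = sigcore.refit_signatures(spectra_norm[cluster], catalog, config.subset)
        sub = sigcore.refit_signatures(spectra_sub[cluster], catalog, config.subset)
        refits[cluster] = {
            "raw": raw.to_dict(),
            "subtracted": sub.to_dict(),
            "n_variants": int(round(spectra_norm[cluster].meta.get("n_classified", 0))),
        }
        if spectra_norm[cluster].total > 0:
            cosines_raw[cluster] = sigcore.cosine_similarity_profile(spectra_norm[cluster], catalog)
        if spectra_sub[cluster].total > 0:
            cosines_sub[cluster] = sigcore.cosine_similarity_profile(spectra_sub[cluster], catalog)

    def _write_spectra(spectra: dict, path: Path):
        df = pd.DataFrame({cl: s.as_series() for cl, s in spectra.items()})
        df.index.name = "channel"
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)

    _write_spectra(spectra_norm, outdir / "spectra_normalized.tsv")
    _write_spectra(spectra_sub, outdir / "spectra_subtracted.tsv")
    for name, cosines in (("cosine_raw", cosines_raw), ("cosine_subtracted", cosines_sub)):
        if cosines:
            df = pd.DataFrame(cosines).sort_index()
            df.index.name = "signature"
            df.to_csv(outdir / f"{name}.tsv", sep="\t", float_format=_FLOAT_FMT)
    io.write_json(refits, outdir / "refit.json")
    return spectra_norm, spectra_sub, refits, cosines_raw, cosines_sub


# --- run & report ------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the run report (JSON + Markdown)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    grid, profiles, assignment, segments, regions, k_suggestion = stage_cnv(config)
    matrix_pre_cs, matrix_post_cs, enrichment = stage_filter(config, assignment)
    spectra_norm, spectra_sub, refits, cosines_raw, cosines_sub = stage_spectra(
        config, assignment, matrix_pre_cs, matrix_post_cs, enrichment
    )

    enriched_any = (
        enrichment.table[enrichment.table["enriched"]]["variant"].nunique()
        if len(enrichment.table)
        else 0
    )
    attrition = [
        {"step": step, "before": before, "after": after}
        for step, before, after in matrix_post_cs.history
    ] + [{"step": "fisher_enriched", "before": len(matrix_post_cs), "after": int(enriched_any)}]

    sizes = assignment.sizes()
    cluster_info = {}
    for cluster in assignment.clusters:
        cluster_info[cluster] = {
            "n_cells": int(sizes[cluster]),
            "is_cs": cluster == assignment.cs_cluster,
            "aberrant_fraction": cnv.aberrant_fraction(
                segments.segments[cluster], grid, config.cn_delta
            ),
            "n_cin_regions": len(regions.regions.get(cluster, [])),
            "top_cosine_raw": (
                cosines_raw[cluster].head(3).round(6).to_dict() if cluster in cosines_raw else {}
            ),
            "top_cosine_subtracted": (
                cosines_sub[cluster].head(3).round(6).to_dict() if cluster in cosines_sub else {}
            ),
            "refit": refits[cluster],
        }

    report = {
        "version": __version__,
        "config": config.to_dict(),
        "k_silhouette_suggestion": k_suggestion,
        "cs_cluster": assignment.cs_cluster,
        "attrition": attrition,
        "clusters": cluster_info,
    }
    io.write_json(report, outdir / "report.json")
    (outdir / "report.md").write_text(render_markdown(report))
    return report


def render_markdown(report: dict) -> str:
    lines = [
        "# cinsig run report",
        "",
        f"- version: {report['version']}",
        f"- seed: {report['config']['seed']}",
        f"- k: {report['config']['k']} (silhouette suggestion: {report['k_silhouette_suggestion']})",
        f"- CS cluster: {report['cs_cluster']}",
        "",
        "## Filter attrition",
        "",
        "| step | before | after |",
        "|---|---|---|",
    ]
    for row in report["attrition"]:
        lines.append(f"| {row['step']} | {row['before']} | {row['after']} |")
    lines += ["", "## Clusters", ""]
    for cluster, info in report["clusters"].items():
        subset = ", ".join(report["config"]["subset"])
        lines += [
            f"### {cluster}{' (CS)' if info['is_cs'] else ''}",
            "",
            f"- cells: {info['n_cells']}",
            f"- aberrant genome fraction: {info['aberrant_fraction']:.4f}",
            f"- CIN regions: {info['n_cin_regions']}",
            f"- variants in spectrum: {info['refit']['n_variants']}",
            f"- fraction explained by {{{subset}}}: "
            f"raw {info['refit']['raw']['fraction_explained']:.4f}, "
            f"baseline-subtracted {info['refit']['subtracted']['fraction_explained']:.4f}",
            "",
        ]
    return "\n".join(lines)


def render_report(outdir: str | Path) -> str:
    """Re-render report.md from persisted stage outputs without recomputation.

    Validates the persisted spectra (negative channel values are rejected)
    and fails with the missing file's name if a stage output is absent.
    """
    outdir = Path(outdir)
    report_path = outdir / "report.json"
    if not report_path.exists():
        raise FileNotFoundError(f"missing stage output: {report_path}")
    for name in ("spectra_normalized.tsv", "spectra_subtracted.tsv", "refit.json", "clusters.tsv"):
        path = outdir / name
        if not path.exists():
            raise FileNotFoundError(f"missing stage output: {path}")
    for name in ("spectra_normalized.tsv", "spectra_subtracted.tsv"):
        df = pd.read_csv(outdir / name, sep="\t", index_col=0)
        if (df.to_numpy(dtype=float) < 0).any():
            raise ValueError(f"{name}: negative spectrum values (corrupted stage output)")
    report = io.read_json(report_path)
    md = render_markdown(report)
    (outdir / "report.md").write_text(md)
    return md
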