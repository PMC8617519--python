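"""Copy-number analysis of binned single-cell counts.

The stages mirror a standard shallow scDNA-seq workflow: per-cell counts are
median-normalized to copy-number profiles (each cell's median is set to 2,
i.e. cells are assumed mostly diploid), cells are grouped by Ward
hierarchical clustering with a user-chosen number of clusters, each
cluster's mean profile is segmented by circular binary segmentation (CBS),
the cluster with (hardly) no aberrations is flagged as chromosomally stable
(CS), and segments deviating from the diploid state by more than half a copy
are reported as CIN regions (gains/losses).

Circular binary segmentation here follows the classic recursive scheme: on
each contig the arc (i, j] maximizing the absolute two-sample mean-shift
statistic

    T(i, j) = |mean(x[i:j]) - mean(x outside)| / sqrt(1/n_in + 1/n_out)

is found exhaustively; the split is accepted when its permutation p-value
(max statistic over shuffled bins) is below ``alpha``, and both sides are
segmented recursively.  The overall scale of the statistic cancels in the
permutation ranking, so no variance estimate is needed.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .grid import BinGrid


class ZeroMedianError(ValueError):
    """Raised when a cell's median (weight-adjusted) count is zero."""

    def __init__(self, barcodes: list[str]):
        self.barcodes = list(barcodes)
        super().__init__(
            f"zero median count for {len(self.barcodes)} cell(s): "
            f"{', '.join(self.barcodes[:5])}{'...' if len(self.barcodes) > 5 else ''}"
        )


def normalize_counts(counts: pd.DataFrame, grid: BinGrid) -> pd.DataFrame:
    """Median-normalize counts to copy-number profiles.

    Counts are first divided by bin weight, then each cell by its median and
    multiplied by 2, so every profile has median exactly 2.  Cells with a
    zero median are rejected with :class:`ZeroMedianError` naming them.
    Returns a bins x cells DataFrame aligned to the grid.
    """
    adjusted = counts.to_numpy(dtype=float) / grid.weights[:, None]
    medians = np.median(adjusted, axis=0)
    bad = medians == 0
    if bad.any():
        raise ZeroMedianError([c for c, b in zip(counts.columns, bad) if b])
    profiles = adjusted / medians[None, :] * 2.0
    return pd.DataFrame(profiles, columns=counts.columns, index=counts.index)


@dataclass
class ClusterAssignment:
    """Cell -> cluster labels plus the CS (chromosomally stable) flag."""

    labels: pd.Series  # index barcode, value cluster label
    cs_cluster: str | None = None

    @property
    def clusters(self) -> list[str]:
        return sorted(self.labels.unique())

    def cells_of(self, cluster: str) -> list[str]:
        return self.labels.index[self.labels == cluster].tolist()

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"barcode": self.labels.index, "cluster": self.labels.values})
        df["is_cs"] = (df["cluster"] == self.cs_cluster).astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClusterAssignment":
        labels = pd.Series(df["cluster"].to_numpy(), index=df["barcode"].to_numpy())
        cs = df.loc[df.get("is_cs", 0) == 1, "cluster"]
        return cls(labels=labels, cs_cluster=cs.iloc[0] if len(cs) else None)


def cluster_cells(profiles: pd.DataFrame, k: int) -> ClusterAssignment:
    """Ward hierarchical clustering of copy-number profiles, cut at ``k``.

    ``profiles`` is bins x cells.  Cells are processed in lexicographic
    barcode order so the result is independent of input column order.
    Cluster labels are ``cluster_1..cluster_k`` ordered by decreasing size
    (ties by smallest member barcode).  If the tree cannot be cut into ``k``
    distinct groups (identical profiles), fewer clusters are returned with a
    warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    barcodes = sorted(profiles.columns)
    if k > len(barcodes):
        raise ValueError(f"k={k} exceeds number of cells ({len(barcodes)})")
    X = profiles[barcodes].to_numpy(dtype=float).T
    if k == 1 or len(barcodes) == 1:
        raw = np.ones(len(barcodes), dtype=int)
    else:
        Z = linkage(X, method="ward")
        raw = fcluster(Z, t=k, criterion="maxclust")
    n_found = len(np.unique(raw))
    if n_found < k:
        warnings.warn(
            f"requested k={k} clusters but only {n_found} distinct groups exist "
            "(degenerate profiles)",
            stacklevel=2,
        )
    # deterministic relabeling: by decreasing size, then smallest barcode
    groups: dict[int, list[str]] = {}
    for bc, lab in zip(barcodes, raw):
        groups.setdefault(int(lab), []).append(bc)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    rename = {old: f"cluster_{i + 1}" for i, (old, _) in enumerate(ordered)}
    labels = pd.Series([rename[int(lab)] for lab in raw], index=barcodes)
    return ClusterAssignment(labels=labels)


# --- circular binary segmentation ------------------------------------------

@dataclass
class Segment:
    contig: str
    start: int
    end: int
    mean_cn: float
    n_bins: int


@dataclass
class SegmentSet:
    """Per-cluster CBS segments tiling the binned genome."""

    segments: dict[str, list[Segment]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": cluster,
                "contig": s.contig,
                "start": s.start,
                "end": s.end,
                "mean_cn": s.mean_cn,
                "n_bins": s.n_bins,
            }
            for cluster, segs in self.segments.items()
            for s in segs
        ]
        return pd.DataFrame(
            rows, columns=["cluster", "contig", "start", "end", "mean_cn", "n_bins"]
        )


@lru_cache(maxsize=512)
def _arc_indices(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Admissible arcs (i, j] (both sides >= min_width) and 1/n_in + 1/n_out."""
    ii, jj = [], []
    for i in range(0, n):
        for j in range(i + 1, n + 1):
            n_in = j - i
            n_out = n - n_in
            if n_in < min_width or n_out < min_width:
                continue
            ii.append(i)
            jj.append(j)
    ii_arr = np.array(ii, dtype=np.intp)
    jj_arr = np.array(jj, dtype=np.intp)
    n_in = jj_arr - ii_arr
    inv = 1.0 / n_in + 1.0 / (n - n_in)
    return ii_arr, jj_arr, inv


def _arc_stats(x: np.ndarray, min_width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All admissible arcs of ``x`` and their T statistics."""
    n = len(x)
    ii, jj, inv = _arc_indices(n, min_width)
    S = np.concatenate([[0.0], np.cumsum(x)])
    total = S[-1]
    n_in = jj - ii
    inside = S[jj] - S[ii]
    mean_in = inside / n_in
    mean_out = (total - inside) / (n - n_in)
    t = np.abs(mean_in - mean_out) / np.sqrt(inv)
    return ii, jj, t


def best_split(x: np.ndarray, min_width: int = 2) -> tuple[int, int, float] | None:
    """Exhaustive max of the arc statistic; None if no admissible arc.

    Returns (i, j, T) for the arc (i, j] maximizing T; ties broken by the
    first arc in (i, j) scan order.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * min_width:
        return None
    ii, jj, t = _arc_stats(x, min_width)
    if len(t) == 0:
        return None
    best = int(np.argmax(t))
    return int(ii[best]), int(jj[best]), float(t[best])


def _perm_max_stats(
    x: np.ndarray, min_width: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Max arc statistic of ``n_perm`` within-segment permutations (batched)."""
    n = len(x)
    ii, jj, inv = _arc_indices(n, min_width)
    perms = np.stack([rng.permutation(x) for _ in range(n_perm)])
    S = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms, axis=1)], axis=1)
    total = S[:, -1:]
    n_in = jj - ii
    inside = S[:, jj] - S[:, ii]
    mean_in = inside / n_in
    mean_out = (total - inside) / (n - n_in)
    t = np.abs(mean_in - mean_out) / np.sqrt(inv)
    return t.max(axis=1)


def cbs_segment_contig(
    x: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Recursive CBS on one contig's per-bin values.

    Returns the sorted list of accepted breakpoints (bin indices b meaning a
    boundary between bins b-1 and b, excluding 0 and n).
    """
    rng = rng or np.random.default_rng(0)
    x = np.asarray(x, dtype=float)
    breakpoints: list[int] = []

    def _recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        res = best_split(seg, min_width)
        if res is None:
            return
        i, j, t_obs = res
        if t_obs <= 0:
            return
        # permutation p-value of the max arc statistic
        exceed = int((_perm_max_stats(seg, min_width, n_perm, rng) >= t_obs).sum())
        p = (exceed + 1) / (n_perm + 1)
        if p >= alpha:
            return
        cuts = [c for c in (i, j) if 0 < c < len(seg)]
        for c in cuts:
            breakpoints.append(lo + c)
        bounds = [0] + cuts + [len(seg)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            _recurse(lo + a, lo + b)

    _recurse(0, len(x))
    return sorted(breakpoints)


def cbs_segment(
    mean_profiles: pd.DataFrame,
    grid: BinGrid,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
) -> SegmentSet:
    """Segment each cluster's mean copy-number profile by CBS.

    ``mean_profiles`` is bins x clusters (grid row order).  Segments tile the
    binned genome per cluster; means are unweighted bin means.
    """
    result = SegmentSet()
    starts = grid.df["start"].to_numpy()
    ends = grid.df["end"].to_numpy()
    for cluster in mean_profiles.columns:
        prof = mean_profiles[cluster].to_numpy(dtype=float)
        segs: list[Segment] = []
        for ci, contig in enumerate(grid.contigs):
            idx = grid.contig_slice(contig)
            x = prof[idx]
            rng = np.random.default_rng(
                [seed, zlib.crc32(str(cluster).encode()) & 0x7FFFFFFF, ci]
            )
            bps = cbs_segment_contig(x, alpha=alpha, n_perm=n_perm, min_width=min_width, rng=rng)
            bounds = [0] + bps + [len(idx)]
            for a, b in zip(bounds[:-1], bounds[1:]):
                segs.append(
                    Segment(
                        contig=contig,
                        start=int(starts[idx[a]]),
                        end=int(ends[idx[b - 1]]),
                        mean_cn=float(x[a:b].mean()),
                        n_bins=b - a,
                    )
                )
        result.segments[cluster] = segs
    return result


# --- CS labeling and CIN regions -------------------------------------------

def aberrant_fraction(
    segments: list[Segment], grid: BinGrid, cn_delta: float = 0.5
) -> float:
    """Weighted genome fraction in segments deviating from CN 2 by > cn_delta."""
    starts = grid.df["start"].to_numpy()
    contigs = grid.df["contig"].to_numpy()
    weights = grid.weights
    total = weights.sum()
    aberrant = 0.0
    for seg in segments:
        if abs(seg.mean_cn - 2.0) > cn_delta:
            mask = (contigs == seg.contig) & (starts >= seg.start) & (starts < seg.end)
            aberrant += weights[mask].sum()
    return aberrant / total


def label_cs_cluster(
    segments: SegmentSet,
    assignment: ClusterAssignment,
    grid: BinGrid,
    cn_delta: float = 0.5,
    cs_max_aberrant: float = 0.05,
) -> ClusterAssignment:
    """Flag the chromosomally stable cluster.

    The cluster with the minimum aberrant genome fraction is flagged CS iff
    that fraction is at most ``cs_max_aberrant``; otherwise no cluster is
    flagged and a warning is raised.  Ties go to the larger cluster, then the
    lexicographically smaller label.
    """
    sizes = assignment.sizes()
    scored = sorted(
        (
            (aberrant_fraction(segs, grid, cn_delta), -int(sizes.get(cluster, 0)), cluster)
            for cluster, segs in segments.segments.items()
        ),
    )
    if not scored:
        raise ValueError("no segmented clusters")
    frac, _, winner = scored[0]
    if frac <= cs_max_aberrant:
        return ClusterAssignment(labels=assignment.labels, cs_cluster=winner)
    warnings.warn(
        f"no chromosomally stable cluster: minimum aberrant fraction {frac:.3f} "
        f"exceeds threshold {cs_max_aberrant}",
        stacklevel=2,
    )
    return ClusterAssignment(labels=assignment.labels, cs_cluster=None)


@dataclass
class CINRegion:
    contig: str
    start: int
    end: int
    direction: str  # "gain" | "loss"


@dataclass
class CINRegionSet:
    regions: dict[str, list[CINRegion]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster": cl, "contig": r.contig, "start": r.start, "end": r.end, "direction": r.direction}
            for cl, regs in self.regions.items()
            for r in regs
        ]
        return pd.DataFrame(rows, columns=["cluster", "contig", "start", "end", "direction"])


def call_cin_regions(segments: SegmentSet, cn_delta: float = 0.5) -> CINRegionSet:
    """Report gained/lost segments; adjacent same-direction regions merged."""
    out = CINRegionSet()
    for cluster, segs in segments.segments.items():
        regions: list[CINRegion] = []
        for seg in segs:
            if seg.mean_cn >= 2.0 + cn_delta:
                direction = "gain"
            elif seg.mean_cn <= 2.0 - cn_delta:
                direction = "loss"
            else:
                continue
            if (
                regions
                and regions[-1].contig == seg.contig
                and regions[-1].end == seg.start
                and regions[-1].direction == direction
            ):
                regions[-1] = CINRegion(seg.contig, regions[-1].start, seg.end, direction)
            else:
                regions.append(CINRegion(seg.contig, seg.start, seg.end, direction))
        out.regions[cluster] = regions
    return out


def _flatten(regions: list[CINRegion]) -> list[CINRegion]:
    return sorted(regions, key=lambda r: (r.contig, r.start, r.direction))


def shared_cin_regions(region_lists: list[list[CINRegion]]) -> list[CINRegion]:
    """Interval intersection of same-direction CIN regions across >= 2 sets.

    Commutative and associative in its inputs.
    """
    if len(region_lists) < 2:
        raise ValueError("need at least two region sets to intersect")
    current = _flatten(region_lists[0])
    for other in region_lists[1:]:
        merged: list[CINRegion] = []
        for a in current:
            for b in _flatten(other):
                if a.contig != b.contig or a.direction != b.direction:
                    continue
                start, end = max(a.start, b.start), min(a.end, b.end)
                if start < end:
                    merged.append(CINRegion(a.contig, start, end, a.direction))
        current = _flatten(merged)
    return current


def filter_genes_to_stable_regions(
    genes: pd.DataFrame,
    region_sets: list[CINRegionSet] | list[list[CINRegion]],
    grid: BinGrid | None = None,
) -> pd.DataFrame:
    """Keep genes overlapping no CIN region in any provided set.

    ``genes`` needs columns gene, contig, start, end (half-open).  Any
    overlap, however small, excludes the gene.  Genes on contigs outside the
    grid (when a grid is given) are excluded with a warning.
    """
    flat: list[CINRegion] = []
    for rs in region_sets:
        if isinstance(rs, CINRegionSet):
            for regs in rs.regions.values():
                flat.extend(regs)
        else:
            flat.extend(rs)
    keep = []
    for row in genes.itertuples():
        if grid is not None and row.contig not in grid.contigs:
            warnings.warn(f"gene {row.gene} on contig {row.contig} absent from grid; excluded", stacklevel=2)
            keep.append(False)
            continue
        hit = any(
            r.contig == row.contig and row.start < r.end and r.start < row.end for r in flat
        )
        keep.append(not hit)
    return genes[np.array(keep, dtype=bool)].reset_index(drop=True)
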