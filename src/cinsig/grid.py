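"""Fixed genomic bin grids.

A :class:`BinGrid` is the shared coordinate system of the copy-number part of
the pipeline: an ordered list of non-overlapping (contig, start, end) bins,
each with a positive weight used to correct expected read counts (partial
terminal bins carry a proportional weight; a mappability track can be folded
in the same way).  Coordinates are 0-based half-open throughout the package;
1-based coordinates appear only in VCF output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BinGrid:
    """Ordered, non-overlapping genomic bins with weights."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"contig", "start", "end"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"grid needs columns {sorted(required)}")
        df = self.df.copy()
        if "weight" not in df.columns:
            df["weight"] = 1.0
        df = df.reset_index(drop=True)
        for contig, sub in df.groupby("contig", sort=False):
            starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
            if not (np.diff(starts) > 0).all() or (starts[1:] < ends[:-1]).any():
                raise ValueError(f"bins on {contig} unsorted or overlapping")
        if (df["weight"] <= 0).any():
            raise ValueError("bin weights must be positive")
        if (df["end"] <= df["start"]).any():
            raise ValueError("empty or inverted bin")
        self.df = df

    @classmethod
    def from_contigs(cls, contig_lengths: dict[str, int], bin_size: int) -> "BinGrid":
        """Tile contigs with fixed-size bins; a trailing partial bin is kept
        with weight proportional to its length."""
        rows = []
        for contig, length in contig_lengths.items():
            for start in range(0, length, bin_size):
                end = min(start + bin_size, length)
                rows.append((contig, start, end, (end - start) / bin_size))
        return cls(pd.DataFrame(rows, columns=["contig", "start", "end", "weight"]))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def contigs(self) -> list[str]:
        return list(dict.fromkeys(self.df["contig"]))

    @property
    def weights(self) -> np.ndarray:
        return self.df["weight"].to_numpy(dtype=float)

    def contig_slice(self, contig: str) -> np.ndarray:
        """Row indices of the bins on ``contig`` (grid order)."""
        return np.flatnonzero((self.df["contig"] == contig).to_numpy())

    def copy_number_vector(self, karyotype: list[tuple[str, int, int, int]]) -> np.ndarray:
        """Per-bin copy number implied by a karyotype.

        The karyotype is a list of (contig, start, end, copy_number) segments
        tiling each contig; a bin straddling a segment boundary gets the
        length-weighted mean copy number.  Bins on contigs with no karyotype
        coverage raise ``ValueError``.
        """
        cn = np.zeros(len(self.df))
        covered = np.zeros(len(self.df))
        contigs = self.df["contig"].to_numpy()
        starts = self.df["start"].to_numpy()
        ends = self.df["end"].to_numpy()
        for contig, seg_start, seg_end, seg_cn in karyotype:
            on = contigs == contig
            overlap = np.minimum(ends, seg_end) - np.maximum(starts, seg_start)
            overlap = np.where(on, np.clip(overlap, 0, None), 0)
            cn += overlap * seg_cn
            covered += overlap
        lengths = ends - starts
        if not np.allclose(covered, lengths):
            bad = self.df.loc[~np.isclose(covered, lengths), ["contig", "start", "end"]]
            raise ValueError(
                f"karyotype does not cover {len(bad)} bin(s), first: "
                f"{bad.iloc[0].tolist() if len(bad) else None}"
            )
        return cn / lengths
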