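"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: FASTA references, minimal VCF v4.2 variant files,
TSV matrices (bin counts with a contig/start/end header triplet, site x cell
presence keyed ``contig:pos:ref:alt``), BED interval tables and JSON
run summaries.  VCFs are written directly (the minimal dialect is fixed by
this package) and read back through cyvcf2.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

_FASTA_WIDTH = 70


def write_fasta(reference: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences."""
    import pyfaidx

    fasta = pyfaidx.Fasta(str(path))
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


# --- bin-count matrix -------------------------------------------------------

def write_bin_counts(counts: pd.DataFrame, grid, path: str | Path) -> None:
    """Write a bins x cells count matrix with a 3-column bin header."""
    out = pd.concat(
        [grid.df[["contig", "start", "end"]].reset_index(drop=True), counts.reset_index(drop=True)],
        axis=1,
    )
    out.to_csv(path, sep="\t", index=False)


def read_bin_counts(path: str | Path):
    """Return (counts DataFrame bins x cells, grid DataFrame contig/start/end)."""
    df = pd.read_csv(path, sep="\t")
    grid_cols = ["contig", "start", "end"]
    if df.columns[:3].tolist() != grid_cols:
        raise ValueError(f"bin-count matrix must start with columns {grid_cols}")
    grid = df[grid_cols].copy()
    counts = df.drop(columns=grid_cols)
    return counts, grid


# --- presence matrix --------------------------------------------------------

def write_presence(presence: pd.DataFrame, path: str | Path) -> None:
    """Write a site x cell 0/1 matrix; rows keyed ``contig:pos:ref:alt``."""
    out = presence.copy()
    out.index.name = "variant"
    out.to_csv(path, sep="\t")


def read_presence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(np.int8)


# --- minimal VCF ------------------------------------------------------------

VCF_HEADER = """##fileformat=VCFv4.2
##source=cinsig
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality of the site">
"""


def write_vcf(
    variants: pd.DataFrame,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
    extra_info: list[str] | None = None,
    info_cols: dict[str, str] | None = None,
) -> None:
    """Write a minimal VCF.

    ``variants`` needs columns contig, pos (1-based), ref, alt, mq; extra INFO
    fields can be taken from additional columns via ``info_cols``
    (column -> INFO key), declared with ``extra_info`` header lines.
    """
    variants = variants.sort_values(["contig", "pos", "ref", "alt"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for line in extra_info or []:
            fh.write(line.rstrip("\n") + "\n")
        for name, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in variants.iterrows():
            info = [f"MQ={row['mq']:g}"]
            for col, key in (info_cols or {}).items():
                val = row[col]
                info.append(f"{key}={val:g}" if isinstance(val, float) else f"{key}={val}")
            fh.write(
                f"{row['contig']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t.\t.\t{';'.join(info)}\n"
            )


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a minimal VCF into a DataFrame (contig, pos, ref, alt, mq, ...)."""
    from cyvcf2 import VCF

    rows = []
    for record in VCF(str(path)):
        for alt in record.ALT:
            rows.append(
                {
                    "contig": record.CHROM,
                    "pos": record.POS,
                    "ref": record.REF,
                    "alt": alt,
                    "mq": record.INFO.get("MQ", np.nan),
                    "vaf": record.INFO.get("VAF", np.nan),
                }
            )
    df = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "mq", "vaf"])
    return df


def variant_key(contig, pos, ref, alt) -> str:
    return f"{contig}:{int(pos)}:{ref}:{alt}"


def split_key(key: str) -> tuple[str, int, str, str]:
    contig, pos, ref, alt = key.rsplit(":", 3)
    return contig, int(pos), ref, alt


# --- blacklist --------------------------------------------------------------

def read_blacklist(path: str | Path) -> set[str]:
    """Read a germline blacklist (TSV with contig/pos/ref/alt, or VCF).

    Returns the set of exact variant keys.  Malformed TSV lines raise with
    the offending line number.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        df = read_vcf(path)
        return {variant_key(r.contig, r.pos, r.ref, r.alt) for r in df.itertuples()}
    keys: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:4] == ["contig", "pos", "ref", "alt"]:
                continue
            if len(fields) < 4:
                raise ValueError(f"malformed blacklist line {lineno}: {line!r}")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"malformed blacklist line {lineno}: {line!r}") from exc
            keys.add(variant_key(fields[0], pos, fields[2], fields[3]))
    return keys


def write_blacklist(variants: pd.DataFrame, path: str | Path) -> None:
    variants[["contig", "pos", "ref", "alt"]].sort_values(["contig", "pos"]).to_csv(
        path, sep="\t", index=False
    )


# --- BED --------------------------------------------------------------------

def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write intervals (contig, start, end + optional name/score cols) as BED."""
    cols = [c for c in ("contig", "start", "end", "name", "score", "strand") if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


# --- JSON -------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
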