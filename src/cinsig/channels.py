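"""Channel definitions for mutation spectra.

Single-base substitutions are classified into the standard 96-channel,
pyrimidine-centered scheme: six substitution classes (C>A, C>G, C>T, T>A,
T>C, T>G) times sixteen 5'/3' flanking-base pairs.  Variants reported with
a purine reference base are reverse-complemented before classification, so
e.g. an A>C change on the forward strand is counted as T>G on the opposite
strand.  The channel order used throughout the package is substitution-major
(all 16 contexts of C>A first, flanks in A,C,G,T order), matching the layout
of the familiar trinucleotide bar plots.

Small insertions/deletions use a compact context scheme: 1-bp events are
collapsed to the pyrimidine base (A->T, G->C) and binned by the length of
the homopolymer run adjacent to the event site; multi-base insertions that
extend a tandem repeat are binned by the number of pre-existing copies of
the inserted unit; everything else falls into catch-all channels.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = "CT"
PURINES = "AG"

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 SBS channel labels, substitution-major, e.g. ``A[C>A]A``.
SBS96_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

SBS96_INDEX: dict[str, int] = {label: i for i, label in enumerate(SBS96_LABELS)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def sbs96_label(ref: str, alt: str, five: str, three: str) -> str:
    """Return the pyrimidine-collapsed channel label for a substitution.

    ``five``/``three`` are the reference bases flanking the variant on the
    forward strand.  Raises ``ValueError`` for non-SNVs or ambiguous (N)
    context bases.
    """
    ref, alt, five, three = ref.upper(), alt.upper(), five.upper(), three.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    for b in (ref, alt, five, three):
        if b not in BASES:
            raise ValueError(f"ambiguous or invalid base {b!r} in context")
    if ref in PURINES:
        ref, alt = revcomp(ref), revcomp(alt)
        five, three = revcomp(three), revcomp(five)
    return f"{five}[{ref}>{alt}]{three}"


def sbs96_channel(ref: str, alt: str, five: str, three: str) -> int:
    """Channel index (0..95) for a substitution; see :func:`sbs96_label`."""
    return SBS96_INDEX[sbs96_label(ref, alt, five, three)]


# --- INDEL channels ---------------------------------------------------------

_HP_BINS = ("1", "2", "3", "4", "5+")
_REP_BINS = ("1", "2", "3+")

#: INDEL channel labels: 1-bp del/ins of C/T by homopolymer-run bin,
#: multi-bp insertions at tandem repeats by repeat-copy bin, plus catch-alls.
INDEL_LABELS: tuple[str, ...] = tuple(
    [f"1bp_del_{base}_hp{hp}" for base in "CT" for hp in _HP_BINS]
    + [f"1bp_ins_{base}_hp{hp}" for base in "CT" for hp in _HP_BINS]
    + [f"ins_rep_{r}" for r in _REP_BINS]
    + ["other_del", "other_ins"]
)

INDEL_INDEX: dict[str, int] = {label: i for i, label in enumerate(INDEL_LABELS)}


def hp_bin(n: int) -> str:
    """Homopolymer-length bin label for a run of length ``n`` (>=1)."""
    return "5+" if n >= 5 else str(n)


def rep_bin(n: int) -> str:
    """Repeat-copy bin label for ``n`` pre-existing unit copies (>=1)."""
    return "3+" if n >= 3 else str(n)
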