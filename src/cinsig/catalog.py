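"""Signature catalogs: COSMIC-format loading and the bundled proxy set.

A catalog maps signature names to 96-channel probability vectors.  COSMIC
v3-style TSVs (a ``Type`` column with labels like ``A[C>A]A`` and one column
per signature) are accepted; for fully self-contained runs a small bundled
*proxy* catalog is constructed programmatically from the defining channels of
the signatures of interest:

* ``SBS17a-proxy`` — 0.90 of its mass on C[T>C]T, the context that defines
  SBS17a (T>C in CTT), 0.10 spread flat over the other 95 channels.
* ``SBS17b-proxy`` — 0.225 on each N[T>G]T channel (T>G in NTT defines
  SBS17b), 0.10 flat elsewhere.
* ``clocklike-proxy`` — 0.60 spread over the four N[C>T]G channels
  (the CpG-deamination contexts typical of age-related signatures),
  0.40 flat over the rest.
* ``flat-proxy`` — uniform over all 96 channels.

These are *synthetic stand-ins* with the right channel support for testing
the pipeline end to end; they are not the COSMIC vectors, which users can
supply as a TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .channels import SBS96_LABELS

BUNDLED_PROXY = "bundled-proxy"

PROXY_NAMES = ("SBS17a-proxy", "SBS17b-proxy", "clocklike-proxy", "flat-proxy")


class SignatureCatalog:
    """A named collection of 96-channel signature probability vectors.

    Stored as a DataFrame indexed by the canonical channel labels with one
    column per signature; every column sums to 1.
    """

    def __init__(self, df: pd.DataFrame):
        if list(df.index) != list(SBS96_LABELS):
            if set(df.index) != set(SBS96_LABELS):
                unknown = sorted(set(df.index) - set(SBS96_LABELS))
                raise ValueError(f"unknown channel labels: {unknown[:5]}")
            df = df.loc[list(SBS96_LABELS)]
        values = df.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("catalog contains negative entries")
        sums = values.sum(axis=0)
        if (sums <= 0).any():
            bad = df.columns[sums <= 0].tolist()
            raise ValueError(f"signature(s) with zero total mass: {bad}")
        if np.abs(sums - 1.0).max() > 1e-6:
            df = df / sums
        self.df = df.astype(float)

    @property
    def names(self) -> list[str]:
        return list(self.df.columns)

    def __contains__(self, name: str) -> bool:
        return name in self.df.columns

    def __getitem__(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()

    def matrix(self, subset: list[str] | None = None) -> np.ndarray:
        """96 x k matrix of the requested signatures (all by default)."""
        names = subset if subset is not None else self.names
        missing = [n for n in names if n not in self.df.columns]
        if missing:
            raise KeyError(f"signatures not in catalog: {missing}")
        return self.df[list(names)].to_numpy(dtype=float)

    def subset(self, names: list[str]) -> "SignatureCatalog":
        return SignatureCatalog(self.df[list(names)].copy())


def proxy_catalog() -> SignatureCatalog:
    """Construct the bundled proxy catalog (see module docstring)."""
    n = len(SBS96_LABELS)
    cols = {}

    a = np.full(n, 0.10 / (n - 1))
    a[SBS96_LABELS.index("C[T>C]T")] = 0.90
    cols["SBS17a-proxy"] = a

    peaks_b = [f"{f}[T>G]T" for f in "ACGT"]
    b = np.full(n, 0.10 / (n - len(peaks_b)))
    for label in peaks_b:
        b[SBS96_LABELS.index(label)] = 0.225
    cols["SBS17b-proxy"] = b

    peaks_c = [f"{f}[C>T]G" for f in "ACGT"]
    c = np.full(n, 0.40 / (n - len(peaks_c)))
    for label in peaks_c:
        c[SBS96_LABELS.index(label)] = 0.60 / len(peaks_c)
    cols["clocklike-proxy"] = c

    cols["flat-proxy"] = np.full(n, 1.0 / n)

    return SignatureCatalog(pd.DataFrame(cols, index=list(SBS96_LABELS)))


def load_catalog(source: str | Path) -> SignatureCatalog:
    """Load a signature catalog.

    ``source`` is either the sentinel ``"bundled-proxy"`` or a path to a
    COSMIC-layout TSV (``Type`` column of channel labels, one column per
    signature).  Raises ``ValueError`` on a malformed file (wrong row count,
    unknown labels, negative entries).
    """
    if str(source) == BUNDLED_PROXY:
        return proxy_catalog()
    df = pd.read_csv(source, sep="\t")
    type_col = next((c for c in df.columns if c.lower() in ("type", "mutationtype", "mutation type")), None)
    if type_col is None:
        raise ValueError("catalog TSV lacks a 'Type' column of channel labels")
    df = df.set_index(type_col)
    if len(df) != len(SBS96_LABELS):
        raise ValueError(f"catalog must have exactly {len(SBS96_LABELS)} channel rows, got {len(df)}")
    return SignatureCatalog(df)
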