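"""Export-signal characterisation across propeptides.

Observed-count sequence-logo matrices over the first 40 alignment columns,
KK-duplet frequencies, hydrophobicity profiles, conserved post-h-region
residue tables, SPI/SPII pathway summaries and the MGE-enrichment
goodness-of-fit chi-square.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from ._alphabet import AMINO_ACIDS, KYTE_DOOLITTLE
from .propeptide_finder import SignalHeuristicParams, _h_region

GAP_CHARS = set("-.")


@dataclasses.dataclass
class LogoCounts:
    family: str
    counts: pd.DataFrame  # residues x columns (1-based column labels)
    totals: np.ndarray  # non-gap count per column
    truncated: bool  # alignment shorter than the requested column count


@dataclasses.dataclass
class KKFrequency:
    fraction: float  # KK duplet within the n-region
    numerator: int
    denominator: int
    anywhere_fraction: float  # KK duplet anywhere in the propeptide


@dataclasses.dataclass
class PathwaySummary:
    n_spi: int
    n_spii: int
    n_unassigned: int
    spii_in_mge: int
    spii_total: int
    expected_mge_fraction: float
    chi2: float
    p: float


def logo_counts(
    aligned: Sequence[str], n_cols: int = 40, family: str = ""
) -> LogoCounts:
    """Raw observed residue counts for the first ``n_cols`` alignment columns
    (no pseudocounts; gaps excluded from column totals)."""
    rows = list(aligned)
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows have unequal lengths")
    use = min(n_cols, width)
    counts = np.zeros((20, use), dtype=int)
    for r in rows:
        for j in range(use):
            c = r[j].upper()
            if c in GAP_CHARS or r[j] in GAP_CHARS:
                continue
            counts[AMINO_ACIDS.index(c), j] += 1
    df = pd.DataFrame(counts, index=list(AMINO_ACIDS), columns=range(1, use + 1))
    return LogoCounts(
        family=family,
        counts=df,
        totals=counts.sum(axis=0),
        truncated=width < n_cols,
    )


def kk_duplet_frequency(
    propeptides: Sequence[str], params: SignalHeuristicParams | None = None
) -> KKFrequency:
    """Fraction of propeptides with a KK duplet in the n-region (first
    ``n_region_max`` residues); the anywhere-in-sequence variant is also
    reported since the narrower reading is ambiguous."""
    seqs = list(propeptides)
    if not seqs:
        raise ValueError("empty propeptide set")
    params = params or SignalHeuristicParams()
    n = sum(1 for s in seqs if "KK" in s[: params.n_region_max])
    anywhere = sum(1 for s in seqs if "KK" in s)
    return KKFrequency(
        fraction=n / len(seqs),
        numerator=n,
        denominator=len(seqs),
        anywhere_fraction=anywhere / len(seqs),
    )


def hydrophobicity_profile(protein: str, window: int = 7) -> np.ndarray:
    """Centered sliding-window mean Kyte–Doolittle hydropathy; edge windows
    truncate to the available residues. Proteins shorter than the window
    collapse to a constant global mean."""
    vals = np.array([KYTE_DOOLITTLE[aa] for aa in protein], dtype=float)
    if len(vals) < window:
        return np.full(len(vals), vals.mean())
    half = window // 2
    out = np.empty(len(vals))
    for i in range(len(vals)):
        lo = max(0, i - half)
        hi = min(len(vals), i + half + 1)
        out[i] = vals[lo:hi].mean()
    return out


def conserved_position_check(
    propeptides: Sequence[str], params: SignalHeuristicParams | None = None
) -> pd.Series:
    """Residue frequency at the first position after the detected h-region.

    Sequences with no detectable h-region (or whose h-region reaches the C
    terminus) are skipped; an all-skip input yields an empty table.
    """
    params = params or SignalHeuristicParams()
    counts: dict[str, int] = {}
    for seq in propeptides:
        if len(seq) < 15:
            continue
        h_span, _ = _h_region(seq, params)
        if h_span is None or h_span[1] >= len(seq):
            continue
        aa = seq[h_span[1]]
        counts[aa] = counts.get(aa, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)


def enrichment_chi_square(
    observed_in_class: int, total: int, expected_fraction: float
) -> tuple[float, float]:
    """Two-cell goodness-of-fit chi-square with 1 df.

    chi2 = (O - E)^2 / E + ((T - O) - (T - E))^2 / (T - E),  E = T * f.
    """
    if not 0.0 < expected_fraction < 1.0:
        raise ValueError("expected_fraction must be in (0, 1)")
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= observed_in_class <= total:
        raise ValueError("observed count must lie in [0, total]")
    expected = total * expected_fraction
    if expected < 5 or (total - expected) < 5:
        warnings.warn(
            "expected cell count below 5; chi-square approximation is weak",
            stacklevel=2,
        )
    chi2 = (observed_in_class - expected) ** 2 / expected + (
        (total - observed_in_class) - (total - expected)
    ) ** 2 / (total - expected)
    return float(chi2), float(chi2_dist.sf(chi2, 1))


def pathway_summary(
    pathways: Sequence[str],
    in_mge: Sequence[bool],
    expected_mge_fraction: float | None = None,
) -> PathwaySummary:
    """Tabulate SPI/SPII/unassigned counts and test SPII enrichment in MGEs.

    ``expected_mge_fraction`` defaults to the observed overall MGE fraction.
    """
    if len(pathways) != len(in_mge):
        raise ValueError("pathways and in_mge must align")
    pw = list(pathways)
    mge = list(bool(x) for x in in_mge)
    n_spi = sum(1 for p in pw if p == "SPI")
    n_spii = sum(1 for p in pw if p == "SPII")
    n_un = len(pw) - n_spi - n_spii
    spii_in_mge = sum(1 for p, m in zip(pw, mge) if p == "SPII" and m)
    if expected_mge_fraction is None:
        expected_mge_fraction = sum(mge) / len(mge) if mge else 0.5
    if n_spii > 0 and 0.0 < expected_mge_fraction < 1.0:
        chi2, p = enrichment_chi_square(spii_in_mge, n_spii, expected_mge_fraction)
    else:
        chi2, p = float("nan"), float("nan")
    return PathwaySummary(
        n_spi=n_spi,
        n_spii=n_spii,
        n_unassigned=n_un,
        spii_in_mge=spii_in_mge,
        spii_total=n_spii,
        expected_mge_fraction=float(expected_mge_fraction),
        chi2=chi2,
        p=p,
    )
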