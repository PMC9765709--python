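"""Propeptide length distributions and mature-peptide repeat structure.

The mature peptide is approximated by the C-terminal residues of the
propeptide; repeat detection takes the last five residues as a seed and
scans the propeptide left-to-right for non-overlapping occurrences with a
small mismatch tolerance, classifying the copies as identical or
pseudorepeated. Length outliers use Tukey fences on linear-interpolation
(type 7) quartiles.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class RepeatReport:
    propeptide_id: str
    seed: str
    count: int
    classification: str  # identical | pseudorepeated | single
    positions: list[int]  # 0-based start of each copy of the seed
    copies: list[str]  # the matched seed-length windows
    variant_positions: list[int]  # 1-based mismatch positions within the seed


@dataclasses.dataclass
class LengthSummary:
    table: pd.DataFrame  # per family: n, quartiles, fences, n_outliers
    outlier_ids: dict[str, list]
    kruskal: pd.DataFrame  # pairwise H/p vs the reference family


def detect_repeats(
    protein: str,
    mismatch_tolerance: int = 1,
    seed_length: int = 5,
    propeptide_id: str = "",
) -> RepeatReport:
    """Greedy non-overlapping scan for (pseudo)copies of the C-terminal seed."""
    if len(protein) < 2 * seed_length:
        seed = protein[-seed_length:]
        return RepeatReport(
            propeptide_id, seed, 1, "single", [len(protein) - len(seed)], [seed], []
        )
    seed = protein[-seed_length:]
    positions: list[int] = []
    copies: list[str] = []
    variant_positions: list[int] = []
    i = 0
    while i <= len(protein) - seed_length:
        window = protein[i : i + seed_length]
        mismatches = [k for k in range(seed_length) if window[k] != seed[k]]
        if len(mismatches) <= mismatch_tolerance:
            positions.append(i)
            copies.append(window)
            variant_positions.extend(k + 1 for k in mismatches)
            i += seed_length
        else:
            i += 1
    count = len(positions)
    if count == 1:
        classification = "single"
    elif variant_positions:
        classification = "pseudorepeated"
    else:
        classification = "identical"
    return RepeatReport(
        propeptide_id,
        seed,
        count,
        classification,
        positions,
        copies,
        sorted(set(variant_positions)),
    )


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    q1, q2, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return float(q1), float(q2), float(q3)


def length_outliers(
    lengths_by_family: Mapping[str, Sequence[float]],
    ids_by_family: Mapping[str, Sequence] | None = None,
    reference: str | None = None,
) -> LengthSummary:
    """Tukey-fence outliers per family plus pairwise Kruskal–Wallis tests
    against a reference family (default: the first family given).

    Families with fewer than 4 values get undefined (NaN) fences, are
    flagged, and contribute no outliers.
    """
    rows = []
    outlier_ids: dict[str, list] = {}
    for family in lengths_by_family:
        values = np.asarray(list(lengths_by_family[family]), dtype=float)
        ids = (
            list(ids_by_family[family])
            if ids_by_family is not None
            else list(range(len(values)))
        )
        if len(values) < 4:
            rows.append(
                dict(
                    family=family,
                    n=len(values),
                    q1=np.nan,
                    median=float(np.median(values)) if len(values) else np.nan,
                    q3=np.nan,
                    lower_fence=np.nan,
                    upper_fence=np.nan,
                    n_outliers=0,
                    fences_defined=False,
                )
            )
            outlier_ids[family] = []
            continue
        q1, q2, q3 = _quartiles(values)
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        mask = (values < lo) | (values > hi)
        rows.append(
            dict(
                family=family,
                n=len(values),
                q1=q1,
                median=q2,
                q3=q3,
                lower_fence=lo,
                upper_fence=hi,
                n_outliers=int(mask.sum()),
                fences_defined=True,
            )
        )
        outlier_ids[family] = [ids[i] for i in np.nonzero(mask)[0]]
    families = list(lengths_by_family)
    reference = reference or (families[0] if families else None)
    kw_rows = []
    for family in families:
        if family == reference:
            continue
        a = list(lengths_by_family[reference])
        b = list(lengths_by_family[family])
        if a and b:
            h, p = kruskal_wallis([a, b])
            kw_rows.append(dict(family=family, reference=reference, H=h, p=p))
    return LengthSummary(
        table=pd.DataFrame(rows),
        outlier_ids=outlier_ids,
        kruskal=pd.DataFrame(kw_rows, columns=["family", "reference", "H", "p"]),
    )


def compare_sibling_propeptides(call_a, call_b) -> tuple[str, list[int] | None]:
    """Position-wise comparison of two sibling mature peptides.

    Returns ('identical', []) or ('variant', [1-based positions]); unequal
    lengths yield ('variant', None).
    """
    a = call_a.mature if hasattr(call_a, "mature") else str(call_a)
    b = call_b.mature if hasattr(call_b, "mature") else str(call_b)
    if len(a) != len(b):
        return "variant", None
    diffs = [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]
    return ("identical", []) if not diffs else ("variant", diffs)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based Kruskal–Wallis H with tie correction; p from chi-square
    with k-1 df. All-identical input returns (0, 1)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def multi_copy_fraction(
    reports: Sequence[RepeatReport], restrict_to: set | None = None
) -> tuple[float, int, int]:
    """Fraction of propeptides carrying more than one (pseudo)copy, optionally
    restricted to a set of propeptide ids (e.g. length outliers).

    Returns (fraction, numerator, denominator).
    """
    pool = [
        r
        for r in reports
        if restrict_to is None or r.propeptide_id in restrict_to
    ]
    if not pool:
        return float("nan"), 0, 0
    num = sum(1 for r in pool if r.count > 1)
    return num / len(pool), num, len(pool)
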