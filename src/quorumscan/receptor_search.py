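"""Profile-based receptor homolog search.

Per-subfamily position-specific score models are built from seed alignments
(log-odds with pseudocounts against fixed background frequencies), scanned
against proteomes with a local gapped dynamic-programming alignment (uniform
affine gap penalties — a documented simplification of full profile-HMM
insert/delete states), and calibrated against random decoys with an
extreme-value (Gumbel) fit so scores can be reported as E-values.

Family assignment applies two special rules:

* proteins passing both the Rap and the NprR thresholds are classed as NprR
  (the Rap model matches the core block shared by both families);
* Rgg assignments require a confirmed nearby propeptide, otherwise the hit
  is dropped (the Rgg model also matches related non-QS regulators).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gumbel_r

from ._align import profile_local_align
from ._alphabet import AMINO_ACIDS, BACKGROUND_FREQUENCIES, encode_protein

GAP_CHARS = set("-.")
_E_FLOOR = 1e-300


@dataclasses.dataclass
class Calibration:
    location: float
    scale: float
    n_decoys: int
    decoy_length: int


@dataclasses.dataclass
class ProfileModel:
    family: str
    matrix: np.ndarray  # (length, 20) log-odds
    calibration: Calibration | None = None

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        """Self-match score of the consensus (sum of column maxima)."""
        return float(self.matrix.max(axis=1).sum())


@dataclasses.dataclass
class SearchThresholds:
    max_evalue: float = 1e-5
    min_coverage: float = 0.6
    per_family: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in [0, 1]")

    def for_family(self, family: str) -> tuple[float, float]:
        return self.per_family.get(family, (self.max_evalue, self.min_coverage))


@dataclasses.dataclass
class ReceptorHit:
    protein_id: str
    family: str
    score: float
    evalue: float
    coverage: float
    replicon_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    assigned_family: str | None = None
    needs_propeptide_confirmation: bool = False
    reassigned_from: str | None = None


def build_profile(
    seed_alignment: Sequence[str],
    background_frequencies: np.ndarray | None = None,
    pseudocount_weight: float = 1.0,
    max_gap_fraction: float = 0.5,
    family: str = "unknown",
) -> ProfileModel:
    """Log-odds profile from an aligned set of sequences.

    Columns whose gap fraction exceeds ``max_gap_fraction`` are dropped.
    The score of residue *a* in a column with observed relative frequency
    ``f`` is ``log((f + w*bg_a) / (1 + w) / bg_a)`` for pseudocount weight
    ``w``.
    """
    rows = list(seed_alignment)
    if not rows:
        raise ValueError("empty seed alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows have unequal lengths")
    bg = (
        BACKGROUND_FREQUENCIES
        if background_frequencies is None
        else np.asarray(background_frequencies, dtype=float)
    )
    w = float(pseudocount_weight)
    columns = []
    for j in range(width):
        col = [r[j] for r in rows]
        residues = []
        for c in col:
            cu = c.upper()
            if cu in GAP_CHARS or c in GAP_CHARS:
                continue
            if cu not in AMINO_ACIDS:
                raise ValueError(f"unknown residue symbol: {c!r} in column {j}")
            residues.append(cu)
        gap_fraction = 1.0 - len(residues) / len(rows)
        if gap_fraction > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for aa in residues:
            counts[AMINO_ACIDS.index(aa)] += 1.0
        freq = counts / counts.sum()
        columns.append(np.log((freq + w * bg) / (1.0 + w) / bg))
    if not columns:
        raise ValueError("no alignment columns retained")
    return ProfileModel(family=family, matrix=np.array(columns))


def calibrate(
    model: ProfileModel,
    n_decoys: int = 500,
    decoy_length: int = 350,
    seed: int = 0,
    min_decoys: int = 500,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> ProfileModel:
    """Fit a Gumbel distribution to best local scores of random decoys.

    Decoys are drawn i.i.d. from the background residue frequencies;
    deterministic for a fixed seed. Returns a new calibrated model.
    """
    if n_decoys < min_decoys:
        raise ValueError(f"n_decoys ({n_decoys}) below configured minimum {min_decoys}")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    for i in range(n_decoys):
        decoy = rng.choice(20, size=decoy_length, p=BACKGROUND_FREQUENCIES).astype(
            np.int8
        )
        scores[i], _, _, _ = profile_local_align(
            model.matrix, decoy, gap_open, gap_extend
        )
    if np.std(scores) < 1e-9:
        raise ValueError("degenerate decoy score variance; cannot calibrate")
    loc, scale = gumbel_r.fit(scores)
    return ProfileModel(
        family=model.family,
        matrix=model.matrix,
        calibration=Calibration(
            location=float(loc),
            scale=float(scale),
            n_decoys=n_decoys,
            decoy_length=decoy_length,
        ),
    )


def tail_probability(model: ProfileModel, score: float) -> float:
    """P(best decoy score >= score) under the fitted Gumbel."""
    if model.calibration is None:
        raise ValueError("model is not calibrated; run calibrate() first")
    z = (score - model.calibration.location) / model.calibration.scale
    if z > 700.0:
        return _E_FLOOR
    p = -np.expm1(-np.exp(-z))
    return float(max(p, _E_FLOOR))


def evalue(model: ProfileModel, score: float, database_size: int) -> float:
    """E-value = tail probability x database size."""
    return max(tail_probability(model, score) * database_size, _E_FLOOR)


def scan_proteome(
    proteins: Mapping[str, str],
    model: ProfileModel,
    thresholds: SearchThresholds | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[ReceptorHit]:
    """Scan every protein with a calibrated model; keep hits passing the
    per-family E-value and coverage thresholds, sorted by E-value."""
    if model.calibration is None:
        raise ValueError("model is not calibrated; run calibrate() first")
    thresholds = thresholds or SearchThresholds()
    max_e, min_cov = thresholds.for_family(model.family)
    n = len(proteins)
    hits: list[ReceptorHit] = []
    for pid, seq in proteins.items():
        enc = encode_protein(seq)
        score, cols, _, _ = profile_local_align(model.matrix, enc, gap_open, gap_extend)
        coverage = cols / model.length
        e = evalue(model, score, n)
        if e <= max_e and coverage >= min_cov:
            hits.append(
                ReceptorHit(
                    protein_id=pid,
                    family=model.family,
                    score=score,
                    evalue=e,
                    coverage=coverage,
                )
            )
    hits.sort(key=lambda h: (h.evalue, h.protein_id))
    return hits


def assign_family(
    hits: Iterable[ReceptorHit],
    propeptide_lookup: Callable[[str], bool] | None = None,
) -> list[ReceptorHit]:
    """Resolve multi-model hits to one assigned family per protein.

    Rap+NprR double hits become NprR (``reassigned_from='Rap'``). Rgg
    assignments are dropped unless ``propeptide_lookup(protein_id)`` is
    true; with no lookup supplied they are kept but flagged
    ``needs_propeptide_confirmation``. Remaining ties break on
    (E-value, family name).
    """
    by_protein: dict[str, list[ReceptorHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    assigned: list[ReceptorHit] = []
    for pid in sorted(by_protein):
        fam_hits = {h.family: h for h in by_protein[pid]}
        if "Rap" in fam_hits and "NprR" in fam_hits:
            chosen = dataclasses.replace(
                fam_hits["NprR"], assigned_family="NprR", reassigned_from="Rap"
            )
        else:
            best = min(by_protein[pid], key=lambda h: (h.evalue, h.family))
            chosen = dataclasses.replace(best, assigned_family=best.family)
        if chosen.assigned_family == "Rgg":
            if propeptide_lookup is None:
                chosen.needs_propeptide_confirmation = True
            elif not propeptide_lookup(pid):
                continue
        assigned.append(chosen)
    return assigned


def attach_coordinates(hits: Iterable[ReceptorHit], genes: pd.DataFrame) -> None:
    """Fill replicon/coordinate fields in place from a gene table."""
    idx = genes.set_index("locus_tag")
    for h in hits:
        if h.protein_id in idx.index:
            row = idx.loc[h.protein_id]
            h.replicon_id = str(row["replicon_id"])
            h.start = int(row["start"])
            h.end = int(row["end"])
            h.strand = str(row["strand"])


def hits_to_frame(hits: Iterable[ReceptorHit]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(h) for h in hits])
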