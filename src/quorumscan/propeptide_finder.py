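"""Locate candidate pheromone-precursor genes next to receptor genes.

The search follows a fixed decision cascade per receptor:

1. build strand-aware flank windows (the 50 terminal bases of the receptor
   gene concatenated with 1,000 additional bases beyond it, on each side);
2. enumerate small ORFs (20–120 aa, starts ATG/GTG/TTG) on both strands of
   each window and score each translated ORF with a signal-peptide
   heuristic; ORFs at or above the primary cutoff are reported;
3. if none pass, re-apply with the relaxed fallback cutoff (0.25);
4. if still none: for the SHP-type families (Rgg, ComR) translate all six
   frames of the upstream window and match peptides longer than 10 aa
   against the known mature peptides (identity > 80%, coverage > 85% of the
   known peptide); for PrgX apply the same matching to the entire plasmid.

The signal-peptide score is a documented heuristic stand-in for neural
signal-peptide predictors: it multiplies an n-region term (KK duplet or
positive residues), an h-region term (max windowed mean hydropathy) and a
c-region term (small residues around a candidate cleavage site); a lipobox
with invariant cysteine switches the pathway to SPII.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._align import fit_align
from ._alphabet import (
    KYTE_DOOLITTLE,
    START_CODONS,
    STOP_CODONS,
    encode_protein,
    revcomp,
    translate,
)
from .io import GenomeBundle
from .receptor_search import ReceptorHit

logger = logging.getLogger(__name__)

TERMINAL_BASES = 50
EXTENSION_BASES = 1000
SHP_ROUTE_FAMILIES = ("Rgg", "ComR")


@dataclasses.dataclass
class FlankWindow:
    """A gene-flank sequence oriented in the focal gene's reading direction.

    ``anchor`` is the replicon coordinate of window position 0 and
    ``direction`` is +1/-1 per window step, so replicon position of window
    position p is ``anchor + direction * p`` (mod length when circular).
    """

    replicon_id: str
    side: str  # downstream | upstream
    seq: str
    anchor: int
    direction: int
    replicon_length: int
    circular: bool
    focal_strand: str

    def replicon_pos(self, p: int) -> int:
        pos = self.anchor + self.direction * p
        return pos % self.replicon_length if self.circular else pos

    def map_span(self, a: int, b: int) -> tuple[int, int]:
        """Window-local half-open span -> replicon half-open span.

        For origin-spanning features of circular replicons the returned end
        may exceed the replicon length (end = start + span length).
        """
        if self.direction == 1:
            start = self.replicon_pos(a)
        else:
            start = self.replicon_pos(b - 1)
        return start, start + (b - a)


@dataclasses.dataclass
class OrfCall:
    replicon_id: str
    start: int
    end: int  # includes the stop codon
    strand: str
    protein: str
    side: str


@dataclasses.dataclass
class SignalHeuristicParams:
    n_region_max: int = 12
    h_window: int = 8
    h_zero: float = 2.0  # windowed hydropathy mapped to 0 at this value
    h_one: float = 3.6  # ... and to 1 here
    c_small: str = "AGS"
    lipobox_pattern: str = r"[LVIF][ASTG][GA]C"
    primary_cutoff: float = 0.6
    fallback_cutoff: float = 0.25
    mature_tail_length: int = 7

    def __post_init__(self) -> None:
        if self.fallback_cutoff > self.primary_cutoff:
            raise ValueError("fallback cutoff must not exceed primary cutoff")


@dataclasses.dataclass
class SignalResult:
    score: float
    cleavage_index: int | None
    pathway: str  # SPI | SPII | none
    h_span: tuple[int, int] | None = None


@dataclasses.dataclass
class PropeptideCall:
    receptor_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    side: str
    protein: str
    score: float
    cleavage_index: int | None
    pathway: str
    predictor: str  # primary | fallback | shp_match | plasmid_wide
    mature: str


# ---------------------------------------------------------------------------
# flank windows
# ---------------------------------------------------------------------------


def _extract(seq: str, start: int, end: int, circular: bool) -> tuple[str, int]:
    """Clipped (linear) or wrapped (circular) slice; returns (subseq, lo)."""
    L = len(seq)
    if circular:
        lo = start % L
        out = "".join(seq[(start + i) % L] for i in range(end - start))
        return out, lo
    lo = max(0, start)
    hi = min(L, end)
    return seq[lo:hi], lo


def build_flank_windows(
    gene: Mapping,
    replicon_seq: str,
    replicon_id: str,
    circular: bool = False,
) -> tuple[FlankWindow, FlankWindow]:
    """Downstream and upstream flank windows of a gene, strand-aware."""
    s, e, strand = int(gene["start"]), int(gene["end"]), str(gene["strand"])
    L = len(replicon_seq)
    if not (0 <= s < e <= L):
        raise ValueError(f"gene coordinates [{s}, {e}) outside replicon of length {L}")
    term = TERMINAL_BASES
    if e - s < term:
        term = e - s
        logger.warning(
            "gene [%d, %d) shorter than %d nt; window uses the whole gene",
            s,
            e,
            TERMINAL_BASES,
        )
    if strand == "+":
        dseq, dlo = _extract(replicon_seq, e - term, e + EXTENSION_BASES, circular)
        down = FlankWindow(replicon_id, "downstream", dseq, dlo, 1, L, circular, "+")
        useq, ulo = _extract(replicon_seq, s - EXTENSION_BASES, s + term, circular)
        up = FlankWindow(replicon_id, "upstream", useq, ulo, 1, L, circular, "+")
    else:
        raw, lo = _extract(replicon_seq, s - EXTENSION_BASES, s + term, circular)
        down = FlankWindow(
            replicon_id,
            "downstream",
            revcomp(raw),
            (lo + len(raw) - 1) % L if circular else lo + len(raw) - 1,
            -1,
            L,
            circular,
            "-",
        )
        raw, lo = _extract(replicon_seq, e - term, e + EXTENSION_BASES, circular)
        up = FlankWindow(
            replicon_id,
            "upstream",
            revcomp(raw),
            (lo + len(raw) - 1) % L if circular else lo + len(raw) - 1,
            -1,
            L,
            circular,
            "-",
        )
    return down, up


# ---------------------------------------------------------------------------
# ORF enumeration
# ---------------------------------------------------------------------------


def _scan_frames(seq: str, min_aa: int, max_aa: int):
    """Yield (start, end) spans (end includes stop codon) of longest-per-stop
    ORFs in the three forward frames of ``seq``."""
    n = len(seq)
    for f in range(3):
        start = None
        for i in range(f, n - 2, 3):
            codon = seq[i : i + 3].upper()
            if codon in STOP_CODONS:
                if start is not None:
                    aa = (i - start) // 3
                    if min_aa <= aa <= max_aa:
                        yield start, i + 3
                    start = None
            elif start is None and codon in START_CODONS:
                start = i


def find_orfs(
    window: FlankWindow, min_aa: int = 20, max_aa: int = 120
) -> list[OrfCall]:
    """All longest-per-stop ORFs on both strands of the window, mapped back
    to replicon coordinates. ORF length counts translated residues
    (stop excluded); the reported span includes the stop codon."""
    W = window.seq
    calls: list[OrfCall] = []
    for on_plus, seq in ((True, W), (False, revcomp(W))):
        for a, b in _scan_frames(seq, min_aa, max_aa):
            protein = translate(seq[a : b - 3], force_met_start=True)
            if on_plus:
                wa, wb = a, b
            else:
                wa, wb = len(W) - b, len(W) - a
            start, end = window.map_span(wa, wb)
            strand = "+" if on_plus == (window.direction == 1) else "-"
            calls.append(
                OrfCall(
                    replicon_id=window.replicon_id,
                    start=start,
                    end=end,
                    strand=strand,
                    protein=protein,
                    side=window.side,
                )
            )
    calls.sort(key=lambda c: (c.start, c.end, c.strand))
    return calls


# ---------------------------------------------------------------------------
# signal-peptide heuristic
# ---------------------------------------------------------------------------


def _h_region(protein: str, params: SignalHeuristicParams):
    """Best hydrophobic window within the signal-peptide region."""
    w = params.h_window
    limit = min(len(protein), 35)
    best = -1e30
    best_start = None
    for i in range(1, limit - w + 1):
        m = sum(KYTE_DOOLITTLE[aa] for aa in protein[i : i + w]) / w
        if m > best:
            best = m
            best_start = i
    if best_start is None:
        return None, 0.0
    return (best_start, best_start + w), best


def score_signal_peptide(
    protein: str, params: SignalHeuristicParams | None = None
) -> SignalResult:
    """Heuristic export-signal score in [0, 1] with predicted cleavage.

    Combines (multiplicatively) the n-region charge term, the h-region
    hydropathy term and the c-region cleavage term; a lipobox match assigns
    SPII. Proteins shorter than 15 aa score 0 with pathway 'none'.
    """
    params = params or SignalHeuristicParams()
    if len(protein) < 15:
        return SignalResult(0.0, None, "none")
    n_region = protein[: params.n_region_max]
    if "KK" in n_region:
        n_score = 1.0
    else:
        basic = sum(n_region.count(aa) for aa in "KR")
        n_score = 0.5 if basic >= 2 else (0.2 if basic == 1 else 0.0)
    h_span, maxh = _h_region(protein, params)
    h_score = min(max((maxh - params.h_zero) / (params.h_one - params.h_zero), 0.0), 1.0)
    pathway = "SPI"
    cleavage = None
    m = re.search(params.lipobox_pattern, protein[2:30])
    if m:
        pathway = "SPII"
        cleavage = 2 + m.start() + 3  # index of the invariant Cys
        c_score = 1.0
    else:
        h_end = h_span[1] if h_span else params.n_region_max
        for i in range(h_end + 1, min(len(protein) - 4, 45)):
            if protein[i - 1] in params.c_small and protein[i - 3] in params.c_small:
                cleavage = i
                break
        c_score = 1.0 if cleavage is not None else 0.3
    score = min(max(n_score * h_score * c_score, 0.0), 1.0)
    if score < params.fallback_cutoff:
        pathway = "none"
    return SignalResult(score, cleavage, pathway, h_span)


# ---------------------------------------------------------------------------
# SHP 6-frame fallback and plasmid-wide mode
# ---------------------------------------------------------------------------


def _frame_peptides(window: FlankWindow, min_len: int = 11):
    """Peptides (> 10 aa) between stops in all six frames of the window,
    with their window-local nt spans and strand."""
    W = window.seq
    for on_plus, seq in ((True, W), (False, revcomp(W))):
        for f in range(3):
            prot = translate(seq[f:])
            start_aa = 0
            for idx, ch in enumerate(prot + "*"):
                if ch == "*":
                    if idx - start_aa >= min_len:
                        a = f + 3 * start_aa
                        b = f + 3 * idx
                        if on_plus:
                            wa, wb = a, b
                        else:
                            wa, wb = len(W) - b, len(W) - a
                        yield prot[start_aa:idx], wa, wb, on_plus
                    start_aa = idx + 1


def shp_fallback_search(
    window: FlankWindow,
    known_peptides: Sequence[str],
    receptor_id: str = "",
    min_identity: float = 0.8,
    min_coverage: float = 0.85,
    predictor: str = "shp_match",
) -> list[PropeptideCall]:
    """Six-frame translation of the window matched against known mature
    peptides; matches with identity > min_identity over > min_coverage of
    the known peptide are returned as calls."""
    calls: list[PropeptideCall] = []
    known = [q for q in known_peptides if q]
    if not known:
        return calls
    encoded = [(q, encode_protein(q)) for q in known]
    for peptide, wa, wb, on_plus in _frame_peptides(window):
        target = encode_protein(peptide)
        best = None
        for q, qenc in encoded:
            _, matches, q_aligned = fit_align(qenc, target)
            identity = matches / len(q)
            coverage = q_aligned / len(q)
            if identity > min_identity and coverage > min_coverage:
                if best is None or identity > best[1]:
                    best = (q, identity)
        if best is not None:
            start, end = window.map_span(wa, wb)
            strand = "+" if on_plus == (window.direction == 1) else "-"
            calls.append(
                PropeptideCall(
                    receptor_id=receptor_id,
                    replicon_id=window.replicon_id,
                    start=start,
                    end=end,
                    strand=strand,
                    side=window.side,
                    protein=peptide,
                    score=best[1],
                    cleavage_index=None,
                    pathway="none",
                    predictor=predictor,
                    mature=best[0],
                )
            )
    return calls


def plasmid_wide_search(
    replicon_id: str,
    replicon_seq: str,
    known_peptides: Sequence[str],
    replicon_type: str,
    receptor_id: str = "",
) -> list[PropeptideCall]:
    """SHP-style matching applied to the whole replicon (both strands);
    only valid for replicons labeled as plasmids."""
    if replicon_type not in ("plasmid", "phage_plasmid"):
        raise ValueError(
            f"plasmid-wide search requires a plasmid replicon, got {replicon_type!r}"
        )
    window = FlankWindow(
        replicon_id=replicon_id,
        side="plasmid",
        seq=replicon_seq,
        anchor=0,
        direction=1,
        replicon_length=len(replicon_seq),
        circular=False,
        focal_strand="+",
    )
    return shp_fallback_search(
        window, known_peptides, receptor_id=receptor_id, predictor="plasmid_wide"
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def call_propeptides(
    receptor: ReceptorHit,
    bundle: GenomeBundle,
    params: SignalHeuristicParams | None = None,
    min_aa: int = 20,
    max_aa: int = 120,
) -> list[PropeptideCall]:
    """Full decision cascade for one receptor; see module docstring."""
    params = params or SignalHeuristicParams()
    family = receptor.assigned_family or receptor.family
    if receptor.replicon_id is None or receptor.start is None:
        raise ValueError(f"receptor {receptor.protein_id} has no resolved coordinates")
    if receptor.replicon_id not in bundle.replicons:
        raise ValueError(f"unknown replicon {receptor.replicon_id!r}")
    replicon = bundle.replicons[receptor.replicon_id]
    if receptor.end > len(replicon):
        raise ValueError("receptor coordinates outside replicon")
    gene = {
        "start": receptor.start,
        "end": receptor.end,
        "strand": receptor.strand or "+",
    }
    circular = receptor.replicon_id in bundle.circular
    down, up = build_flank_windows(
        gene, replicon, receptor.replicon_id, circular=circular
    )
    orfs: list[OrfCall] = []
    for window in (down, up):
        for orf in find_orfs(window, min_aa=min_aa, max_aa=max_aa):
            if _overlap(orf.start, orf.end, receptor.start, receptor.end) > 50:
                continue
            orfs.append(orf)

    def stage(cutoff: float, predictor: str) -> list[PropeptideCall]:
        out = []
        for orf in orfs:
            res = score_signal_peptide(orf.protein, params)
            if res.score >= cutoff and res.pathway != "none":
                mature = orf.protein[-params.mature_tail_length :]
                out.append(
                    PropeptideCall(
                        receptor_id=receptor.protein_id,
                        replicon_id=orf.replicon_id,
                        start=orf.start,
                        end=orf.end,
                        strand=orf.strand,
                        side=orf.side,
                        protein=orf.protein,
                        score=res.score,
                        cleavage_index=res.cleavage_index,
                        pathway=res.pathway,
                        predictor=predictor,
                        mature=mature,
                    )
                )
        return out

    calls = stage(params.primary_cutoff, "primary")
    if not calls:
        # family-specific known-peptide routes run before the relaxed generic
        # cutoff: the SHP-type propeptides carry no canonical signal, so a
        # relaxed signal search could only return noise for these families
        known = bundle.known_peptides
        peptides = (
            list(known[known["family"] == family]["peptide"]) if len(known) else []
        )
        if family in SHP_ROUTE_FAMILIES and peptides:
            calls = shp_fallback_search(
                up, peptides, receptor_id=receptor.protein_id
            )
        elif family == "PrgX" and peptides:
            rtype = bundle.replicon_type(receptor.replicon_id)
            if rtype in ("plasmid", "phage_plasmid"):
                calls = plasmid_wide_search(
                    receptor.replicon_id,
                    replicon,
                    peptides,
                    rtype,
                    receptor_id=receptor.protein_id,
                )
    if not calls:
        calls = stage(params.fallback_cutoff, "fallback")
    seen: set[tuple] = set()
    unique = []
    for call in sorted(calls, key=lambda c: (-c.score, c.start, c.end, c.strand)):
        key = (call.start, call.end, call.strand)
        if key not in seen:
            seen.add(key)
            unique.append(call)
    return unique


def calls_to_frame(calls: Iterable[PropeptideCall]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in calls])
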