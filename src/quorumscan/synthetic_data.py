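"""Synthetic genomes with planted peptide-QS systems.

Generates replicons, gene tables, proteomes and MGE labels together with a
complete planted-truth record, so that every downstream stage (receptor
search, propeptide finding, repeat analysis, context/role classification)
can be exercised and scored without external data.

Design notes
------------
* Family consensus proteins are fixed toy sequences drawn once from the
  background residue distribution. Rap and NprR share a 200-residue core
  block (NprR additionally carries an N-terminal DNA-binding block and a
  C-terminal extension), which reproduces the one-way profile confusion the
  disambiguation rule exists for.
* Background DNA is i.i.d. uniform over ACGT.
* All coordinates are 0-based half-open, strand '+'/'-'; planted ORF
  coordinates include the stop codon. A TAA guard is placed immediately
  upstream (in frame) of every planted small ORF so that its start codon is
  the longest-ORF start for its stop.
* Randomness is split into named substreams of the master seed so tests can
  independently replay individual decision streams (see ``STREAM_*``).
* The short-hydrophobic-peptide (SHP) gene model used for Rgg/ComR (a <20 aa
  peptide gene upstream of the receptor, with no canonical export signal) is
  a stand-in: the literature does not fully specify SHP gene architecture.
  Rgg systems are never planted as eavesdroppers because receptor candidates
  of that family without a nearby propeptide are, by rule, discarded.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from ._alphabet import AMINO_ACIDS, BACKGROUND_FREQUENCIES, PREFERRED_CODON, revcomp
from .io import GENE_COLUMNS, MGE_COLUMNS, GenomeBundle

FAMILIES = ("Rap", "Rgg", "ComR", "NprR", "PlcR", "PrgX", "AimR")
#: families whose propeptide is a short hydrophobic peptide without a
#: canonical export signal (found by the 6-frame fallback route)
SHP_FAMILIES = ("Rgg", "ComR")
#: families planted with canonical SEC-type signal-peptide propeptides
CANONICAL_FAMILIES = ("Rap", "NprR", "PlcR", "AimR")

# named RNG substreams of the master seed (np.random.default_rng([seed, k]))
STREAM_EAVESDROPPER = 1
STREAM_CONTEXT = 2
STREAM_SEQUENCE = 3
STREAM_LAYOUT = 4
STREAM_ARCHITECTURE = 5

_CONSENSUS_SEED = 731024
_AA = np.array(list(AMINO_ACIDS))
#: polar filler for planted n-regions, so the h-region window detection
#: cannot drift left onto n-region residues
_POLAR = np.array(list("STNQDEH"))
#: planted h-regions are poly-Ile: Ile has the maximal hydropathy, so the
#: best hydrophobic window sits exactly on the planted block and the residue
#: right after it (the conserved G/V position) stays outside the h-region
_H_BLOCK = "I" * 8


class SizingError(ValueError):
    """Raised when a replicon cannot hold the requested systems."""


def _sample_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_AA, size=n, p=BACKGROUND_FREQUENCIES))


@lru_cache(maxsize=1)
def family_consensus() -> dict[str, str]:
    """Fixed per-family consensus proteins (deterministic toy sequences)."""
    rng = np.random.default_rng(_CONSENSUS_SEED)
    core = _sample_protein(rng, 200)  # shared Rap/NprR block
    cons = {
        "Rap": _sample_protein(rng, 80) + core,
        "NprR": _sample_protein(rng, 120) + core + _sample_protein(rng, 80),
        "Rgg": _sample_protein(rng, 300),
        "ComR": _sample_protein(rng, 310),
        "PlcR": _sample_protein(rng, 320),
        "PrgX": _sample_protein(rng, 330),
        "AimR": _sample_protein(rng, 340),
    }
    return cons


def mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability ``rate`` (never to itself)."""
    out = list(protein)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        choices = [aa for aa in AMINO_ACIDS if aa != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def family_seed_alignment(
    family: str, n_sequences: int = 8, mutation_rate: float = 0.05, seed: int = 0
) -> list[str]:
    """Gap-free toy seed alignment: mutated copies of the family consensus."""
    cons = family_consensus()[family]
    rng = np.random.default_rng([seed, 100 + FAMILIES.index(family)])
    return [mutate_protein(cons, mutation_rate, rng) for _ in range(n_sequences)]


def reverse_translate(protein: str) -> str:
    return "".join(PREFERRED_CODON[aa] for aa in protein)


def _greedy_seed_scan(protein: str, seed5: str, tol: int = 1):
    """Non-overlapping left-to-right scan for ``seed5`` with <= tol mismatches.

    Internal construction check; the analysis-side implementation lives in
    :mod:`quorumscan.repeat_analysis`.
    """
    hits = []
    k = len(seed5)
    i = 0
    while i <= len(protein) - k:
        mm = sum(a != b for a, b in zip(protein[i : i + k], seed5))
        if mm <= tol:
            hits.append((i, mm))
            i += k
        else:
            i += 1
    return hits


# ---------------------------------------------------------------------------
# configuration and truth records
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SimConfig:
    n_replicons: int = 4
    replicon_length: int = 250_000
    families: tuple[str, ...] = FAMILIES
    systems_per_family: int = 20
    eavesdropper_fraction: float = 0.1
    repeat_copy_range: tuple[int, int] = (1, 3)
    sibling_gene_probability: float = 0.1
    spii_fraction: float = 0.2
    mutation_rate: float = 0.1
    prophage_fraction: float = 0.2
    plasmid_fraction: float = 0.12
    phage_plasmid_fraction: float = 0.04
    prgx_distant_probability: float = 0.5
    mature_length: int = 8
    background_genes: int = 24
    plasmid_length: int = 30_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "eavesdropper_fraction",
            "sibling_gene_probability",
            "spii_fraction",
            "mutation_rate",
            "prophage_fraction",
            "plasmid_fraction",
            "phage_plasmid_fraction",
            "prgx_distant_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.repeat_copy_range
        if not (1 <= lo <= hi <= 6):
            raise ValueError("repeat_copy_range must lie within [1, 6]")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        if self.replicon_length < 2 * _MAX_CASSETTE_SPAN:
            raise SizingError(
                f"replicon_length {self.replicon_length} < 2x max planted-gene "
                f"span ({2 * _MAX_CASSETTE_SPAN})"
            )


#: upper bound on a planted system cassette (two flank ORFs + receptor gene)
_MAX_CASSETTE_SPAN = 3 * 400 + 3 + 2 * 1000
_SLOT_PAD = 1100  # room left before each cassette inside its slot
_MIN_SLOT = _MAX_CASSETTE_SPAN + _SLOT_PAD + 1100


@dataclasses.dataclass
class PlantedPropeptide:
    propeptide_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    protein: str
    mature: str
    matures: tuple[str, ...]
    n_copies: int
    classification: str  # identical | pseudorepeated | single
    variant_position: int | None
    pathway: str  # SPI | SPII | none
    kind: str  # canonical | shp | plasmid_wide
    side: str  # downstream | upstream | distant


@dataclasses.dataclass
class PlantedSystem:
    system_id: str
    family: str
    replicon_id: str
    receptor_id: str
    start: int
    end: int
    strand: str
    context: str  # chromosome | prophage | plasmid | phage-plasmid
    is_eavesdropper: bool
    propeptides: list[PlantedPropeptide]
    expected_role: str


def _expected_role(propeptides: Sequence[PlantedPropeptide]) -> str:
    if not propeptides:
        return "eavesdropper"
    counts: dict[str, int] = {}
    for pp in propeptides:
        for m in pp.matures:
            counts[m] = counts.get(m, 0) + 1
    if max(counts.values()) >= 2:
        return "chatterer"
    if len(counts) >= 2:
        return "multi-message"
    return "single"


# ---------------------------------------------------------------------------
# propeptide construction
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PropeptideDesign:
    nt: str  # in-frame ORF including stop codon
    protein: str
    mature: str
    matures: tuple[str, ...]
    n_copies: int
    classification: str
    variant_position: int | None
    pathway: str


def generate_propeptide(
    family: str,
    n_copies: int = 1,
    variant_position: int | None = None,
    pathway: str = "SPI",
    seed: int | None = 0,
    mature_length: int = 8,
    rng: np.random.Generator | None = None,
) -> PropeptideDesign:
    """Build a canonical propeptide: n-region with KK duplet, hydrophobic
    h-region, cleavage region, and ``n_copies`` tandem mature-peptide copies
    ending at the C terminus.

    SPII variants carry a lipobox ending in an invariant cysteine instead of
    the SPI cleavage motif. ``variant_position`` (1-based, within the last
    five residues of the mature peptide) mutates the first copy only.
    """
    if not 1 <= n_copies <= 6:
        raise ValueError("n_copies must be in [1, 6]")
    if pathway not in ("SPI", "SPII"):
        raise ValueError("pathway must be 'SPI' or 'SPII'")
    if rng is None:
        rng = np.random.default_rng(seed)
    min_overhead = 5 + 8 + 1 + (3 if pathway == "SPI" else 4)
    if n_copies * mature_length + min_overhead > 120:
        raise SizingError(
            f"{n_copies} copies of a {mature_length}-mer exceed the 120 aa budget"
        )
    if variant_position is not None and not (
        mature_length - 4 <= variant_position <= mature_length
    ):
        raise ValueError(
            "variant_position must fall in the last five mature residues"
        )

    for _ in range(400):
        mature = _sample_protein(rng, mature_length)
        seed5 = mature[-5:]
        copies = [mature] * n_copies
        if variant_position is not None:
            if n_copies < 2:
                raise ValueError("variant_position requires n_copies >= 2")
            i = variant_position - 1
            alt = [aa for aa in AMINO_ACIDS if aa != mature[i]]
            copies[0] = mature[:i] + alt[rng.integers(0, len(alt))] + mature[i + 1 :]
        n_region = "MKK" + "".join(rng.choice(_POLAR, size=2))
        h_region = _H_BLOCK
        if pathway == "SPI":
            post_h = {"NprR": "G", "PlcR": "G", "Rap": "V"}.get(
                family, _sample_protein(rng, 1)
            )
            pre = n_region + h_region + post_h + "AQA"
        else:
            pre = n_region + h_region + "LAGC"
        linker_len = int(rng.integers(0, 6))
        budget = 120 - len(pre) - n_copies * mature_length
        linker = _sample_protein(rng, min(linker_len, max(budget, 0)))
        protein = pre + linker + "".join(copies)
        if not 20 <= len(protein) <= 120:
            continue
        # construction check: the greedy last-5-mer scan must see exactly the
        # planted copies, each at a copy suffix, with the planted mismatches
        hits = _greedy_seed_scan(protein, seed5, tol=1)
        if len(hits) != n_copies:
            continue
        prefix = len(protein) - n_copies * mature_length
        want = [prefix + (i + 1) * mature_length - 5 for i in range(n_copies)]
        if [p for p, _ in hits] != want:
            continue
        mismatched = [mm for _, mm in hits if mm > 0]
        if variant_position is not None and variant_position > mature_length - 5:
            expect_class = "pseudorepeated"
            if not mismatched:
                continue
        else:
            expect_class = "single" if n_copies == 1 else "identical"
            if mismatched:
                continue
        return PropeptideDesign(
            nt=reverse_translate(protein) + "TAA",
            protein=protein,
            mature=mature,
            matures=tuple(copies),
            n_copies=n_copies,
            classification=expect_class,
            variant_position=variant_position,
            pathway=pathway,
        )
    raise RuntimeError("failed to construct a self-consistent propeptide")


def generate_shp_propeptide(
    family: str,
    seed: int | None = 0,
    mature_length: int = 8,
    rng: np.random.Generator | None = None,
) -> PropeptideDesign:
    """Short peptide gene (<20 aa, no canonical signal) for the SHP-style
    families; the mature peptide is the C-terminal segment."""
    if rng is None:
        rng = np.random.default_rng(seed)
    mature = _sample_protein(rng, mature_length)
    filler = _sample_protein(rng, int(rng.integers(4, 9)))
    protein = "M" + filler + mature
    return PropeptideDesign(
        nt=reverse_translate(protein) + "TAA",
        protein=protein,
        mature=mature,
        matures=(mature,),
        n_copies=1,
        classification="single",
        variant_position=None,
        pathway="none",
    )


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class _Part:
    start: int
    end: int
    strand: str
    kind: str  # receptor | propeptide
    payload: object


def _build_cassette(
    receptor_nt: str,
    down: list[PropeptideDesign],
    up: list[PropeptideDesign],
    strand: str,
    rng: np.random.Generator,
    dna_rng: np.random.Generator,
) -> tuple[str, list[_Part]]:
    """Assemble receptor + flank ORFs into one forward-strand string, then
    reverse-complement the whole cassette for '-' systems."""
    chunks: list[str] = []
    parts: list[_Part] = []
    pos = 0

    def bg(n: int) -> str:
        return "".join(dna_rng.choice(list("ACGT"), size=n))

    for design in up:
        # ORF must end before the receptor start and begin within 1,000 nt
        gap = int(rng.integers(10, max(11, 980 - len(design.nt))))
        chunks.append("TAA" + design.nt)
        parts.append(
            _Part(pos + 3, pos + 3 + len(design.nt), "+", "propeptide", design)
        )
        pos += 3 + len(design.nt)
        chunks.append(bg(gap))
        pos += gap
    rstart = pos
    chunks.append(receptor_nt)
    pos += len(receptor_nt)
    parts.append(_Part(rstart, pos, "+", "receptor", None))
    for design in down:
        gap = int(rng.integers(10, max(11, 980 - len(design.nt))))
        chunks.append(bg(gap) + "TAA")
        pos += gap + 3
        chunks.append(design.nt)
        parts.append(_Part(pos, pos + len(design.nt), "+", "propeptide", design))
        pos += len(design.nt)
    cassette = "".join(chunks)
    if strand == "-":
        L = len(cassette)
        cassette = revcomp(cassette)
        parts = [
            _Part(L - p.end, L - p.start, "-", p.kind, p.payload) for p in parts
        ]
    return cassette, parts


def generate_genome(config: SimConfig) -> tuple[GenomeBundle, list[PlantedSystem]]:
    """Generate replicons, annotation tables and the planted truth.

    Deterministic for a fixed config (the master seed is split into the
    documented ``STREAM_*`` substreams).
    """
    seed = config.seed
    rng_e = np.random.default_rng([seed, STREAM_EAVESDROPPER])
    rng_c = np.random.default_rng([seed, STREAM_CONTEXT])
    rng_s = np.random.default_rng([seed, STREAM_SEQUENCE])
    rng_l = np.random.default_rng([seed, STREAM_LAYOUT])
    rng_a = np.random.default_rng([seed, STREAM_ARCHITECTURE])
    cons = family_consensus()

    plan = [
        (family, i)
        for family in config.families
        for i in range(config.systems_per_family)
    ]

    # -- decision streams (replayable in isolation) --
    eav_draws = rng_e.random(len(plan)) < config.eavesdropper_fraction
    contexts: list[str] = []
    for (family, _), _u in zip(plan, range(len(plan))):
        u = rng_c.random()
        if family == "PrgX":
            contexts.append("plasmid")  # draw consumed; PrgX rides plasmids
            continue
        if u < config.plasmid_fraction:
            contexts.append("plasmid")
        elif u < config.plasmid_fraction + config.phage_plasmid_fraction:
            contexts.append("phage-plasmid")
        elif u < (
            config.plasmid_fraction
            + config.phage_plasmid_fraction
            + config.prophage_fraction
        ):
            contexts.append("prophage")
        else:
            contexts.append("chromosome")

    # -- per-system construction --
    systems: list[dict] = []
    lo, hi = config.repeat_copy_range
    for idx, (family, i) in enumerate(plan):
        sys_id = f"{family}_{i:03d}"
        eav = bool(eav_draws[idx]) and family != "Rgg"
        context = contexts[idx]
        receptor = mutate_protein(cons[family], config.mutation_rate, rng_s)
        receptor_nt = reverse_translate(receptor) + "TAA"
        down: list[PropeptideDesign] = []
        up: list[PropeptideDesign] = []
        distant: PropeptideDesign | None = None
        if not eav:
            if family in SHP_FAMILIES:
                up.append(
                    generate_shp_propeptide(
                        family, mature_length=config.mature_length, rng=rng_s
                    )
                )
            elif family == "PrgX":
                if rng_a.random() < config.prgx_distant_probability:
                    distant = generate_shp_propeptide(
                        family, mature_length=config.mature_length, rng=rng_s
                    )
                else:
                    down.append(
                        generate_propeptide(
                            family,
                            n_copies=1,
                            pathway="SPI",
                            mature_length=config.mature_length,
                            rng=rng_s,
                        )
                    )
            else:  # canonical signal-peptide families
                sibling = rng_a.random() < config.sibling_gene_probability
                pathway = "SPII" if rng_a.random() < config.spii_fraction else "SPI"
                if sibling:
                    d0 = generate_propeptide(
                        family,
                        n_copies=1,
                        pathway=pathway,
                        mature_length=config.mature_length,
                        rng=rng_s,
                    )
                    identical = rng_a.random() < 0.2
                    if identical:
                        mature_b = d0.mature
                    else:
                        vp = int(rng_a.choice([5, 6]))
                        alt = [aa for aa in AMINO_ACIDS if aa != d0.mature[vp - 1]]
                        mature_b = (
                            d0.mature[: vp - 1]
                            + alt[rng_s.integers(0, len(alt))]
                            + d0.mature[vp:]
                        )
                    d1 = _sibling_with_mature(
                        family, mature_b, pathway, config.mature_length, rng_s
                    )
                    down.append(d0)
                    up.append(d1)
                else:
                    n_copies = int(rng_a.integers(lo, hi + 1))
                    variant = None
                    if n_copies >= 2 and rng_a.random() < 0.3:
                        variant = int(
                            rng_a.integers(
                                config.mature_length - 4, config.mature_length + 1
                            )
                        )
                    down.append(
                        generate_propeptide(
                            family,
                            n_copies=n_copies,
                            variant_position=variant,
                            pathway=pathway,
                            mature_length=config.mature_length,
                            rng=rng_s,
                        )
                    )
        strand = "+" if rng_l.random() < 0.5 else "-"
        systems.append(
            dict(
                sys_id=sys_id,
                family=family,
                eav=eav,
                context=context,
                receptor=receptor,
                receptor_nt=receptor_nt,
                down=down,
                up=up,
                distant=distant,
                strand=strand,
            )
        )

    # -- layout --
    replicons: dict[str, str] = {}
    gene_rows: list[dict] = []
    proteome: dict[str, str] = {}
    mge_rows: list[dict] = []
    truth: list[PlantedSystem] = []
    known_rows: list[dict] = []

    chrom_ids = [f"chrom_{k:02d}" for k in range(config.n_replicons)]
    chrom_seqs = {
        cid: np.array(
            rng_s.choice(list("ACGT"), size=config.replicon_length), dtype="<U1"
        )
        for cid in chrom_ids
    }
    chrom_items: dict[str, list] = {cid: [] for cid in chrom_ids}
    plasmid_systems = []
    for k, sysd in enumerate(systems):
        if sysd["context"] in ("plasmid", "phage-plasmid"):
            plasmid_systems.append(sysd)
        else:
            chrom_items[chrom_ids[k % len(chrom_ids)]].append(sysd)
    for b in range(config.background_genes):
        chrom_items[chrom_ids[b % len(chrom_ids)]].append({"bg": b})

    for cid in chrom_ids:
        items = chrom_items[cid]
        seq = chrom_seqs[cid]
        if items:
            slot = (config.replicon_length - 3000) // len(items)
            if slot < _MIN_SLOT:
                raise SizingError(
                    f"replicon {cid} too short for {len(items)} planted items: "
                    f"slot {slot} nt < required {_MIN_SLOT} nt"
                )
        for j, item in enumerate(items):
            off = 1500 + j * slot + _SLOT_PAD
            if "bg" in item:
                prot = _sample_protein(rng_s, int(rng_s.integers(150, 301)))
                nt = reverse_translate(prot) + "TAA"
                strand = "+" if rng_l.random() < 0.5 else "-"
                placed = nt if strand == "+" else revcomp(nt)
                seq[off : off + len(placed)] = list(placed)
                tag = f"BG_{item['bg']:03d}"
                gene_rows.append(
                    dict(
                        replicon_id=cid,
                        start=off,
                        end=off + len(placed),
                        strand=strand,
                        locus_tag=tag,
                        product="hypothetical protein",
                    )
                )
                proteome[tag] = prot
            else:
                _place_system(
                    item,
                    cid,
                    off,
                    seq,
                    rng_l,
                    rng_s,
                    gene_rows,
                    proteome,
                    mge_rows,
                    truth,
                    known_rows,
                    config,
                )
        replicons[cid] = "".join(seq.tolist())

    for k, sysd in enumerate(plasmid_systems):
        ptype = "plasmid" if sysd["context"] == "plasmid" else "phage_plasmid"
        pid = f"{ptype}_{k:02d}"
        L = config.plasmid_length
        seq = np.array(rng_s.choice(list("ACGT"), size=L), dtype="<U1")
        off = 2000
        _place_system(
            sysd,
            pid,
            off,
            seq,
            rng_l,
            rng_s,
            gene_rows,
            proteome,
            mge_rows,
            truth,
            known_rows,
            config,
        )
        mge_rows.append(dict(replicon_id=pid, type=ptype, start=0, end=L))
        replicons[pid] = "".join(seq.tolist())

    bundle = GenomeBundle(
        replicons=replicons,
        genes=pd.DataFrame(gene_rows, columns=GENE_COLUMNS),
        proteome=proteome,
        mge=pd.DataFrame(mge_rows, columns=MGE_COLUMNS),
        known_peptides=pd.DataFrame(
            known_rows, columns=["family", "peptide"]
        ).drop_duplicates(),
    )
    return bundle, truth


def _sibling_with_mature(
    family: str,
    mature: str,
    pathway: str,
    mature_length: int,
    rng: np.random.Generator,
) -> PropeptideDesign:
    """Second sibling gene encoding a prescribed mature peptide."""
    for _ in range(100):
        n_region = "MKK" + "".join(rng.choice(_POLAR, size=2))
        h_region = _H_BLOCK
        if pathway == "SPI":
            post_h = {"NprR": "G", "PlcR": "G", "Rap": "V"}.get(
                family, _sample_protein(rng, 1)
            )
            pre = n_region + h_region + post_h + "AQA"
        else:
            pre = n_region + h_region + "LAGC"
        linker = _sample_protein(rng, int(rng.integers(0, 6)))
        protein = pre + linker + mature
        hits = _greedy_seed_scan(protein, mature[-5:], tol=1)
        if len(hits) == 1 and hits[0] == (len(protein) - 5, 0):
            return PropeptideDesign(
                nt=reverse_translate(protein) + "TAA",
                protein=protein,
                mature=mature,
                matures=(mature,),
                n_copies=1,
                classification="single",
                variant_position=None,
                pathway=pathway,
            )
    raise RuntimeError("failed to construct sibling propeptide")


def _place_system(
    sysd: dict,
    replicon_id: str,
    off: int,
    seq: np.ndarray,
    rng_l: np.random.Generator,
    rng_s: np.random.Generator,
    gene_rows: list,
    proteome: dict,
    mge_rows: list,
    truth: list,
    known_rows: list,
    config: SimConfig,
) -> None:
    cassette, parts = _build_cassette(
        sysd["receptor_nt"], sysd["down"], sysd["up"], sysd["strand"], rng_l, rng_s
    )
    seq[off : off + len(cassette)] = list(cassette)
    receptor_id = f"{sysd['sys_id']}_R"
    planted_pps: list[PlantedPropeptide] = []
    rstart = rend = 0
    for p in parts:
        gstart, gend = off + p.start, off + p.end
        if p.kind == "receptor":
            rstart, rend = gstart, gend
            gene_rows.append(
                dict(
                    replicon_id=replicon_id,
                    start=gstart,
                    end=gend,
                    strand=p.strand,
                    locus_tag=receptor_id,
                    product=f"{sysd['family']} family receptor",
                )
            )
            proteome[receptor_id] = sysd["receptor"]
        else:
            design: PropeptideDesign = p.payload  # type: ignore[assignment]
            side = "upstream" if design in sysd["up"] else "downstream"
            pp_id = f"{sysd['sys_id']}_P{len(planted_pps)}"
            planted_pps.append(
                PlantedPropeptide(
                    propeptide_id=pp_id,
                    replicon_id=replicon_id,
                    start=gstart,
                    end=gend,
                    strand=p.strand,
                    protein=design.protein,
                    mature=design.mature,
                    matures=design.matures,
                    n_copies=design.n_copies,
                    classification=design.classification,
                    variant_position=design.variant_position,
                    pathway=design.pathway,
                    kind="shp" if design.pathway == "none" else "canonical",
                    side=side,
                )
            )
            if sysd["family"] in SHP_FAMILIES:
                known_rows.append(
                    dict(family=sysd["family"], peptide=design.mature)
                )
    if sysd["distant"] is not None:
        design = sysd["distant"]
        dstart = int(
            rng_l.integers(off + len(cassette) + 5000, len(seq) - len(design.nt) - 500)
        )
        block = "TAA" + design.nt
        seq[dstart : dstart + len(block)] = list(block)
        planted_pps.append(
            PlantedPropeptide(
                propeptide_id=f"{sysd['sys_id']}_P0",
                replicon_id=replicon_id,
                start=dstart + 3,
                end=dstart + 3 + len(design.nt),
                strand="+",
                protein=design.protein,
                mature=design.mature,
                matures=design.matures,
                n_copies=1,
                classification="single",
                variant_position=None,
                pathway="none",
                kind="plasmid_wide",
                side="distant",
            )
        )
        known_rows.append(dict(family="PrgX", peptide=design.mature))
    if sysd["family"] == "PrgX" and not sysd["eav"] and sysd["down"]:
        # adjacent PrgX propeptides are still registered as known peptides
        known_rows.append(dict(family="PrgX", peptide=sysd["down"][0].mature))
    if sysd["context"] == "prophage":
        m1 = int(rng_l.integers(100, 601))
        m2 = int(rng_l.integers(100, 601))
        mge_rows.append(
            dict(
                replicon_id=replicon_id,
                type="prophage",
                start=max(0, off - m1),
                end=min(len(seq), off + len(cassette) + m2),
            )
        )
    truth.append(
        PlantedSystem(
            system_id=sysd["sys_id"],
            family=sysd["family"],
            replicon_id=replicon_id,
            receptor_id=receptor_id,
            start=rstart,
            end=rend,
            strand=sysd["strand"],
            context=sysd["context"],
            is_eavesdropper=sysd["eav"],
            propeptides=planted_pps,
            expected_role=_expected_role(planted_pps),
        )
    )


def truth_to_frame(truth: Sequence[PlantedSystem]) -> pd.DataFrame:
    """Flatten planted systems to one row per system (propeptides as JSON-ish)."""
    rows = []
    for s in truth:
        rows.append(
            dict(
                system_id=s.system_id,
                family=s.family,
                replicon_id=s.replicon_id,
                receptor_id=s.receptor_id,
                start=s.start,
                end=s.end,
                strand=s.strand,
                context=s.context,
                is_eavesdropper=s.is_eavesdropper,
                n_propeptides=len(s.propeptides),
                expected_role=s.expected_role,
                matures=";".join(m for pp in s.propeptides for m in pp.matures),
            )
        )
    return pd.DataFrame(rows)
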