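"""Tests for flank windows, ORF finding, signal scoring and the fallbacks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from quorumscan import synthetic_data as sd
from quorumscan._alphabet import START_CODONS, STOP_CODONS, revcomp
from quorumscan.io import GenomeBundle
from quorumscan.propeptide_finder import (
    FlankWindow,
    SignalHeuristicParams,
    build_flank_windows,
    call_propeptides,
    find_orfs,
    plasmid_wide_search,
    score_signal_peptide,
    shp_fallback_search,
)
from quorumscan.receptor_search import ReceptorHit


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def make_window(seq, side="downstream"):
    return FlankWindow(
        replicon_id="r",
        side=side,
        seq=seq,
        anchor=0,
        direction=1,
        replicon_length=len(seq),
        circular=False,
        focal_strand="+",
    )


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


class TestFlankWindows:
    def test_plus_gene_index_arithmetic(self, rng):
        replicon = random_dna(rng, 10_000)
        gene = {"start": 100, "end": 400, "strand": "+"}
        down, up = build_flank_windows(gene, replicon, "r")
        assert down.seq == replicon[350:1400]
        assert down.anchor == 350 and down.direction == 1
        assert up.seq == replicon[0:150]  # truncated at the origin
        assert up.anchor == 0

    def test_gene_at_linear_end(self, rng):
        replicon = random_dna(rng, 5_000)
        gene = {"start": 4_500, "end": 5_000, "strand": "+"}
        down, _ = build_flank_windows(gene, replicon, "r")
        assert down.seq == replicon[4950:5000]  # last 50 nt of the gene only

    def test_minus_gene_windows_are_mirror_of_plus(self, rng):
        replicon = random_dna(rng, 8_000)
        L = len(replicon)
        gene_plus = {"start": 3_000, "end": 3_900, "strand": "+"}
        dp, upl = build_flank_windows(gene_plus, replicon, "r")
        mirrored = revcomp(replicon)
        gene_minus = {"start": L - 3_900, "end": L - 3_000, "strand": "-"}
        dm, um = build_flank_windows(gene_minus, mirrored, "r")
        assert dm.seq == dp.seq
        assert um.seq == upl.seq

    def test_circular_rotation_invariance(self, rng):
        replicon = random_dna(rng, 6_000)
        gene = {"start": 5_500, "end": 5_900, "strand": "+"}
        down, up = build_flank_windows(gene, replicon, "r", circular=True)
        shift = 2_000
        rotated = replicon[-shift:] + replicon[:-shift]
        gene2 = {"start": (5_500 + shift) % 6_000, "end": (5_900 + shift) % 6_000, "strand": "+"}
        down2, up2 = build_flank_windows(gene2, rotated, "r", circular=True)
        assert down.seq == down2.seq
        assert up.seq == up2.seq

    def test_short_gene_uses_whole_gene(self, rng):
        replicon = random_dna(rng, 2_000)
        gene = {"start": 1_000, "end": 1_030, "strand": "+"}
        down, _ = build_flank_windows(gene, replicon, "r")
        assert down.seq == replicon[1000:2030]

    def test_out_of_range_gene_errors(self, rng):
        replicon = random_dna(rng, 1_000)
        with pytest.raises(ValueError):
            build_flank_windows({"start": 500, "end": 1_200, "strand": "+"}, replicon, "r")


# ---------------------------------------------------------------------------
# ORF finding vs brute-force oracle
# ---------------------------------------------------------------------------


def orf_oracle(window, min_aa=20, max_aa=120):
    """Independent brute-force six-frame enumeration of start-stop spans
    (longest ORF per stop), using Biopython for translation."""
    W = window.seq
    found = set()
    for on_plus, seq in ((True, W), (False, revcomp(W))):
        n = len(seq)
        for f in range(3):
            codon_pos = list(range(f, n - 2, 3))
            stops = [i for i in codon_pos if seq[i : i + 3].upper() in STOP_CODONS]
            starts = [i for i in codon_pos if seq[i : i + 3].upper() in START_CODONS]
            prev = -1
            for stop in stops:
                cands = [s for s in starts if prev < s < stop]
                if cands:
                    st = min(cands)
                    aa = (stop - st) // 3
                    if min_aa <= aa <= max_aa:
                        prot = str(Seq(seq[st:stop]).translate())
                        prot = "M" + prot[1:]
                        if on_plus:
                            wa, wb = st, stop + 3
                        else:
                            wa, wb = len(W) - (stop + 3), len(W) - st
                        start, end = window.map_span(wa, wb)
                        strand = "+" if on_plus == (window.direction == 1) else "-"
                        found.add((start, end, strand, prot))
                prev = stop
    return found


class TestFindOrfs:
    def test_no_start_codon_empty(self):
        window = make_window("CCC" * 400)
        assert find_orfs(window) == []

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            window = make_window(random_dna(rng, 1_050))
            got = {
                (o.start, o.end, o.strand, o.protein) for o in find_orfs(window)
            }
            assert got == orf_oracle(window)

    def test_length_boundaries(self):
        pad = "CCC" * 20
        orf20 = sd.reverse_translate("M" + "A" * 19) + "TAA"
        orf19 = sd.reverse_translate("M" + "A" * 18) + "TAA"
        for orf, expect in ((orf20, True), (orf19, False)):
            window = make_window(pad + "TAA" + orf + pad)
            spans = {(o.start, o.end) for o in find_orfs(window)}
            span = (len(pad) + 3, len(pad) + 3 + len(orf))
            assert (span in spans) == expect

    def test_alternative_start_codons(self):
        pad = "CCC" * 20
        for start in ("ATG", "GTG", "TTG"):
            orf = start + sd.reverse_translate("A" * 24) + "TAA"
            window = make_window(pad + "TAA" + orf + pad)
            spans = {(o.start, o.end): o.protein for o in find_orfs(window)}
            span = (len(pad) + 3, len(pad) + 3 + len(orf))
            assert span in spans
            assert spans[span].startswith("M")  # initiator reads as Met


# ---------------------------------------------------------------------------
# signal heuristic
# ---------------------------------------------------------------------------


class TestSignalHeuristic:
    def test_short_protein_none(self):
        res = score_signal_peptide("MKKLLLL")
        assert res.score == 0.0 and res.pathway == "none"

    def test_poly_ala_none(self):
        res = score_signal_peptide("A" * 40)
        assert res.pathway == "none"
        assert res.score < 0.25

    def test_planted_spi_cleavage(self):
        mature = "WNTETHQR"
        protein = "MKK" + "L" * 10 + "AQA" + mature
        res = score_signal_peptide(protein)
        assert res.pathway == "SPI"
        assert res.score >= 0.6
        assert res.cleavage_index == len(protein) - len(mature)

    def test_planted_lipobox_spii(self):
        protein = "MKKST" + "L" * 8 + "LAGC" + "DNKQWERT"
        res = score_signal_peptide(protein)
        assert res.pathway == "SPII"
        assert protein[res.cleavage_index] == "C"

    def test_fallback_cutoff_validation(self):
        with pytest.raises(ValueError):
            SignalHeuristicParams(primary_cutoff=0.2, fallback_cutoff=0.25)

    def test_generated_propeptides_score_above_primary(self):
        params = SignalHeuristicParams()
        for seed in range(25):
            d = sd.generate_propeptide("AimR", n_copies=1, pathway="SPI", seed=seed)
            assert score_signal_peptide(d.protein, params).score >= params.primary_cutoff
        for seed in range(25):
            d = sd.generate_propeptide("Rap", n_copies=1, pathway="SPII", seed=seed)
            assert score_signal_peptide(d.protein, params).pathway == "SPII"


# ---------------------------------------------------------------------------
# SHP fallback and plasmid-wide search
# ---------------------------------------------------------------------------


class TestShpFallback:
    def _window_with_peptide(self, rng, protein):
        pad = random_dna(rng, 120)
        nt = "TAA" + sd.reverse_translate(protein) + "TAA"
        return make_window(pad + nt + random_dna(rng, 120), side="upstream")

    def test_known_prgx_peptide_found(self, rng):
        carrier = "MNE" + "LTSWWGL" + "QR"  # 12 aa, > 10 aa rule
        window = self._window_with_peptide(rng, carrier)
        calls = shp_fallback_search(window, ["LTSWWGL", "AIFILAS"])
        assert len(calls) == 1
        assert calls[0].mature == "LTSWWGL"
        assert calls[0].score == pytest.approx(1.0)

    def test_empty_known_set(self, rng):
        window = self._window_with_peptide(rng, "MNELTSWWGLQR")
        assert shp_fallback_search(window, []) == []

    def test_identity_thresholds(self, rng):
        query = "LTSWWGL"
        hit_6_of_7 = "MNE" + "LTSWAGL" + "QR"  # 85.7% identity
        hit_5_of_7 = "MNE" + "LTSAAGL" + "QR"  # 71.4% identity
        w1 = self._window_with_peptide(rng, hit_6_of_7)
        w2 = self._window_with_peptide(rng, hit_5_of_7)
        assert len(shp_fallback_search(w1, [query])) == 1
        assert shp_fallback_search(w2, [query]) == []


class TestPlasmidWide:
    def test_chromosome_rejected(self, rng):
        with pytest.raises(ValueError, match="plasmid"):
            plasmid_wide_search("c", random_dna(rng, 1000), ["LTSWWGL"], "chromosome")

    def test_distant_peptide_found(self, rng):
        plasmid = random_dna(rng, 20_000)
        protein = "MTD" + "AIFILAS" + "KE"
        nt = "TAA" + sd.reverse_translate(protein) + "TAA"
        plasmid = plasmid[:15_000] + nt + plasmid[15_000 + len(nt) :]
        calls = plasmid_wide_search("p", plasmid, ["AIFILAS"], "plasmid")
        assert any(c.mature == "AIFILAS" for c in calls)

    def test_no_match_empty(self, rng):
        calls = plasmid_wide_search("p", random_dna(rng, 5_000), ["WWWWWWWW"], "plasmid")
        assert calls == []


# ---------------------------------------------------------------------------
# orchestration on planted genomes
# ---------------------------------------------------------------------------


class TestCallPropeptides:
    def test_planted_canonical_recovered_exactly(self, small_run):
        _, bundle, truth, result = small_run
        for s in truth:
            calls = result.calls_by_receptor.get(s.receptor_id, [])
            keys = {(c.start, c.end, c.strand) for c in calls}
            for pp in s.propeptides:
                if pp.kind == "canonical":
                    assert (pp.start, pp.end, pp.strand) in keys

    def test_receptor_outside_replicon_errors(self, small_run):
        _, bundle, _, _ = small_run
        hit = ReceptorHit(
            protein_id="x",
            family="Rap",
            score=1,
            evalue=1e-30,
            coverage=1.0,
            replicon_id=next(iter(bundle.replicons)),
            start=10,
            end=10**9,
            strand="+",
        )
        with pytest.raises(ValueError):
            call_propeptides(hit, bundle)

    def test_strand_symmetry(self, family_models):
        """Reverse-complementing the genome and flipping all features yields
        the same calls with remapped coordinates."""
        config = sd.SimConfig(
            seed=21,
            families=("Rap", "PlcR"),
            systems_per_family=3,
            n_replicons=1,
            background_genes=0,
            plasmid_fraction=0.0,
            phage_plasmid_fraction=0.0,
        )
        bundle, truth = sd.generate_genome(config)
        flipped_replicons = {k: revcomp(v) for k, v in bundle.replicons.items()}
        genes = bundle.genes.copy()
        lengths = genes["replicon_id"].map({k: len(v) for k, v in bundle.replicons.items()})
        genes["start"], genes["end"] = lengths - bundle.genes["end"], lengths - bundle.genes["start"]
        genes["strand"] = bundle.genes["strand"].map({"+": "-", "-": "+"})
        flipped = GenomeBundle(
            replicons=flipped_replicons,
            genes=genes,
            proteome=bundle.proteome,
            mge=bundle.mge,
            known_peptides=bundle.known_peptides,
        )
        for s in truth:
            L = len(bundle.replicons[s.replicon_id])
            hit = ReceptorHit(
                protein_id=s.receptor_id, family=s.family, score=1, evalue=1e-30,
                coverage=1.0, replicon_id=s.replicon_id, start=s.start, end=s.end,
                strand=s.strand, assigned_family=s.family,
            )
            flipped_hit = ReceptorHit(
                protein_id=s.receptor_id, family=s.family, score=1, evalue=1e-30,
                coverage=1.0, replicon_id=s.replicon_id, start=L - s.end,
                end=L - s.start, strand="-" if s.strand == "+" else "+",
                assigned_family=s.family,
            )
            calls = call_propeptides(hit, bundle)
            calls_f = call_propeptides(flipped_hit, flipped)
            fwd = {(c.start, c.end, c.strand, c.protein) for c in calls}
            back = {
                (L - c.end, L - c.start, "-" if c.strand == "+" else "+", c.protein)
                for c in calls_f
            }
            assert fwd == back

    def test_eavesdropper_plants_rarely_get_calls(self, family_models):
        config = sd.SimConfig(seed=3, eavesdropper_fraction=1.0)
        bundle, truth = sd.generate_genome(config)
        from quorumscan import pipeline

        result = pipeline.run_pipeline(bundle, models=family_models)
        eav = [s for s in truth if s.is_eavesdropper]
        false_calls = sum(
            len(result.calls_by_receptor.get(s.receptor_id, [])) for s in eav
        )
        assert len(eav) >= 100
        assert false_calls / len(eav) <= 0.2
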