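import numpy as np
import pytest

from ifnscan.protein_features import (
    CHOU_FASMAN_ALPHA,
    KYTE_DOOLITTLE,
    FeatureParams,
    call_signal_peptide,
    find_motif,
    find_tm_segments,
    helix_profile,
)

P = FeatureParams()


class TestSignalPeptide:
    SP_PROTEIN = "MKKT" + "L" * 13 + "ASA" + "DEFGHIKLMNPQRS" * 3

    def test_constructed_signal_peptide_accepted(self):
        call = call_signal_peptide(self.SP_PROTEIN, P)
        # verify each clause directly
        charge = sum({"K": 1, "R": 1, "D": -1, "E": -1}.get(a, 0) for a in self.SP_PROTEIN[:5])
        assert charge >= 0
        kd = [KYTE_DOOLITTLE[a] for a in self.SP_PROTEIN]
        assert any(
            np.mean(kd[s : s + 8]) >= 1.5 for s in range(1, 13)
        ), "no h-region window in 2..20"
        assert call.has_sp
        assert 15 <= call.cleavage_pos <= 35
        p = call.cleavage_pos
        assert self.SP_PROTEIN[p - 2] in "AGSCT" and self.SP_PROTEIN[p - 4] in "AGSCT"
        assert call.score >= 1.5

    def test_acidic_n_terminus_rejected(self):
        protein = "M" + "D" * 30 + "AEELKKL" * 5
        call = call_signal_peptide(protein, P)
        assert not call.has_sp
        assert call.cleavage_pos == 0

    def test_too_short_is_error(self):
        with pytest.raises(ValueError, match="too short"):
            call_signal_peptide("MKKTLLLLLLLLLASADEF"[:19], P)

    def test_pure_function(self):
        a = call_signal_peptide(self.SP_PROTEIN, P)
        b = call_signal_peptide(self.SP_PROTEIN, P)
        assert a == b


class TestHelixProfile:
    def test_helix_rich_repeat(self):
        prof = helix_profile("EA" * 30, P)
        # direct window-mean oracle
        pa = [CHOU_FASMAN_ALPHA[a] for a in "EA" * 30]
        for i in range(3, 57):
            assert np.mean(pa[i - 3 : i + 4]) >= 1.03
        assert prof.helix_fraction >= 0.9

    def test_helix_breaking_repeat(self):
        prof = helix_profile("GP" * 30, P)
        assert prof.helix_fraction == 0.0
        assert prof.segments == ()

    def test_short_input_is_error(self):
        with pytest.raises(ValueError):
            helix_profile("EAEAE", P)

    def test_segments_are_maximal_runs(self):
        protein = "EA" * 10 + "GPGPGPGP" + "EA" * 10
        prof = helix_profile(protein, P)
        assert len(prof.segments) == 2
        for s, e in prof.segments:
            assert e - s >= P.helix_min_segment
            assert all(prof.per_residue_helix[s:e])

    def test_planted_positive_has_multiple_helices(self, small_genome):
        for pg in small_genome.truth.positives:
            prof = helix_profile(pg.protein, P)
            assert len(prof.segments) >= P.min_helix_segments


class TestMotifs:
    def test_cysteine_tryptophan_pattern(self):
        hits = find_motif("MCAAAAAWK", "CXXXXX_WL")
        assert len(hits) == 1
        assert hits[0].position == 1
        assert hits[0].matched == "CAAAAAW"

    def test_seventh_residue_must_be_w_or_l(self):
        assert find_motif("CAAAAAF", "CXXXXX_WL") == []
        assert len(find_motif("CAAAAAL", "CXXXXX_WL")) == 1

    def test_box1_pattern(self):
        hits = find_motif("PKKL", "BOX1_PXXL")
        assert len(hits) == 1 and hits[0].position == 0 and hits[0].matched == "PKKL"

    def test_unknown_motif_is_error(self):
        with pytest.raises(ValueError, match="unknown motif"):
            find_motif("ACDE", "ZINC_FINGER")

    def test_overlapping_hits_match_naive_scan(self):
        rng = np.random.default_rng(13)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(300):
            protein = "".join(rng.choice(aas, size=int(rng.integers(7, 60))))
            got = [(h.position, h.matched) for h in find_motif(protein, "CXXXXX_WL")]
            naive = [
                (i, protein[i : i + 7])
                for i in range(len(protein) - 6)
                if protein[i] == "C" and protein[i + 6] in "WL"
            ]
            assert got == naive


class TestTmSegments:
    def test_poly_ile_core_is_one_segment(self):
        protein = "S" * 30 + "I" * 25 + "S" * 30
        segs = find_tm_segments(protein, P)
        assert len(segs) == 1
        s, e = segs[0]
        assert s >= 25 and e <= 60  # covers the hydrophobic core, not the flanks
        # window-mean oracle: every marked residue's window is above threshold
        kd = [KYTE_DOOLITTLE[a] for a in protein]
        for i in range(s, e):
            assert np.mean(kd[i - 9 : i + 10]) >= 1.6

    def test_polar_protein_has_no_segments(self):
        assert find_tm_segments("S" * 80, P) == []

    def test_two_separated_hydrophobic_blocks(self):
        protein = "S" * 25 + "L" * 25 + "SQNTKDE" * 5 + "L" * 25 + "S" * 25
        assert len(find_tm_segments(protein, P)) == 2

    def test_short_protein_returns_empty(self):
        assert find_tm_segments("ILVILVILV", P) == []


class TestScreen:
    def test_positive_passes_all_four(self, small_genome):
        from ifnscan.candidate_search import scan_genome
        from ifnscan.gene_model import intron_phases
        from ifnscan.genome_io import extract_intergenic
        from ifnscan.protein_features import screen_candidate

        ig = extract_intergenic(small_genome.annotation, small_genome.genome, 200)
        cands = scan_genome(small_genome.genome, ig, small_genome.truth.params)
        by_coords = {tuple(c.model.coding_exons): c for c in cands}
        for pg in small_genome.truth.positives:
            cand = by_coords[tuple(pg.model.coding_exons)]
            report = screen_candidate(cand, intron_phases(cand.model), P)
            assert report.passed
            assert all(report.criteria.values())

    @pytest.mark.parametrize(
        "defect,criterion",
        [("no_signal_peptide", "signal_peptide"), ("low_helix", "multi_helix")],
    )
    def test_screen_decoys_fail_exactly_one_criterion(self, small_genome, defect, criterion):
        from ifnscan.candidate_search import scan_genome
        from ifnscan.gene_model import intron_phases
        from ifnscan.genome_io import extract_intergenic
        from ifnscan.protein_features import screen_candidate

        ig = extract_intergenic(small_genome.annotation, small_genome.genome, 200)
        cands = scan_genome(small_genome.genome, ig, small_genome.truth.params)
        by_coords = {tuple(c.model.coding_exons): c for c in cands}
        decoys = [p for p in small_genome.truth.decoys if p.defect == defect]
        assert decoys
        for pg in decoys:
            cand = by_coords[tuple(pg.model.coding_exons)]
            report = screen_candidate(cand, intron_phases(cand.model), P)
            assert not report.passed
            failed = {k for k, v in report.criteria.items() if not v}
            assert failed == {criterion}

    def test_screen_monotone_in_thresholds(self, small_genome):
        from ifnscan.candidate_search import scan_genome
        from ifnscan.gene_model import intron_phases
        from ifnscan.genome_io import extract_intergenic
        from ifnscan.protein_features import screen_candidate

        relaxed = FeatureParams(sp_h_threshold=1.0, helix_threshold=0.9,
                                min_helix_segments=2, sp_cleavage_max=40)
        ig = extract_intergenic(small_genome.annotation, small_genome.genome, 200)
        cands = scan_genome(small_genome.genome, ig, small_genome.truth.params)
        for cand in cands:
            phases = intron_phases(cand.model)
            if screen_candidate(cand, phases, P).passed:
                assert screen_candidate(cand, phases, relaxed).passed
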