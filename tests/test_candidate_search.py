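import itertools

import numpy as np
import pytest

from ifnscan.candidate_search import (
    SearchParams,
    chain_candidates,
    enumerate_exons,
    scan_genome,
)
from ifnscan.gene_model import intron_phases, translate_cds
from ifnscan.genome_io import extract_intergenic

STOPS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# naive oracles (direct transcription of the exon/chain rules)

def naive_exons(region, params):
    found = set()
    n = len(region)
    for s in range(n):
        for L in range(params.min_exon, params.max_exon + 1, 3):
            e = s + L
            if e > n:
                break
            sub = region[s:e]
            codons = [sub[i : i + 3] for i in range(0, L, 3)]
            if region[s : s + 3] == "ATG" and region[e : e + 2] == "GT":
                if not any(c in STOPS or "N" in c for c in codons):
                    found.add((s, e, "first"))
            if s >= 2 and region[s - 2 : s] == "AG":
                if region[e : e + 2] == "GT" and not any(c in STOPS or "N" in c for c in codons):
                    found.add((s, e, "internal"))
                if codons[-1] in STOPS and not any(c in STOPS or "N" in c for c in codons[:-1]):
                    found.add((s, e, "last"))
    return found


def naive_chains(region, params):
    exons = sorted(naive_exons(region, params))
    firsts = [x for x in exons if x[2] == "first"]
    internals = [x for x in exons if x[2] == "internal"]
    lasts = [x for x in exons if x[2] == "last"]
    chains = set()
    lo, hi = params.min_intron, params.max_intron

    def ok(prev_end, start):
        return lo <= start - prev_end <= hi

    for f in firsts:
        for i1 in internals:
            if not ok(f[1], i1[0]):
                continue
            for i2 in internals:
                if not ok(i1[1], i2[0]):
                    continue
                for i3 in internals:
                    if not ok(i2[1], i3[0]):
                        continue
                    for l in lasts:
                        if not ok(i3[1], l[0]):
                            continue
                        coding = sum(x[1] - x[0] for x in (f, i1, i2, i3, l))
                        if params.min_cds <= coding <= params.max_cds:
                            chains.add(tuple((x[0], x[1]) for x in (f, i1, i2, i3, l)))
    return chains


# ---------------------------------------------------------------------------

RELAXED = SearchParams(min_exon=30, max_exon=60, min_intron=60, max_intron=120,
                       min_protein=50, max_protein=100)


class TestEnumerateExons:
    def test_constructed_first_exon(self):
        # ATG-led stop-free 30-mer followed by GT
        region = "ATG" + "GCA" * 9 + "GT" + "C" * 40
        cands = enumerate_exons(region, RELAXED)
        assert any(c.start == 0 and c.end == 30 and c.role == "first" for c in cands)

    def test_stop_repeats_yield_nothing(self):
        region = "TAA" * 40
        assert enumerate_exons(region, RELAXED) == []

    def test_n_at_donor_site_rejects_boundary(self):
        clean = "ATG" + "GCA" * 9 + "GT" + "C" * 40
        broken = "ATG" + "GCA" * 9 + "NT" + "C" * 40
        assert any(c.end == 30 for c in enumerate_exons(clean, RELAXED))
        assert not any(c.end == 30 for c in enumerate_exons(broken, RELAXED))

    def test_matches_naive_oracle_on_random_regions(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            region = "".join(rng.choice(list("ACGTN"), size=400, p=[0.29, 0.2, 0.2, 0.29, 0.02]))
            got = {(c.start, c.end, c.role) for c in enumerate_exons(region, RELAXED)}
            assert got == naive_exons(region, RELAXED)


class TestChaining:
    def test_matches_brute_force_on_random_regions(self):
        rng = np.random.default_rng(23)
        hits = 0
        for _ in range(50):
            region = "".join(rng.choice(list("ACGT"), size=2000, p=[0.3, 0.2, 0.2, 0.3]))
            exons = enumerate_exons(region, RELAXED)
            got = {
                tuple(c.model.coding_exons)
                for c in chain_candidates(exons, RELAXED, dedupe=False)
            }
            expected = naive_chains(region, RELAXED)
            assert got == expected
            hits += len(expected)
        assert hits > 0, "test regions never produced a chain; oracle untested"

    def test_planted_gene_recovered_exactly(self, small_genome):
        truth = {tuple(p.model.coding_exons) for p in small_genome.truth.positives}
        ig = extract_intergenic(small_genome.annotation, small_genome.genome, 200)
        cands = scan_genome(small_genome.genome, ig, small_genome.truth.params)
        got = {tuple(c.model.coding_exons) for c in cands}
        assert truth <= got

    @pytest.mark.parametrize("defect", ["nonzero_phase", "wrong_exon_count", "no_start", "internal_stop"])
    def test_structural_decoys_not_found(self, small_genome, defect):
        decoys = [p for p in small_genome.truth.decoys if p.defect == defect]
        assert decoys, f"fixture lacks a {defect} decoy"
        ig = extract_intergenic(small_genome.annotation, small_genome.genome, 200)
        cands = scan_genome(small_genome.genome, ig, small_genome.truth.params)
        got = {tuple(c.model.coding_exons) for c in cands}
        for p in decoys:
            assert tuple(p.model.coding_exons) not in got

    def test_emitted_candidates_are_valid_genes(self, small_genome):
        ig = extract_intergenic(small_genome.annotation, small_genome.genome, 200)
        for cand in scan_genome(small_genome.genome, ig, small_genome.truth.params):
            assert cand.model.n_exons == 5
            assert intron_phases(cand.model).all_zero
            protein = translate_cds(cand.cds)  # raises on any defect
            assert protein == cand.protein
            assert 120 <= len(protein) <= 250

    def test_widening_protein_bounds_is_monotone(self):
        rng = np.random.default_rng(31)
        region = "".join(rng.choice(list("ACGT"), size=3000, p=[0.3, 0.2, 0.2, 0.3]))
        narrow = RELAXED
        wide = SearchParams(min_exon=30, max_exon=60, min_intron=60, max_intron=120,
                            min_protein=40, max_protein=120)
        get = lambda p: {
            tuple(c.model.coding_exons)
            for c in chain_candidates(enumerate_exons(region, p), p, dedupe=False)
        }
        assert get(narrow) <= get(wide)


class TestScanGenome:
    def test_empty_intergenic_list(self, small_genome):
        assert scan_genome(small_genome.genome, [], small_genome.truth.params) == []

    def test_determinism(self, small_genome):
        ig = extract_intergenic(small_genome.annotation, small_genome.genome, 200)
        a = scan_genome(small_genome.genome, ig, small_genome.truth.params)
        b = scan_genome(small_genome.genome, ig, small_genome.truth.params)
        assert [(c.span, c.model.strand, c.cds) for c in a] == [
            (c.span, c.model.strand, c.cds) for c in b
        ]

    def test_off_sequence_interval_is_error(self, small_genome):
        from ifnscan.genome_io import AnnotatedInterval

        bad = AnnotatedInterval("elsewhere", 0, 100, "+")
        with pytest.raises(ValueError):
            scan_genome(small_genome.genome, [bad], small_genome.truth.params)
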