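import numpy as np
import pytest

from islandscout.genome_model import (AnnotatedGenome, CircularInterval, Feature,
                                      GenomeError, gc_fraction, reverse_complement)
from islandscout.is_atlas import ISFamily, map_is_copies
from islandscout.island_scan import (assemble_symbiosis_islands,
                                     find_candidate_low_gc_islands,
                                     find_partial_trna_copies,
                                     find_trna_anchored_islands)
from islandscout.synth import (GenePlan, ISFamilyPlan, IslandPlan, SymbiosisPlan,
                               SynthSpec, generate_pair)

from conftest import random_dna
from oracles import suffix_occurrences


def _island_genome(rng, dup_len=47, island_len=30_000, n_stack=1, trna_len=76):
    """Hand-built genome: one + strand tRNA with n_stack stacked islands."""
    trna = random_dna(rng, trna_len, gc=0.55)
    parts = [random_dna(rng, 20_000, gc=0.63), trna]
    t_start = 20_001
    t_end = 20_000 + trna_len
    islands = []
    boundary = t_end
    for _ in range(n_stack):
        body = random_dna(rng, island_len - dup_len, gc=0.52)
        dup = trna[-dup_len:]
        if body[-1] == trna[-(dup_len + 1)]:
            body = body[:-1] + "ACGT"["ACGT".index(body[-1]) - 1]
        parts.extend([body, dup])
        end = boundary + island_len
        islands.append((boundary + 1, end, dup_len))
        boundary = end
    parts.append(random_dna(rng, 20_000, gc=0.63))
    seq = "".join(parts)
    # scrub spurious copies of the minimal suffix outside planted sites
    s_min = trna[-14:]
    planted_ends = {t_end} | {e for _, e, _ in islands}
    for p0 in suffix_occurrences(seq, s_min):
        if p0 + 14 not in planted_ends:
            mid = p0 + 7
            seq = seq[:mid] + {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[mid]] + seq[mid + 1:]
    feats = [Feature("tV", "tRNA", CircularInterval(t_start, t_end), "+",
                     product="tRNA-Val", anticodon="CAC")]
    g = AnnotatedGenome(id="ISL", sequence=seq, features=feats)
    return g, islands


class TestTrnaAnchoredIslands:
    def test_single_planted_island_exact(self, rng):
        g, planted = _island_genome(rng, dup_len=47, island_len=30_000)
        found = find_trna_anchored_islands(g)
        assert len(found) == 1
        isl = found[0]
        s, e, d = planted[0]
        assert (isl.interval.start, isl.interval.end) == (s, e)
        assert isl.duplication_length == d
        assert isl.nesting_index == 1
        assert isl.gc_pct < gc_fraction(g)

    def test_four_stacked_islands(self, rng):
        g, planted = _island_genome(rng, dup_len=46, island_len=8_000, n_stack=4)
        found = find_trna_anchored_islands(g)
        assert [i.nesting_index for i in found] == [1, 2, 3, 4]
        for isl, (s, e, d) in zip(found, planted):
            assert (isl.interval.start, isl.interval.end, isl.duplication_length) == (s, e, d)

    def test_stacked_islands_tile_without_gaps(self, rng):
        g, _ = _island_genome(rng, dup_len=30, island_len=5_000, n_stack=3)
        found = find_trna_anchored_islands(g)
        t_end = g.get_feature("tV").interval.end
        expect_start = t_end + 1
        for isl in found:
            assert isl.interval.start == expect_start
            expect_start = isl.interval.end + 1

    def test_below_min_dup_not_reported(self, rng):
        g, _ = _island_genome(rng, dup_len=13, island_len=10_000)
        assert find_trna_anchored_islands(g, min_dup=14) == []

    def test_threshold_boundary_14(self, rng):
        g, _ = _island_genome(rng, dup_len=14, island_len=10_000)
        found = find_trna_anchored_islands(g, min_dup=14)
        assert len(found) == 1 and found[0].duplication_length == 14

    def test_gc_filter_drops_high_gc_island(self, rng):
        trna = random_dna(rng, 76, gc=0.5)
        body = random_dna(rng, 5_000, gc=0.75)  # island hotter than backbone
        seq = random_dna(rng, 10_000, gc=0.5) + trna + body + trna[-20:] \
            + random_dna(rng, 10_000, gc=0.5)
        g = AnnotatedGenome(id="HOT", sequence=seq, features=[
            Feature("tX", "tRNA", CircularInterval(10_001, 10_076), "+")])
        assert find_trna_anchored_islands(g, gc_filter=True) == []
        assert len(find_trna_anchored_islands(g, gc_filter=False)) == 1

    def test_minus_strand_anchor(self, rng):
        g, planted = _island_genome(rng, dup_len=40, island_len=12_000)
        # mirror the genome: the tRNA becomes a minus-strand anchor
        L = g.length
        rc = reverse_complement(g.sequence)
        f = g.features[0]
        feats = [Feature("tV", "tRNA",
                         CircularInterval(L - f.interval.end + 1, L - f.interval.start + 1),
                         "-", anticodon="CAC")]
        gm = AnnotatedGenome(id="ISLM", sequence=rc, features=feats)
        found = find_trna_anchored_islands(gm)
        assert len(found) == 1
        s, e, d = planted[0]
        assert (found[0].interval.start, found[0].interval.end) == (L - e + 1, L - s + 1)
        assert found[0].duplication_length == d

    def test_integrase_attached(self):
        spec = SynthSpec(seed=9, genome_length=150_000,
                         island_plans=(IslandPlan("trnK", 12_000, 30, integrase=True),))
        ga, _, truth = generate_pair(spec)
        found = find_trna_anchored_islands(ga)
        assert len(found) == 1
        assert found[0].integrase_locus == truth.islands[0]["integrase_locus"]
        assert found[0].integrase_locus is not None

    def test_no_trna_error(self, rng):
        g = AnnotatedGenome(id="NONE", sequence=random_dna(rng, 1_000))
        with pytest.raises(GenomeError):
            find_trna_anchored_islands(g)


class TestCandidateIslands:
    def test_planted_low_gc_candidate(self):
        spec = SynthSpec(seed=21, genome_length=150_000,
                         island_plans=(IslandPlan("trnV", 30_000, 0),))
        ga, _, truth = generate_pair(spec)
        cands = find_candidate_low_gc_islands(ga, gc_margin=2.0)
        assert len(cands) == 1
        c = cands[0]
        t = truth.candidates[0]
        assert c.flanking_trna.feature_id == t["anchor"] == "trnV"
        assert abs(c.interval.start - t["start"]) <= 1_000
        assert abs(c.interval.end - t["end"]) <= 1_000
        assert c.evidence == "low_gc_only"

    def test_duplication_makes_it_typical_not_candidate(self):
        spec = SynthSpec(seed=22, genome_length=150_000,
                         island_plans=(IslandPlan("trnV", 30_000, 40),))
        ga, _, _ = generate_pair(spec)
        cands = find_candidate_low_gc_islands(ga, gc_margin=2.0)
        assert all(c.flanking_trna.feature_id != "trnV" for c in cands)
        assert len(find_trna_anchored_islands(ga)) == 1

    def test_uniform_genome_no_candidates(self):
        spec = SynthSpec(seed=23, genome_length=120_000)
        ga, _, _ = generate_pair(spec)
        assert find_candidate_low_gc_islands(ga, gc_margin=2.0) == []


class TestPartialTrnaCopies:
    def test_minus_strand_descending_coordinates(self):
        spec = SynthSpec(seed=31, genome_length=200_000,
                         symbiosis_plan=SymbiosisPlan(), symbiosis_anchor="trnV")
        ga, _, truth = generate_pair(spec)
        trnv = ga.get_feature("trnV")
        hits = find_partial_trna_copies(ga, ga.feature_sequence(trnv), 45,
                                        exclude=trnv.interval)
        assert len(hits) == 1
        h = hits[0]
        t = truth.partial_trnv
        assert (h.start, h.end, h.strand, h.length) == (t["start"], t["end"], "-", 45)
        assert h.start > h.end  # descending convention

    def test_no_copy_planted_empty(self):
        spec = SynthSpec(seed=32, genome_length=120_000)
        ga, _, _ = generate_pair(spec)
        trnv = ga.get_feature("trnV")
        assert find_partial_trna_copies(ga, ga.feature_sequence(trnv), 45,
                                        exclude=trnv.interval) == []

    def test_matches_exhaustive_scan_oracle(self, rng):
        trna = random_dna(rng, 76)
        suffix = trna[-45:]
        seq = (random_dna(rng, 5_000) + suffix + random_dna(rng, 5_000)
               + reverse_complement(suffix) + random_dna(rng, 5_000))
        g = AnnotatedGenome(id="PX", sequence=seq)
        hits = find_partial_trna_copies(g, trna, 45)
        fwd_oracle = suffix_occurrences(seq, suffix)
        rev_oracle = suffix_occurrences(seq, reverse_complement(suffix))
        got_fwd = sorted(min(h.start, h.end) - 1 for h in hits if h.strand == "+")
        got_rev = sorted(min(h.start, h.end) - 1 for h in hits if h.strand == "-")
        assert got_fwd == fwd_oracle
        assert got_rev == rev_oracle

    def test_min_len_must_be_shorter_than_gene(self, rng):
        g = AnnotatedGenome(id="PL", sequence=random_dna(rng, 1_000))
        with pytest.raises(GenomeError):
            find_partial_trna_copies(g, "ACGT" * 10, min_len=40)


@pytest.fixture(scope="module")
def assembled():
    spec = SynthSpec(seed=5, genome_length=300_000,
                     is_family_plans=(ISFamilyPlan("ISx1", 800, copies=4,
                                                   identity=0.95),),
                     gene_plan=GenePlan(count=10),
                     symbiosis_plan=SymbiosisPlan(), symbiosis_anchor="trnV")
    ga, _, truth = generate_pair(spec)
    fams = [ISFamily(n, s) for n, s in truth.is_families.items()]
    copies = map_is_copies(ga, fams)
    cands = find_candidate_low_gc_islands(ga, gc_margin=2.0)
    tier1 = [CircularInterval(t["start"], t["end"])
             for t in truth.symbiosis.values()]
    result = assemble_symbiosis_islands(ga, cands, copies, tier1, "trnV")
    return result, truth


class TestSymbiosisAssembly:
    def test_three_fragments_recovered(self, assembled):
        result, truth = assembled
        assert result.complete
        for name in "ABC":
            frag = result.fragments[name]
            t = truth.symbiosis[name]
            assert abs(frag.interval.start - t["start"]) <= 1_000, name
            assert abs(frag.interval.end - t["end"]) <= 1_000, name

    def test_every_fragment_has_two_evidence_lines(self, assembled):
        result, _ = assembled
        for frag in result.fragments.values():
            assert len(frag.evidence) >= 2

    def test_total_kb(self, assembled):
        result, truth = assembled
        planted_kb = sum((t["end"] - t["start"] + 1)
                        for t in truth.symbiosis.values()) / 1000.0
        assert result.total_kb == pytest.approx(planted_kb, abs=3.0)

    def test_fragment_b_integrase(self, assembled):
        result, _ = assembled
        assert result.fragments["B"].integrase_locus is not None

    def test_partial_hit_reported(self, assembled):
        result, truth = assembled
        assert len(result.partial_trnv_hits) == 1
        assert result.partial_trnv_hits[0].strand == truth.partial_trnv["strand"]

    def test_missing_trnv_error(self, rng):
        g = AnnotatedGenome(id="NOV", sequence=random_dna(rng, 2_000))
        with pytest.raises(GenomeError, match="trnV"):
            assemble_symbiosis_islands(g, [], [], [], "trnV")

    def test_degenerate_evidence_partial_result(self):
        # no IS enrichment and no conserved loci: at most fragment A survives
        spec = SynthSpec(seed=33, genome_length=200_000,
                         symbiosis_plan=SymbiosisPlan(is_in_a=0, is_in_c=0),
                         symbiosis_anchor="trnV")
        ga, _, truth = generate_pair(spec)
        cands = find_candidate_low_gc_islands(ga, gc_margin=2.0)
        result = assemble_symbiosis_islands(ga, cands, [], [], "trnV")
        assert not result.complete
        assert result.notes  # explicit evidence report
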