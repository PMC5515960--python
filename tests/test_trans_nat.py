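import numpy as np
import pytest

from natseek.genome_io import reverse_complement
from natseek.trans_nat import (
    TransSearchConfig,
    anneal_duplex,
    find_complementary_regions,
    find_trans_candidates,
)

from _oracles import complementary_regions_bruteforce, random_dna


def _planted_pair(rng, a_len=500, b_len=500, a_span=(200, 350), b_at=100):
    """Random sequences with rc(a[a_span]) embedded in b."""
    a = random_dna(rng, a_len)
    b = random_dna(rng, b_len)
    seg = reverse_complement(a[a_span[0] : a_span[1]])
    b = b[:b_at] + seg + b[b_at + len(seg) :]
    return a, b


class TestComplementaritySearch:
    def test_planted_exact_complement_is_found(self):
        rng = np.random.default_rng(0)
        a, b = _planted_pair(rng)
        regions = find_complementary_regions(a, b, min_len=100)
        assert regions, "planted 150-nt complement not found"
        best = max(regions, key=lambda r: r.length)
        assert best.length >= 150
        # the planted window is covered
        assert best.a_span.start <= 200 and best.a_span.end >= 350

    @pytest.mark.parametrize("seed", range(100))
    def test_independent_random_pairs_have_no_long_region(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_dna(rng, 500), random_dna(rng, 500)
        assert find_complementary_regions(a, b, min_len=100) == []

    def test_threshold_semantics_on_90nt_complement(self):
        rng = np.random.default_rng(1)
        a, b = _planted_pair(rng, a_span=(200, 290))
        assert find_complementary_regions(a, b, min_len=100) == []
        found = find_complementary_regions(a, b, min_len=80)
        assert found and max(r.length for r in found) >= 90

    def test_empty_sequence_gives_empty_list(self):
        assert find_complementary_regions("", "ACGT" * 50) == []

    def test_min_len_below_seed_size_rejected(self):
        with pytest.raises(ValueError):
            find_complementary_regions("ACGT" * 30, "ACGT" * 30, min_len=8)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_diagonal_scan(self, seed):
        """Seeded/indexed search equals a nested-loop scan on short sequences."""
        rng = np.random.default_rng(seed)
        a, b = _planted_pair(
            rng, a_len=300, b_len=280,
            a_span=(60, 60 + int(rng.integers(40, 120))), b_at=int(rng.integers(0, 120)),
        )
        for min_len in (20, 40, 80):
            got = {
                (r.a_span.start, r.a_span.end, r.b_span.start, r.b_span.end)
                for r in find_complementary_regions(a, b, min_len=min_len)
            }
            expected = complementary_regions_bruteforce(a, b, min_len=min_len)
            assert got == expected

    def test_raising_min_len_never_adds_regions(self):
        rng = np.random.default_rng(3)
        a, b = _planted_pair(rng)
        loose = {
            (r.a_span, r.b_span) for r in find_complementary_regions(a, b, min_len=50)
        }
        tight = {
            (r.a_span, r.b_span) for r in find_complementary_regions(a, b, min_len=120)
        }
        assert tight <= loose


def _bubble_pair(rng, ins_len, half=100):
    """200-nt complement with an interior insertion of ``ins_len`` in b."""
    a = random_dna(rng, 400)
    block = reverse_complement(a[100:300])
    block = block[:half] + random_dna(rng, ins_len) + block[half:]
    b = random_dna(rng, 50) + block + random_dna(rng, 50)
    return a, b


class TestAnnealing:
    def test_perfect_complement_anneals_without_bubbles(self):
        rng = np.random.default_rng(0)
        a, b = _planted_pair(rng, a_span=(100, 300), b_at=50)
        (region,) = sorted(
            find_complementary_regions(a, b, min_len=150), key=lambda r: -r.length
        )[:1]
        duplex = anneal_duplex(a, b, region)
        assert duplex.bubbles == []
        assert duplex.region_len >= 200
        assert duplex.coincides and duplex.passes

    @pytest.mark.parametrize("seed", range(5))
    def test_small_interior_bubble_passes_ten_percent_rule(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _bubble_pair(rng, 15)
        region = max(find_complementary_regions(a, b, min_len=80), key=lambda r: r.length)
        duplex = anneal_duplex(a, b, region)
        assert 15 in duplex.bubbles
        assert max(duplex.bubbles) <= 0.10 * duplex.region_len
        assert duplex.passes

    @pytest.mark.parametrize("seed", range(5))
    def test_large_interior_bubble_fails_ten_percent_rule(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _bubble_pair(rng, 25)
        region = max(find_complementary_regions(a, b, min_len=80), key=lambda r: r.length)
        duplex = anneal_duplex(a, b, region)
        assert max(duplex.bubbles) >= 25
        assert max(duplex.bubbles) > 0.10 * duplex.region_len
        assert not duplex.passes

    def test_bubble_rule_threshold_is_monotone(self):
        rng = np.random.default_rng(7)
        a, b = _bubble_pair(rng, 25)
        region = max(find_complementary_regions(a, b, min_len=80), key=lambda r: r.length)
        strict = anneal_duplex(a, b, region, bubble_max_frac=0.05)
        loose = anneal_duplex(a, b, region, bubble_max_frac=0.20)
        assert not strict.passes and loose.passes


class TestCandidateSearch:
    def test_filter_soundness_on_fixture(self, fixture_bundle, pipeline_result):
        cfg = pipeline_result.config
        for pair in pipeline_result.trans_pairs:
            assert pair.region.length > cfg.trans_min_complement_nt
            assert pair.duplex.passes
            assert pair.high_coverage

    def test_planted_trans_recovery_and_decoys(self, fixture_bundle):
        b = fixture_bundle
        pairs = find_trans_candidates(b.genes, b.transcripts, b.genome)
        got = {(p.st_id, p.nat_id) for p in pairs}
        for t in b.truth.planted_trans:
            if t.expect_pass:
                assert (t.st_id, t.nat_id) in got, f"missed planted pair {t.nat_id}"
            else:
                assert (t.st_id, t.nat_id) not in got, (
                    f"decoy {t.nat_id} ({t.reason}) incorrectly reported"
                )

    def test_cis_overlapping_loci_are_excluded(self, fixture_bundle):
        """Same-locus antisense partners never appear in the trans catalog."""
        b = fixture_bundle
        pairs = find_trans_candidates(b.genes, b.transcripts, b.genome)
        genes = {g.id: g for g in b.genes}
        txs = {t.id: t for t in b.transcripts}
        for p in pairs:
            assert not genes[p.st_id].interval.overlaps(txs[p.nat_id].interval)

    def test_monotonicity_in_thresholds(self, fixture_bundle):
        b = fixture_bundle
        base = {
            (p.st_id, p.nat_id)
            for p in find_trans_candidates(b.genes, b.transcripts, b.genome)
        }
        stricter_len = {
            (p.st_id, p.nat_id)
            for p in find_trans_candidates(
                b.genes, b.transcripts, b.genome,
                TransSearchConfig(min_complement_nt=150),
            )
        }
        assert stricter_len <= base
        looser_bubble = {
            (p.st_id, p.nat_id)
            for p in find_trans_candidates(
                b.genes, b.transcripts, b.genome,
                TransSearchConfig(bubble_max_frac=0.25),
            )
        }
        assert base <= looser_bubble
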