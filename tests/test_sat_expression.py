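import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from natseek.cis_nat import CisPair
from natseek.genome_io import ExpressionMatrix, GenomicInterval, Span
from natseek.sat_expression import (
    normalize_profile,
    pearson_with_significance,
    relationship_type,
    rpkm,
    venn_partition,
)


def _pair(st, nat):
    iv = GenomicInterval("s", 0, 100, "+")
    jv = GenomicInterval("s", 50, 150, "-")
    return CisPair(st, nat, "s", iv, jv, Span(50, 100), "convergent", 0.5, 0.5)


def _matrix(rows: dict[str, tuple]) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=["M", "P", "FB"]).astype(float)
    )


class TestRpkm:
    def test_arithmetic(self):
        assert rpkm(100, 500, 10**6) == pytest.approx(200.0)

    def test_zero_reads(self):
        assert rpkm(0, 500, 10**6) == 0.0

    def test_doubling_library_halves_value(self):
        assert rpkm(100, 500, 2 * 10**6) == pytest.approx(rpkm(100, 500, 10**6) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 10**6)
        with pytest.raises(ValueError):
            rpkm(1, 500, 0)


class TestRelationships:
    def test_single_pair_is_one_to_one(self):
        (rel,) = relationship_type([_pair("g1", "a1")])
        assert rel.relation == "1:1"

    def test_one_gene_two_nats(self):
        rels = relationship_type([_pair("g1", "a1"), _pair("g1", "a2")])
        assert [r.relation for r in rels] == ["1:n", "1:n"]

    def test_full_nxn_case(self):
        rels = relationship_type(
            [_pair("g1", "a1"), _pair("g2", "a1"), _pair("g2", "a2")]
        )
        by_pair = {(r.st_id, r.nat_id): r.relation for r in rels}
        assert by_pair == {
            ("g1", "a1"): "n:1",
            ("g2", "a1"): "n:n",
            ("g2", "a2"): "1:n",
        }

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_degree_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pairs = list(
            {
                (f"g{int(rng.integers(0, 15))}", f"a{int(rng.integers(0, 15))}")
                for _ in range(40)
            }
        )
        rels = relationship_type([_pair(s, n) for s, n in pairs])
        st_deg = {s: sum(1 for x, _ in pairs if x == s) for s, _ in pairs}
        nat_deg = {n: sum(1 for _, x in pairs if x == n) for _, n in pairs}
        for rel in rels:
            st_multi = st_deg[rel.st_id] >= 2
            nat_multi = nat_deg[rel.nat_id] >= 2
            expected = {
                (True, True): "n:n", (True, False): "1:n",
                (False, True): "n:1", (False, False): "1:1",
            }[(st_multi, nat_multi)]
            assert rel.relation == expected


class TestVenn:
    def test_all_zero_matrix(self):
        m = _matrix({"t1": (0, 0, 0), "t2": (0, 0, 0)})
        counts = venn_partition(m, ["t1", "t2"])
        assert counts["total"] == 0
        assert all(v == 0 for k, v in counts.items())

    def test_cutoff_is_inclusive(self):
        m = _matrix({"t1": (2.0, 1.9, 0.0)})
        counts = venn_partition(m, ["t1"])
        assert counts["M"] == 1 and counts["total"] == 1

    def test_regions_sum_to_total(self):
        rng = np.random.default_rng(0)
        rows = {f"t{i}": tuple(rng.uniform(0, 6, 3)) for i in range(60)}
        m = _matrix(rows)
        counts = venn_partition(m, list(rows))
        region_sum = sum(v for k, v in counts.items() if k != "total")
        assert region_sum == counts["total"]

    def test_requires_exactly_three_stages(self):
        df = pd.DataFrame({"M": [1.0], "P": [1.0]}, index=["t1"])
        with pytest.raises(ValueError, match="3 stages"):
            venn_partition(ExpressionMatrix(df), ["t1"])


class TestNormalize:
    def test_constant_profile_max_mode(self):
        assert np.allclose(normalize_profile([4, 4, 4], mode="max"), [1, 1, 1])

    def test_mean_mode_averages_to_one(self):
        out = normalize_profile([3.0, 7.0, 11.0], mode="mean")
        assert out.mean() == pytest.approx(1.0)

    def test_max_mode_peaks_at_one(self):
        out = normalize_profile([3.0, 7.0, 11.0], mode="max")
        assert out.max() == pytest.approx(1.0)

    def test_all_zero_profile_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_profile([0, 0, 0])

    def test_log_transform_applied_first(self):
        out = normalize_profile([0.0, 1.0, 3.0], mode="max", log=True)
        expected = np.log2(np.array([0, 1, 3.0]) + 1)
        assert np.allclose(out, expected / expected.max())


class TestCorrelation:
    def test_perfect_linearity_reports_infinite_t(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = pearson_with_significance(x, [2 * v + 1 for v in x])
        assert res.r == pytest.approx(1.0)
        assert math.isinf(res.t) and res.t > 0
        assert res.p == 0.0

    def test_t_statistic_formula(self):
        # r = 0.8 at N = 5: t = 0.8 / sqrt(0.36/3) = 2.3094
        rng = np.random.default_rng(0)
        # construct profiles with a known r by rotation
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            res = pearson_with_significance(x, y)
            if abs(res.r) >= 1 - 1e-9:
                continue
            expected_t = res.r / math.sqrt((1 - res.r**2) / 3)
            assert res.t == pytest.approx(expected_t)
            # cross-check the directional p against an independent route
            assert res.p == pytest.approx(float(stats.t.sf(abs(expected_t), 3)))

    def test_zero_correlation_gives_half(self):
        res = pearson_with_significance([1.0, 2.0, 1.0, 2.0], [1.0, 1.0, 2.0, 2.0])
        assert res.r == pytest.approx(0.0)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(size=6)
        a = pearson_with_significance(x, y)
        b = pearson_with_significance(y, x)
        assert a.r == pytest.approx(b.r) and a.p == pytest.approx(b.p)

    def test_zero_variance_is_flagged_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_with_significance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("rho", [-0.9, 0.0, 0.9])
    def test_planted_correlation_recovery(self, rho):
        """Mean sample r over 1000 three-point pairs recovers the planted
        correlation's sign and magnitude (within the small-N attenuation)."""
        rng = np.random.default_rng(12345)
        cov = [[1.0, rho], [rho, 1.0]]
        rs = []
        for _ in range(1000):
            xy = rng.multivariate_normal([0, 0], cov, size=3)
            try:
                rs.append(pearson_with_significance(xy[:, 0], xy[:, 1]).r)
            except ValueError:
                continue
        mean_r = float(np.mean(rs))
        assert abs(mean_r - rho) <= 0.1
        if rho != 0:
            assert math.copysign(1, mean_r) == math.copysign(1, rho)


def test_fixture_relationship_labels(fixture_bundle, pipeline_result, member_to_unit):
    truth = fixture_bundle.truth
    got = {(r.st_id, r.nat_id): r.relation for r in pipeline_result.relationships}
    for planted in truth.planted_cis:
        key = (planted.st_id, member_to_unit[planted.nat_id])
        assert got[key] == planted.relation


def test_fixture_stage_presence_matches_planted_patterns(
    fixture_bundle, pipeline_result, member_to_unit
):
    truth = fixture_bundle.truth
    venn = pipeline_result.venn
    planted_regions: dict[str, int] = {}
    final_nats = {member_to_unit[p.nat_id] for p in truth.planted_cis} | {
        t.nat_id for t in truth.planted_trans if t.expect_pass
    }
    for nat_id, stages in truth.stage_patterns.items():
        uid = member_to_unit.get(nat_id, nat_id)
        if uid in final_nats or nat_id in final_nats:
            region = "&".join(s for s in ("M", "P", "FB") if s in stages)
            planted_regions[region] = planted_regions.get(region, 0) + 1
    for region, count in planted_regions.items():
        assert venn[region] == count
    assert venn["total"] == sum(planted_regions.values())
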