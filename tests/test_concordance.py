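"""Concordance engine vs independent set-arithmetic and binomial oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ffconcord.io_formats import CoverageBin, GenomicRegionSet, VariantRecord
from ffconcord.concordance import (
    PowerFilterConfig,
    af_sweep,
    combine_callers,
    detection_power,
    min_detectable_af,
    partition,
    power_filter,
    stratify_by_region,
)
from ffconcord.synthetic import (
    SimulationConfig,
    sample_observed_callsets,
    simulate_coverage,
    simulate_truth,
)


def _variants_from_keys(keys, depth=100, alt=30):
    return [VariantRecord("1", 10 * (i + 1), "C", "T", depth=depth, alt_count=alt)
            for i in sorted(keys)]


def _random_variants(rng, n, n_positions=1500, chrom="1"):
    pos = rng.choice(np.arange(1, n_positions + 1) * 7, size=n, replace=False)
    out = []
    for p in sorted(pos):
        depth = int(rng.integers(40, 150))
        alt = int(rng.integers(1, depth + 1))
        out.append(VariantRecord(chrom, int(p), "C", "T",
                                 depth=depth, alt_count=alt))
    return out


class TestPartition:
    def test_identical_sets(self):
        vs = _variants_from_keys(range(5))
        p = partition(vs, vs)
        assert (p.agreement, p.sensitivity, p.ppv) == (1.0, 1.0, 1.0)

    def test_small_example(self):
        ff = _variants_from_keys([0, 1, 2])
        ffpe = _variants_from_keys([1, 2, 3])
        p = partition(ff, ffpe)
        assert len(p.overlap) == 2
        assert p.agreement == pytest.approx(0.5)
        assert p.sensitivity == pytest.approx(2 / 3)
        assert p.ppv == pytest.approx(2 / 3)

    def test_both_empty_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            partition([], [])

    def test_duplicate_keys_rejected(self):
        v = _variants_from_keys([1])[0]
        with pytest.raises(ValueError, match="duplicate"):
            partition([v, v], [])

    def test_against_brute_force_sets(self, rng):
        ff = _random_variants(rng, 1000)
        ffpe = _random_variants(rng, 1000)
        p = partition(ff, ffpe)
        ff_keys = {v.key for v in ff}
        ffpe_keys = {v.key for v in ffpe}
        assert {v.key for v in p.overlap} == ff_keys & ffpe_keys
        assert {v.key for v in p.ff_unique} == ff_keys - ffpe_keys
        assert {v.key for v in p.ffpe_unique} == ffpe_keys - ff_keys
        assert p.agreement == len(ff_keys & ffpe_keys) / len(ff_keys | ffpe_keys)

    def test_count_conservation(self, rng):
        ff = _random_variants(rng, 400)
        ffpe = _random_variants(rng, 400)
        p = partition(ff, ffpe)
        assert p.n_ff + p.n_ffpe - len(p.overlap) == p.n_union
        assert p.n_ff == len(ff) and p.n_ffpe == len(ffpe)


class TestCombineCallers:
    def test_single_callset_identity(self, rng):
        cs = _random_variants(rng, 50)
        assert combine_callers([cs]) == sorted(cs, key=lambda v: v.key)

    def test_disjoint_empty(self):
        a = _variants_from_keys([0, 1])
        b = _variants_from_keys([5, 6])
        assert combine_callers([a, b]) == []

    def test_planted_common_core(self, rng):
        core = _variants_from_keys(range(40))
        sets = []
        for offset in (100, 200, 300):
            extra = _variants_from_keys(range(offset, offset + 60))
            sets.append(core + extra)
        combined = combine_callers(sets)
        assert {v.key for v in combined} == {v.key for v in core}

    def test_associative(self, rng):
        a, b, c = (_random_variants(rng, 120) for _ in range(3))
        assert combine_callers([combine_callers([a, b]), c]) == \
            combine_callers([a, b, c])

    def test_evidence_from_first_callset(self):
        a = _variants_from_keys([1], depth=100, alt=50)
        b = _variants_from_keys([1], depth=60, alt=10)
        assert combine_callers([a, b])[0].depth == 100


class TestStratify:
    def test_whole_genome_stratum_equals_global(self, rng):
        ff = _random_variants(rng, 200)
        ffpe = _random_variants(rng, 200)
        p = partition(ff, ffpe)
        whole = GenomicRegionSet("all", [("1", 0, 10**9)])
        strata = stratify_by_region(p, [whole])
        assert strata["all"].summary() == p.summary()
        assert strata["unstratified"] is None

    def test_boundary_convention(self):
        # interval (0,100) covers 1-based 1..100; (100,200) covers 101..200
        v100 = _variants_from_keys([9])  # pos = 100
        assert v100[0].pos == 100
        inside = GenomicRegionSet("in", [("1", 0, 100)])
        outside = GenomicRegionSet("out", [("1", 100, 200)])
        p = partition(v100, v100)
        res = stratify_by_region(p, [inside, outside])
        assert res["in"] is not None and len(res["in"].overlap) == 1
        assert res["out"] is None

    def test_region_dependent_concordance(self):
        """High-AF variants planted inside stratum A agree; low-AF outside don't."""
        cfg = SimulationConfig(seed=13, n_variants=1500,
                               chrom_lengths={"1": 40_000_000}, cna_segments=[],
                               subclone_fraction=0.0)
        truth = simulate_truth(cfg)
        df = truth.variants
        inside = df["pos"] <= 20_000_000
        df.loc[~inside, ["true_af_ff", "true_af_ffpe"]] = \
            df.loc[~inside, ["true_af_ff", "true_af_ffpe"]] * 0.12
        ff, ffpe = sample_observed_callsets(truth, cfg)
        p = partition(ff, ffpe)
        stratum_a = GenomicRegionSet("A", [("1", 0, 20_000_000)])
        res = stratify_by_region(p, [stratum_a])
        assert res["A"].agreement > res["unstratified"].agreement

    def test_variant_lists_are_disjoint_and_cover_union(self, rng):
        ff = _random_variants(rng, 300)
        ffpe = _random_variants(rng, 300)
        p = partition(ff, ffpe)
        keys = [{v.key for v in lst}
                for lst in (p.ff_unique, p.ffpe_unique, p.overlap)]
        assert not (keys[0] & keys[1] or keys[0] & keys[2] or keys[1] & keys[2])
        assert keys[0] | keys[1] | keys[2] == \
            {v.key for v in ff} | {v.key for v in ffpe}


class TestAfSweep:
    def test_threshold_zero_equals_partition(self, rng):
        ff = _random_variants(rng, 200)
        ffpe = _random_variants(rng, 200)
        sweep = af_sweep(ff, ffpe, [0.0])
        assert sweep.loc[0, "agreement"] == partition(ff, ffpe).agreement

    def test_above_max_af_undefined(self):
        ff = _variants_from_keys([1], depth=100, alt=10)
        sweep = af_sweep(ff, ff, [0.5])
        assert np.isnan(sweep.loc[0, "agreement"])

    def test_matches_brute_force(self, rng):
        ff = _random_variants(rng, 500)
        ffpe = _random_variants(rng, 500)
        thresholds = [0.0, 0.1, 0.3, 0.6]
        sweep = af_sweep(ff, ffpe, thresholds)
        for i, t in enumerate(thresholds):
            ff_k = {v.key for v in ff if v.alt_count / v.depth >= t}
            ffpe_k = {v.key for v in ffpe if v.alt_count / v.depth >= t}
            expected = len(ff_k & ffpe_k) / len(ff_k | ffpe_k)
            assert sweep.loc[i, "agreement"] == pytest.approx(expected)

    def test_undefined_af_rejected(self):
        v = VariantRecord("1", 5, "C", "T")
        with pytest.raises(ValueError, match="undefined AF"):
            af_sweep([v], [v], [0.0])


class TestDetectionPower:
    def test_edge_cases(self):
        assert detection_power(100, 0.0, 1) == 0.0
        assert detection_power(100, 0.3, 0) == 1.0
        assert detection_power(0, 0.5, 1) == 0.0

    def test_against_brute_force_summation(self, rng):
        for _ in range(200):
            depth = int(rng.integers(0, 201))
            af = float(rng.random())
            k = int(rng.integers(0, 8))
            expected = sum(
                math.comb(depth, j) * af**j * (1 - af) ** (depth - j)
                for j in range(k, depth + 1)
            )
            assert detection_power(depth, af, k) == pytest.approx(expected,
                                                                  abs=1e-10)

    def test_study_threshold_point(self):
        expected = sum(math.comb(70, j) * 0.067**j * 0.933**(70 - j)
                       for j in range(3, 71))
        assert detection_power(70, 0.067, 3) == pytest.approx(expected,
                                                              abs=1e-12)


class TestMinDetectableAf:
    @pytest.mark.parametrize("depth,k,target", [(70, 3, 0.9), (120, 3, 0.8),
                                                (40, 2, 0.95)])
    def test_bracketing_definition(self, depth, k, target):
        af = min_detectable_af(depth, k, target)
        assert detection_power(depth, af, k) >= target
        assert detection_power(depth, af - 1e-4, k) < target

    def test_monotone_in_depth(self, rng):
        for _ in range(50):
            depth = int(rng.integers(10, 150))
            k = int(rng.integers(1, 5))
            target = float(rng.uniform(0.5, 0.99))
            assert min_detectable_af(2 * depth, k, target) <= \
                min_detectable_af(depth, k, target)

    def test_depth_equals_required_reads_limit(self):
        assert min_detectable_af(3, 3, 0.999) == pytest.approx(1.0, abs=5e-4)

    def test_unattainable_raises(self):
        with pytest.raises(ValueError, match="no AF"):
            min_detectable_af(2, 3, 0.9)


class TestPowerFilter:
    def _pair(self, d_ff, a_ff, d_ffpe, a_ffpe, pos=100):
        ff = [VariantRecord("1", pos, "C", "T", depth=d_ff, alt_count=a_ff)]
        ffpe = [VariantRecord("1", pos, "C", "T", depth=d_ffpe, alt_count=a_ffpe)]
        return ff, ffpe

    def test_kept_when_af_condition_met_in_one_sample(self):
        ff, ffpe = self._pair(100, 10, 100, 0)
        kept_ff, _, _ = power_filter(ff, ffpe)
        assert len(kept_ff) == 1

    def test_dropped_on_low_depth_regardless_of_af(self):
        ff, ffpe = self._pair(50, 25, 100, 50)
        with pytest.raises(ValueError, match="empty"):
            power_filter(ff, ffpe)  # sole variant dropped -> empty partition

    def test_strict_inequalities(self):
        # depth exactly 70 fails the "> 70" rule; af exactly 0.067 fails "> 0.067"
        ff, ffpe = self._pair(70, 35, 100, 50)
        with pytest.raises(ValueError, match="empty"):
            power_filter(ff, ffpe)
        ff2 = [VariantRecord("1", 1, "C", "T", depth=1000, alt_count=67)]
        ffpe2 = [VariantRecord("1", 1, "C", "T", depth=1000, alt_count=67)]
        with pytest.raises(ValueError, match="empty"):
            power_filter(ff2, ffpe2)

    def test_missing_cross_sample_depth_errors_with_keys(self):
        ff = [VariantRecord("1", 100, "C", "T", depth=100, alt_count=30)]
        with pytest.raises(ValueError, match="lack cross-sample depth"):
            power_filter(ff, [])

    def test_coverage_lookup_resolves_uncalled_side(self):
        ff = [VariantRecord("1", 150, "C", "T", depth=100, alt_count=30)]
        cov = [CoverageBin("1", 0, 1000, 90.0)]
        kept_ff, kept_ffpe, part = power_filter(ff, [], ffpe_coverage=cov)
        assert len(kept_ff) == 1 and kept_ffpe == []
        low_cov = [CoverageBin("1", 0, 1000, 60.0)]
        with pytest.raises(ValueError, match="empty"):
            power_filter(ff, [], ffpe_coverage=low_cov)

    def test_survivors_subset_and_idempotent(self, rng):
        ff = _random_variants(rng, 300)
        ffpe = _random_variants(rng, 300)
        cov = [CoverageBin("1", 0, 10**6, 100.0)]
        f1, p1, _ = power_filter(ff, ffpe, ff_coverage=cov, ffpe_coverage=cov)
        assert set(v.key for v in f1) <= set(v.key for v in ff)
        f2, p2, _ = power_filter(f1, p1, ff_coverage=cov, ffpe_coverage=cov)
        assert (f1, p1) == (f2, p2)

    def test_filter_improves_simulated_agreement(self):
        """Power filtering raises FF-FFPE agreement in nearly all replicates."""
        hits = 0
        for seed in range(100):
            cfg = SimulationConfig(seed=seed, n_variants=600,
                                   chrom_lengths={"1": 30_000_000},
                                   cna_segments=[])
            truth = simulate_truth(cfg)
            ff, ffpe = sample_observed_callsets(truth, cfg)
            pre = partition(ff, ffpe).agreement
            cov_ff = simulate_coverage(cfg, "FF")
            cov_ffpe = simulate_coverage(cfg, "FFPE")
            _, _, post = power_filter(ff, ffpe, PowerFilterConfig(),
                                      cov_ff, cov_ffpe)
            hits += post.agreement > pre
        assert hits >= 95
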