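"""Concordance, consensus, discordance histogram, coverage and sensitivity:
hand-computed fixtures plus structural invariants."""

import numpy as np
import pandas as pd
import pytest

from ffpemeth.bsio import GenomicSite, Region
from ffpemeth.concord import (
    build_consensus,
    coverage_proportion_curve,
    discordance_histogram,
    intersect_profiles,
    select_validation_targets,
    sensitivity_by_coverage,
)
from ffpemeth.methcall import CallParams, MethCall, MethProfile


def site(pos, strand="+"):
    return GenomicSite("chrT", pos, strand)


def profile(spec, label="p"):
    """Build a profile from {pos: (n_meth, n_unmeth)} or {pos: proportion@cov}."""
    calls = {}
    for pos, val in spec.items():
        s = site(pos) if isinstance(pos, int) else pos
        n_meth, n_unmeth = val
        calls[s] = MethCall(s, n_meth=n_meth, n_unmeth=n_unmeth)
    return MethProfile(calls, params=CallParams(), label=label)


def from_proportions(spec, cov=10, label="p"):
    """{pos: proportion} -> profile at the given coverage."""
    return profile(
        {pos: (round(p * cov), cov - round(p * cov)) for pos, p in spec.items()},
        label=label,
    )


class TestIntersect:
    def test_identical_profiles_fully_concordant(self):
        a = from_proportions({i: 0.9 for i in range(10)})
        summary, paired = intersect_profiles(a, a)
        assert summary.n_intersect == 10
        assert summary.concordant_fraction == 1.0
        assert summary.n_discordant == 0

    def test_hand_computed_example(self):
        # A: s1 hypo, s2 hyper, s3 intermediate; B: s1 hypo, s2 intermediate, s4 hyper
        a = from_proportions({1: 0.1, 2: 0.9, 3: 0.5}, label="A")
        b = from_proportions({1: 0.1, 2: 0.5, 4: 0.9}, label="B")
        summary, paired = intersect_profiles(a, b)
        assert (summary.n_a, summary.n_b) == (3, 3)
        assert summary.n_intersect == 2
        assert summary.n_concordant == 1
        assert summary.n_discordant == 1
        assert summary.overlap_fraction_a == pytest.approx(2 / 3)

    def test_symmetry(self, small_profiles):
        a, b = small_profiles
        sa, _ = intersect_profiles(a, b)
        sb, _ = intersect_profiles(b, a)
        assert sa.n_intersect == sb.n_intersect
        assert sa.n_concordant == sb.n_concordant

    def test_simulated_null_pair_highly_concordant(self, small_sim):
        # same truth, no bowing difference at work on concordance
        from ffpemeth.methcall import call_methylation
        cfg, reference, targets, _, ffpe, ff = small_sim
        pa = call_methylation(ffpe, reference, targets, CallParams())
        pb = call_methylation(ff, reference, targets, CallParams())
        summary, _ = intersect_profiles(pa, pb)
        assert summary.n_intersect > 1000
        assert summary.concordant_fraction > 0.6  # mixture puts mass near thresholds


@pytest.fixture
def small_profiles():
    rng = np.random.default_rng(8)
    a = {}
    b = {}
    for i in range(50):
        a[i] = float(rng.random())
        if rng.random() < 0.8:
            b[i] = float(rng.random())
    return from_proportions(a, label="A"), from_proportions(b, label="B")


class TestConsensus:
    def test_identical_replicates_no_off(self):
        a = from_proportions({1: 0.1, 2: 0.9}, cov=12)
        cons = build_consensus(a, a, min_cov=10)
        assert cons.n_off == 0
        assert cons.category[site(1)] == "hypo"

    def test_disagreement_marked_off(self):
        a = from_proportions({1: 0.1}, cov=12)
        b = from_proportions({1: 0.9}, cov=12)
        cons = build_consensus(a, b, min_cov=10)
        assert cons.category[site(1)] == "off"
        assert cons.without_off() == {}

    def test_coverage_cutoff_applies_to_both(self):
        a = from_proportions({1: 0.1}, cov=12)
        b = from_proportions({1: 0.1}, cov=9)
        assert len(build_consensus(a, b, min_cov=10)) == 0
        assert len(build_consensus(a, b, min_cov=9)) == 1

    def test_min_cov_below_one_rejected(self):
        a = from_proportions({1: 0.1})
        with pytest.raises(ValueError):
            build_consensus(a, a, min_cov=0)

    def test_consensus_idempotence(self, small_profiles):
        a, _ = small_profiles
        cons = build_consensus(a, a, min_cov=1)
        assert cons.n_off == 0
        for s, cat in cons.category.items():
            assert cat == a[s].category

    def test_simulated_replicates_modest_off_fraction(self, small_sim):
        from ffpemeth import simdata
        from ffpemeth.methcall import call_methylation
        cfg, reference, targets, truth, _, _ = small_sim
        cfg2 = simdata.with_overrides(cfg, mean_coverage=30)
        r1 = simdata.simulate_reads(reference, targets, truth, cfg2, "r1", "FF", rng=cfg2.rng(11))
        r2 = simdata.simulate_reads(reference, targets, truth, cfg2, "r2", "FF", rng=cfg2.rng(12))
        p1 = call_methylation(r1, reference, targets, CallParams())
        p2 = call_methylation(r2, reference, targets, CallParams())
        cons = build_consensus(p1, p2, min_cov=10)
        assert len(cons) > 200
        assert cons.n_off / len(cons) < 0.35  # threshold noise near category borders


class TestDiscordanceHistogram:
    def _paired(self, pairs):
        rows = []
        for pa, pb in pairs:
            from ffpemeth.methcall import categorize
            rows.append(("chrT", len(rows), "+", 10, pa, categorize(pa),
                         10, pb, categorize(pb), categorize(pa) == categorize(pb)))
        return pd.DataFrame(rows, columns=[
            "chrom", "pos", "strand", "coverage_a", "proportion_a", "category_a",
            "coverage_b", "proportion_b", "category_b", "concordant"])

    def test_extreme_divergence_in_last_bin(self):
        hist = discordance_histogram(self._paired([(1.0, 0.0)]))
        assert hist["count"].sum() == 1
        assert hist.loc[hist["count"] == 1, "bin_end"].iloc[0] == pytest.approx(1.0)

    def test_no_discordant_sites_all_zero(self):
        hist = discordance_histogram(self._paired([(0.9, 0.95), (0.1, 0.05)]))
        assert hist["count"].sum() == 0
        assert len(hist) == 100

    def test_hand_binned_six_site_example(self):
        # d values: -1, -0.5, 0.3, 1, 1, 0.31 (all pairs discordant)
        pairs = [(0.0, 1.0), (0.1, 0.6), (0.9, 0.6), (1.0, 0.0), (1.0, 0.0), (0.81, 0.5)]
        paired = self._paired(pairs)
        assert not paired["concordant"].any()
        hist = discordance_histogram(paired)
        by_start = {round(r.bin_start, 2): r.count for r in hist.itertuples()}
        assert by_start[-1.0] == 1      # d = -1 in [-1, -0.98)
        assert by_start[-0.5] == 1      # d = -0.5 in [-0.5, -0.48)
        assert by_start[0.3] == 2       # 0.30 and 0.31 share [0.30, 0.32)
        assert by_start[0.98] == 2      # the closed final bin holds d = 1
        assert hist["count"].sum() == 6

    def test_mass_conservation(self, small_profiles):
        a, b = small_profiles
        summary, paired = intersect_profiles(a, b)
        hist = discordance_histogram(paired)
        assert hist["count"].sum() == summary.n_discordant


class TestCoverageCurve:
    def test_constant_coverage(self):
        prof = profile({i: (3, 2) for i in range(4)})  # all coverage 5
        curve = coverage_proportion_curve(prof)
        assert list(curve["fraction"]) == [1.0] * 5
        assert list(curve["min_coverage"]) == [1, 2, 3, 4, 5]

    def test_hand_computed_mixed_coverages(self):
        prof = profile({1: (1, 0), 2: (1, 1), 3: (5, 5)})  # coverages 1, 2, 10
        curve = coverage_proportion_curve(prof)
        frac = dict(zip(curve["min_coverage"], curve["fraction"]))
        assert frac[1] == 1.0
        assert frac[2] == pytest.approx(2 / 3)
        for c in range(3, 11):
            assert frac[c] == pytest.approx(1 / 3)

    def test_non_increasing(self, small_profiles):
        a, _ = small_profiles
        curve = coverage_proportion_curve(a)
        assert curve["fraction"].is_monotonic_decreasing

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            coverage_proportion_curve(MethProfile({}))


class TestSensitivity:
    def _gold(self, spec, min_cov=10):
        a = from_proportions(spec, cov=max(10, min_cov))
        return build_consensus(a, a, min_cov=min_cov)

    def test_identical_sample_perfect_sensitivity(self):
        gold = self._gold({1: 0.1, 2: 0.9, 3: 0.5})
        sample = from_proportions({1: 0.1, 2: 0.9, 3: 0.5}, cov=10)
        curve = sensitivity_by_coverage(gold, sample, max_cov=10)
        assert (curve.table["sensitivity"] == 1.0).all()

    def test_hand_computed_tp_fp_by_coverage(self):
        # gold: s1 hypo, s2 hyper; sample: s1 hypo @12x, s2 intermediate @4x
        gold = self._gold({1: 0.1, 2: 0.9})
        sample = profile({1: (1, 11), 2: (2, 2)})
        curve = sensitivity_by_coverage(gold, sample, max_cov=12)
        t = curve.table.set_index("min_coverage")
        assert (t.loc[1, "tp"], t.loc[1, "fp"]) == (1, 1)
        assert t.loc[1, "sensitivity"] == pytest.approx(0.5)
        assert (t.loc[5, "tp"], t.loc[5, "fp"]) == (1, 0)
        assert t.loc[5, "sensitivity"] == 1.0

    def test_off_sites_excluded_not_counted_fp(self):
        r1 = from_proportions({1: 0.1, 2: 0.1}, cov=10, label="r1")
        r2 = from_proportions({1: 0.1, 2: 0.9}, cov=10, label="r2")
        gold = build_consensus(r1, r2, min_cov=10)  # site 2 is 'off'
        sample = from_proportions({1: 0.1, 2: 0.9}, cov=10)
        curve = sensitivity_by_coverage(gold, sample, max_cov=5)
        assert (curve.table["tp"] == 1).all()
        assert (curve.table["fp"] == 0).all()

    def test_empty_gold_rejected(self):
        r1 = from_proportions({1: 0.1}, cov=10)
        r2 = from_proportions({1: 0.9}, cov=10)
        gold = build_consensus(r1, r2, min_cov=10)
        with pytest.raises(ValueError):
            sensitivity_by_coverage(gold, from_proportions({1: 0.1}))

    def test_adding_correct_call_never_decreases_sensitivity(self):
        gold = self._gold({i: 0.1 for i in range(6)})
        base = {1: (0, 12), 2: (11, 1), 3: (1, 11)}  # hypo TP, hyper FP, hypo TP
        s1 = profile(base)
        curve1 = sensitivity_by_coverage(gold, s1, max_cov=12)
        extended = dict(base)
        extended[4] = (0, 12)  # one more correct hypo call at 12x
        curve2 = sensitivity_by_coverage(gold, profile(extended), max_cov=12)
        j = curve1.table.merge(curve2.table, on="min_coverage", suffixes=("_1", "_2"))
        covered = j.dropna(subset=["sensitivity_1", "sensitivity_2"])
        assert (covered["sensitivity_2"] >= covered["sensitivity_1"] - 1e-12).all()

    def test_truth_sharing_fraction_recovered_at_plateau(self):
        # two samples sharing category truth at 60% of sites, deep coverage:
        # the plateau sits near the sharing fraction
        from ffpemeth import simdata
        from ffpemeth.methcall import call_methylation
        cfg = simdata.SimConfig(
            seed=77, reference_length=80_000, n_targets=8, target_size=2_500,
            cpg_period=10, mean_coverage=90, insert_mean_ff=250.0)
        reference, targets = simdata.simulate_reference(cfg)
        gold_truth = simdata.simulate_truth(reference, targets, cfg)
        sample_truth = simdata.derive_related_truth(gold_truth, 0.6, cfg, cfg.rng(5))
        r1 = simdata.simulate_reads(reference, targets, gold_truth, cfg, "r1", "FF", rng=cfg.rng(6))
        r2 = simdata.simulate_reads(reference, targets, gold_truth, cfg, "r2", "FF", rng=cfg.rng(7))
        sm = simdata.simulate_reads(reference, targets, sample_truth, cfg, "s", "FF", rng=cfg.rng(8))
        params = CallParams()
        gold = build_consensus(
            call_methylation(r1, reference, targets, params),
            call_methylation(r2, reference, targets, params),
            min_cov=10,
        )
        curve = sensitivity_by_coverage(
            gold, call_methylation(sm, reference, targets, params), max_cov=30)
        assert curve.plateau == pytest.approx(0.6, abs=0.05)


class TestValidationTargets:
    def _setup(self):
        """9 regions engineered so exactly 5 pass the selection filter."""
        regions = [Region("chrT", i * 100, i * 100 + 50) for i in range(9)]
        gold_spec = {}
        profs = {"S1": {}, "S2": {}}
        # regions 0..4 qualify: covered >=10x everywhere, gold non-'off'
        for i in range(5):
            pos = i * 100 + 10
            gold_spec[pos] = 0.1
            for lab in profs:
                profs[lab][pos] = (1, 11)  # hypo at 12x -> TP
        # region 5: one sample at 9x
        gold_spec[510] = 0.1
        profs["S1"][510] = (1, 11)
        profs["S2"][510] = (1, 8)  # 9x
        # region 6: site missing from S2
        gold_spec[610] = 0.1
        profs["S1"][610] = (1, 11)
        # region 7: gold 'off' at its only site (constructed below)
        # region 8: no gold site at all
        g1 = from_proportions(gold_spec, cov=12, label="g1")
        g2_spec = dict(gold_spec)
        g1_calls = dict(g1.calls)
        off_site = site(710)
        g1_calls[off_site] = MethCall(off_site, 1, 11)  # hypo in rep 1
        g2 = from_proportions(g2_spec, cov=12, label="g2")
        g2_calls = dict(g2.calls)
        g2_calls[off_site] = MethCall(off_site, 11, 1)  # hyper in rep 2
        gold = build_consensus(
            MethProfile(g1_calls, label="g1"), MethProfile(g2_calls, label="g2"),
            min_cov=10)
        profs["S1"][710] = (1, 11)
        profs["S2"][710] = (1, 11)
        profiles = {lab: profile(spec, label=lab) for lab, spec in profs.items()}
        return regions, profiles, {"CL": gold}

    def test_exactly_five_regions_selected(self):
        regions, profiles, golds = self._setup()
        out = select_validation_targets(regions, profiles, golds, min_cov=10)
        assert len(out) == 5
        assert set(out["start"]) == {0, 100, 200, 300, 400}
        assert (out["status"] == "TP").all()
        assert (out["sharing"] == "all").all()

    def test_nine_x_sample_excludes_region(self):
        regions, profiles, golds = self._setup()
        out = select_validation_targets(regions, profiles, golds, min_cov=10)
        assert 500 not in set(out["start"])

    def test_fp_annotation(self):
        regions, profiles, golds = self._setup()
        # flip both samples at region 0's site to hyper: gold says hypo -> FP
        for lab in profiles:
            profiles[lab].calls[site(10)] = MethCall(site(10), 11, 1)
        out = select_validation_targets(regions, profiles, golds, min_cov=10)
        assert out.loc[out["start"] == 0, "status"].iloc[0] == "FP"
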