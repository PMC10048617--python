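"""Match probabilities, hand LRs, and the semi-continuous replicate engine."""

import math

import numpy as np
import pytest

import dscspg as d
from dscspg.lr import SemiContinuousModel


def table(theta=0.0, **loci):
    return d.AlleleFrequencyTable(dict(loci), theta=theta, validate_sums=False)


class TestMatchProbability:
    def test_theta_zero_reduces_to_hardy_weinberg(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p_i, p_j = rng.uniform(0.01, 0.45, size=2)
            freqs = table(TH01={7.0: p_i, 8.0: p_j, 9.0: 1 - p_i - p_j})
            het = d.locus_match_probability((7.0, 8.0), freqs, "TH01")
            hom = d.locus_match_probability((7.0, 7.0), freqs, "TH01")
            assert het == pytest.approx(2 * p_i * p_j, rel=1e-12)
            assert hom == pytest.approx(p_i**2, rel=1e-12)

    def test_homozygote_certain_allele(self):
        freqs = table(TH01={7.0: 1.0})
        assert d.locus_match_probability((7.0, 7.0), freqs, "TH01") == 1.0

    def test_theta_corrected_heterozygote_value(self):
        # independent arithmetic: 2(θ+(1−θ)p_i)(θ+(1−θ)p_j)/((1+θ)(1+2θ))
        theta, p_i, p_j = 0.01, 0.1, 0.2
        expected = (
            2 * (theta + (1 - theta) * p_i) * (theta + (1 - theta) * p_j)
            / ((1 + theta) * (1 + 2 * theta))
        )
        freqs = table(theta=theta, TH01={7.0: p_i, 8.0: p_j, 9.0: 0.7})
        got = d.locus_match_probability((7.0, 8.0), freqs, "TH01")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.04401, abs=5e-5)

    def test_absent_locus_raises(self, freqs):
        with pytest.raises(KeyError):
            d.locus_match_probability((7.0, 8.0), freqs, "NOPE")


class TestSingleSourceLR:
    def test_single_het_locus_log10_two(self):
        freqs = table(TH01={7.0: 0.5, 8.0: 0.5})
        prof = d.ReferenceProfile("x", {"TH01": (7.0, 8.0)})
        res = d.single_source_profile_lr(prof, freqs)
        assert res.log10_lr_total == pytest.approx(math.log10(2.0))

    def test_21_heterozygous_loci_closed_form(self, panel):
        loci = {
            name: {7.0: 0.1, 8.0: 0.1, 9.0: 0.8} for name in panel.names
        }
        freqs = d.AlleleFrequencyTable(loci, theta=0.0)
        prof = d.ReferenceProfile("x", {n: (7.0, 8.0) for n in panel.names})
        res = d.single_source_profile_lr(prof, freqs)
        assert res.log10_lr_total == pytest.approx(21 * math.log10(50.0), rel=1e-12)
        assert res.log10_lr_total == pytest.approx(
            sum(res.per_locus_log10.values()), abs=1e-9
        )

    def test_theta_shrinks_the_lr(self, panel):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.dirichlet([2.0] * 5)
            loci = {n: {float(6 + i): float(p[i]) for i in range(5)}
                    for n in panel.names[:8]}
            f0 = d.AlleleFrequencyTable(dict(loci), theta=0.0)
            f1 = d.AlleleFrequencyTable(dict(loci), theta=0.03)
            prof = d.sample_reference_profiles(f0, 1, int(rng.integers(1 << 30)))[0]
            lr0 = d.single_source_profile_lr(prof, f0).log10_lr_total
            lr1 = d.single_source_profile_lr(prof, f1).log10_lr_total
            assert lr1 < lr0

    def test_missing_locus_raises_unless_partial(self, freqs):
        prof = d.ReferenceProfile("x", {freqs.loci[0]: (7.0, 8.0)})
        with pytest.raises(KeyError):
            d.single_source_profile_lr(prof, freqs)
        res = d.single_source_profile_lr(prof, freqs, partial=True)
        assert len(res.per_locus_log10) == 1


class TestSemiContinuousEngine:
    def test_clean_profile_collapses_to_hand_lr(self, panel, freqs, donors):
        donor = donors[0]
        epg = d.clean_epg_from_reference(donor, panel)
        hp = d.Hypothesis([donor], 0, theta=freqs.theta)
        hd = d.Hypothesis([], 1, theta=freqs.theta)
        res = SemiContinuousModel([epg], hp, hd, freqs, fixed_dropout=0.0,
                                  drop_in_rate=0.0).fit()
        hand = d.single_source_profile_lr(donor, freqs)
        assert res.log10_lr_total == pytest.approx(hand.log10_lr_total, abs=1e-9)

    def test_duplicate_replicate_leaves_lr_unchanged(self, panel, freqs, donors):
        donor = donors[1]
        epg = d.clean_epg_from_reference(donor, panel)
        hp = d.Hypothesis([donor], 0, theta=freqs.theta)
        hd = d.Hypothesis([], 1, theta=freqs.theta)
        one = SemiContinuousModel([epg], hp, hd, freqs, fixed_dropout=0.0,
                                  drop_in_rate=0.0).fit()
        two = SemiContinuousModel([epg, epg], hp, hd, freqs, fixed_dropout=0.0,
                                  drop_in_rate=0.0).fit()
        assert two.log10_lr_total == pytest.approx(one.log10_lr_total, abs=1e-9)

    def test_single_locus_dropout_brute_force_oracle(self):
        # donor {11,12}, only 11 observed, d fixed 0.3, c = 0, theta = 0
        p_a = p_b = 0.1
        freqs = table(D16S539={11.0: p_a, 12.0: p_b, 13.0: 0.8})
        donor = d.ReferenceProfile("poi", {"D16S539": (11.0, 12.0)})
        epg = d.Epg("s", {"D16S539": [d.Peak(11.0, 500.0, 256.0)]}, at_applied=True)
        dval = 0.3
        hp = d.Hypothesis([donor], 0, theta=0.0)
        hd = d.Hypothesis([], 1, theta=0.0)
        res = SemiContinuousModel([epg], hp, hd, freqs, fixed_dropout=dval,
                                  drop_in_rate=0.0).fit()
        # oracle: enumerate all defence genotypes over {11, 12, Q}
        p_q = 1.0 - p_a - p_b
        lp = (1 - dval) * dval
        ld = (
            p_a**2 * (1 - dval**2)            # {11,11}
            + 2 * p_a * p_b * (1 - dval) * dval   # {11,12}
            + 2 * p_a * p_q * (1 - dval) * dval   # {11,Q}
        )
        assert res.log10_lr_total == pytest.approx(math.log10(lp / ld), abs=1e-9)

    def test_theta_engine_reproduces_match_probability(self, panel, freqs, donors):
        # single known contributor vs one unknown, d=0, c=0: per-locus LR
        # equals the closed-form theta-corrected match probability
        donor = donors[2]
        epg = d.clean_epg_from_reference(donor, panel)
        hp = d.Hypothesis([donor], 0, theta=freqs.theta)
        hd = d.Hypothesis([], 1, theta=freqs.theta)
        res = SemiContinuousModel([epg], hp, hd, freqs, fixed_dropout=0.0,
                                  drop_in_rate=0.0).fit()
        for locus in freqs.loci:
            expected = -math.log10(
                d.locus_match_probability(donor.genotype(locus), freqs, locus)
            )
            assert res.per_locus_log10[locus] == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_locus_and_replicate_order(self, panel, freqs, donors):
        cfg = d.SimulationConfig()
        at = d.AnalyticalThresholds()
        donor = donors[3]
        reps = []
        for seed in (41, 42):
            epg = d.simulate_subsample([(donor, 1)], cfg, panel, seed, freqs=freqs)
            reps.append(d.apply_analytical_threshold(epg, at, panel))
        hp = d.Hypothesis([donor], 0, theta=freqs.theta)
        hd = d.Hypothesis([], 1, theta=freqs.theta)
        a = SemiContinuousModel(reps, hp, hd, freqs).fit()
        b = SemiContinuousModel(reps[::-1], hp, hd, freqs,
                                loci=list(reversed(freqs.loci))).fit()
        assert a.log10_lr_total == pytest.approx(b.log10_lr_total, abs=1e-9)

    def test_complementary_dropout_replicates_gain(self):
        # sister alleles recovered in different replicates support the donor
        # more strongly together than either replicate alone
        freqs = table(D16S539={11.0: 0.1, 12.0: 0.1, 13.0: 0.8})
        donor = d.ReferenceProfile("poi", {"D16S539": (11.0, 12.0)})
        rep_a = d.Epg("r1", {"D16S539": [d.Peak(11.0, 400.0, 256.0)]}, at_applied=True)
        rep_b = d.Epg("r2", {"D16S539": [d.Peak(12.0, 380.0, 260.0)]}, at_applied=True)
        hp = d.Hypothesis([donor], 0, theta=0.0)
        hd = d.Hypothesis([], 1, theta=0.0)

        def lr(reps):
            return SemiContinuousModel(reps, hp, hd, freqs,
                                       drop_in_rate=0.001).fit().log10_lr_total

        joint = lr([rep_a, rep_b])
        assert joint > lr([rep_a])
        assert joint > lr([rep_b])

    def test_noc_guard(self, freqs, donors):
        epg = d.Epg("s", {}, at_applied=True)
        hp = d.Hypothesis(donors[:2], 2, theta=freqs.theta)
        hd = d.Hypothesis([], 4, theta=freqs.theta)
        with pytest.raises(ValueError, match="NOC"):
            SemiContinuousModel([epg], hp, hd, freqs)

    def test_mean_lr_over_defence_draws_is_one(self):
        # Turing expectation E[LR | Hd] = 1 at a single locus with the
        # engine evaluated at the generating drop-out and drop-in rates
        freqs = table(TH01={7.0: 0.3, 8.0: 0.3, 9.0: 0.4})
        alleles = [7.0, 8.0, 9.0]
        p = [0.3, 0.3, 0.4]
        dval, c = 0.35, 0.05
        rng = np.random.default_rng(17)
        poi = d.ReferenceProfile("poi", {"TH01": (7.0, 8.0)})
        hp = d.Hypothesis([poi], 0, theta=0.0)
        hd = d.Hypothesis([], 1, theta=0.0)
        lrs = []
        for _ in range(2000):
            geno = rng.choice(alleles, size=2, p=p)
            present = set()
            for a in geno:
                if rng.random() > dval:
                    present.add(float(a))
            if rng.random() < c:
                present.add(float(rng.choice(alleles, p=p)))
            peaks = [d.Peak(a, 300.0, 150.0 + 4 * a) for a in sorted(present)]
            epg = d.Epg("s", {"TH01": peaks}, at_applied=True)
            res = SemiContinuousModel([epg], hp, hd, freqs, fixed_dropout=dval,
                                      drop_in_rate=c).fit()
            lrs.append(10.0 ** res.log10_lr_total)
        lrs = np.array(lrs)
        se = lrs.std(ddof=1) / math.sqrt(len(lrs))
        assert abs(lrs.mean() - 1.0) < 3 * se + 0.01
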