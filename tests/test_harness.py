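"""Validation experiment designs and database search."""

import math

import pandas as pd
import pytest

import dscspg as d


def noise_free_config():
    return d.SimulationConfig(cv_peak=0.05, lsae_sd=0.0, drop_in_rate=0.0)


class TestDatabaseSearch:
    def test_true_donor_entry_matches_direct_computation(self, panel, freqs,
                                                         donors):
        epg = d.clean_epg_from_reference(donors[0], panel)
        results = d.database_search([epg], donors[:5], freqs)
        by_id = {r.hp.known_contributors[0].donor_id: r for r in results}
        direct = d.SemiContinuousModel(
            [epg],
            d.Hypothesis([donors[0]], 0, theta=freqs.theta),
            d.Hypothesis([], 1, theta=freqs.theta),
            freqs,
        ).fit()
        assert by_id["DONOR000"].log10_lr_total == pytest.approx(
            direct.log10_lr_total, abs=1e-9
        )

    def test_results_ordered_by_donor_id(self, panel, freqs, donors):
        epg = d.clean_epg_from_reference(donors[0], panel)
        results = d.database_search([epg], list(reversed(donors[:5])), freqs)
        ids = [r.hp.known_contributors[0].donor_id for r in results]
        assert ids == sorted(ids)

    def test_empty_database_rejected(self, panel, freqs, donors):
        epg = d.clean_epg_from_reference(donors[0], panel)
        with pytest.raises(ValueError):
            d.database_search([epg], [], freqs)

    def test_non_contributors_stay_below_strong_threshold(self, panel, freqs):
        database = d.sample_reference_profiles(freqs, 40, 555)
        donor = d.sample_reference_profiles(freqs, 1, 556)[0]
        donor.donor_id = "TRUE"
        epg = d.clean_epg_from_reference(donor, panel)
        results = d.database_search([epg], database, freqs)
        assert all(r.log10_lr_total < d.LOG_LR_STRONG for r in results)


class TestSensitivitySpecificity:
    def test_noise_free_config_fully_inclusionary(self, panel, freqs):
        rep = d.sensitivity_specificity_experiment(
            noise_free_config(), n_1cell=6, n_2cell_ss=4, n_2cell_mix=3,
            db_size=10, seed=5, panel=panel, freqs=freqs,
            n_replicate_groups=3, db_subsample_stride=5,
        )
        df = rep.frame()
        contrib = df[df["is_contributor"]]
        assert (contrib["log10_lr"] > d.LOG_LR_INCLUSION).all()
        assert rep.aggregates["false_positives_gt0"] == 0
        assert rep.aggregates["false_positives_ge6"] == 0

    def test_reports_reproducible_and_recomputable(self, panel, freqs, cfg,
                                                   tmp_path):
        kwargs = dict(n_1cell=5, n_2cell_ss=4, n_2cell_mix=2, db_size=8,
                      seed=9, panel=panel, freqs=freqs, n_replicate_groups=2,
                      db_subsample_stride=6)
        a = d.sensitivity_specificity_experiment(cfg, **kwargs)
        b = d.sensitivity_specificity_experiment(cfg, **kwargs)
        pd.testing.assert_frame_equal(a.frame(), b.frame())
        assert a.aggregates == a.recompute_aggregates()
        a.write(tmp_path)
        assert (tmp_path / "sensitivity_specificity_records.csv").exists()
        assert (tmp_path / "sensitivity_specificity_manifest.yaml").exists()

    def test_every_record_carries_a_seed(self, panel, freqs, cfg):
        rep = d.sensitivity_specificity_experiment(
            cfg, n_1cell=4, n_2cell_ss=2, n_2cell_mix=2, db_size=5, seed=2,
            panel=panel, freqs=freqs, n_replicate_groups=2,
            db_subsample_stride=10,
        )
        assert all("seed" in r and r["seed"] is not None for r in rep.records)

    def test_replicate_lr_dominates_member_median(self, panel, freqs, cfg):
        rep = d.sensitivity_specificity_experiment(
            cfg, n_1cell=24, n_2cell_ss=12, n_2cell_mix=2, db_size=5,
            seed=11, panel=panel, freqs=freqs, n_replicate_groups=8,
            db_subsample_stride=100,
        )
        df = rep.frame()
        reps = df[df["model"] == "replicate"]
        subs = df[(df["model"] == "subsample") & (df["noc"] == 1)]
        wins = total = 0
        for _, row in reps.iterrows():
            members = subs[subs["donor"] == row["donor"]]["log10_lr"]
            if len(members) == 0:
                continue
            total += 1
            if row["log10_lr"] >= members.median():
                wins += 1
        assert total >= 4
        assert wins / total >= 0.9


class TestNOCMisspecification:
    def test_clean_profiles_stable_under_overstatement(self, panel, freqs):
        rep = d.noc_misspecification_experiment(
            noise_free_config(), n_single_source=6, n_minimix=2, seed=3,
            panel=panel, freqs=freqs,
        )
        df = rep.frame()
        stated = df[df["class"] == "single_source_stated"].set_index("sample_id")
        over = df[df["class"] == "single_source_overstated"].set_index("sample_id")
        for sid in stated.index:
            assert abs(stated.loc[sid, "log10_lr"] - over.loc[sid, "log10_lr"]) < 1.0

    def test_minimix_at_n1_often_excludes_true_donor(self, panel, freqs, cfg):
        rep = d.noc_misspecification_experiment(
            cfg, n_single_source=2, n_minimix=20, seed=7, panel=panel,
            freqs=freqs,
        )
        df = rep.frame()
        under = df[df["class"] == "minimix_understated"]
        excluded = (under["log10_lr"] <= 0).mean()
        assert excluded > 0.5


class TestReplicateMisclassification:
    def test_intruder_quality_drives_impact(self, panel, freqs, cfg):
        rep = d.replicate_misclassification_experiment(
            cfg, seed=21, panel=panel, freqs=freqs,
            intruder_spec=[
                {"donor": 1, "cells": 1, "label": "poor"},
                {"donor": 1, "cells": 5, "label": "high_quality"},
            ],
        )
        df = rep.frame().set_index("model")
        base = rep.aggregates["baseline_log10_lr"]
        with_intruders = rep.frame()
        poor = with_intruders[with_intruders["intruder"] == "poor"].iloc[0]
        good = with_intruders[with_intruders["intruder"] == "high_quality"].iloc[0]
        # a near-empty wrong-donor profile barely moves the replicate LR; a
        # high-quality wrong-donor profile collapses it
        assert abs(poor["log10_lr"] - base) < abs(good["log10_lr"] - base)
        assert good["log10_lr"] <= 0.0

    def test_duplicate_member_acts_as_extra_replicate(self, panel, freqs, cfg):
        rep = d.replicate_misclassification_experiment(
            cfg, seed=23, panel=panel, freqs=freqs, engine="semi_continuous",
            group_spec={"n_replicates": 3, "cells": 2},
            intruder_spec=[{"donor": 0, "cells": 2, "label": "same_donor"}],
        )
        base = rep.aggregates["baseline_log10_lr"]
        row = rep.frame()
        extra = row[row["intruder"] == "same_donor"].iloc[0]
        assert extra["log10_lr"] >= base - 1.0


class TestMixtureDeconvolution:
    def test_ceiling_property_and_bulk_refusal(self, panel, freqs):
        rep = d.mixture_deconvolution_experiment(
            noise_free_config(), noc_list=[2, 5], seed=13, panel=panel,
            freqs=freqs, n_subsamples_per_donor=2,
        )
        df = rep.frame()
        for (sid, donor), grp in df.groupby(["sample_id", "donor"]):
            by_model = grp.set_index("model")
            ceiling = by_model.loc["reference_ceiling", "log10_lr"]
            dscs = by_model.loc["dscs_replicate", "log10_lr"]
            assert dscs <= ceiling + 0.1
            # noise-free subsamples recover the full reference LR
            assert dscs == pytest.approx(ceiling, abs=0.1)
        bulk5 = df[(df["class"] == "mix5") & (df["model"] == "bulk_standard")]
        assert (bulk5["status"] == "not supported").all()
        assert bulk5["log10_lr"].isna().all()
        dscs5 = df[(df["class"] == "mix5") & (df["model"] == "dscs_replicate")]
        assert (dscs5["log10_lr"] > 0).all()


class TestPerturbationRobustness:
    def test_quantitative_lr_stable_under_insults(self, panel, freqs):
        rep = d.perturbation_robustness_experiment(seed=3, panel=panel,
                                                   freqs=freqs)
        assert rep.aggregates["max_abs_delta"] < 1.0
        df = rep.frame()
        assert set(df["model"]) == {"original", "degraded", "inhibited", "drop_in"}
        assert (df["status"] == "ok").all()
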