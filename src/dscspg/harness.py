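"""Validation experiment designs.

End-to-end experiments on synthetic few-cell subsamples: sensitivity and
specificity against a non-contributor database, the impact of over- and
under-stating the number of contributors, replicate analysis with
intentionally misclassified subsamples, and mixture deconvolution by
repeated single-cell subsampling compared against the single-source
reference ceiling log10(1/RMP).

Every experiment returns an :class:`ExperimentReport` whose aggregate
rates are recomputed from the per-sample records at write time, and whose
records each carry the seed that generated them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lr import (
    Hypothesis,
    LRResult,
    QuantitativeModel,
    SemiContinuousModel,
    single_source_profile_lr,
    database_search,
)
from .panel import LocusPanel, default_panel
from .profiles import (
    AlleleFrequencyTable,
    AnalyticalThresholds,
    Epg,
    ReferenceProfile,
    apply_analytical_threshold,
    filter_unmodeled_stutter,
)
from .simulate import (
    SimulationConfig,
    child_seeds,
    sample_reference_profiles,
    simulate_subsample,
    synthetic_frequencies,
)
from .stutter import STUTTER_OFFSETS

#: Reporting thresholds on log10 LR: inclusionary, and the level above
#: which non-contributor matches were never observed.
LOG_LR_INCLUSION = 0.0
LOG_LR_STRONG = 6.0


@dataclass
class ExperimentReport:
    """Per-sample records plus recomputable aggregate rates."""

    design: str
    records: list[dict] = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)
    seed: int = 0
    config: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def recompute_aggregates(self) -> dict:
        df = self.frame()
        out: dict = {}
        if df.empty:
            return out
        for (cls, model), grp in df.groupby(["class", "model"]):
            finite = grp["log10_lr"].astype(float)
            out[f"{cls}/{model}/pct_gt0"] = 100.0 * float((finite > LOG_LR_INCLUSION).mean())
            out[f"{cls}/{model}/pct_ge6"] = 100.0 * float((finite >= LOG_LR_STRONG).mean())
            out[f"{cls}/{model}/n"] = int(len(grp))
        if "is_contributor" in df.columns:
            nc = df[~df["is_contributor"].astype(bool)]
            out["false_positives_gt0"] = int((nc["log10_lr"] > LOG_LR_INCLUSION).sum())
            out["false_positives_ge6"] = int((nc["log10_lr"] >= LOG_LR_STRONG).sum())
        return out

    def finalize(self) -> "ExperimentReport":
        self.aggregates = self.recompute_aggregates()
        return self

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        recomputed = self.recompute_aggregates()
        for key, val in recomputed.items():
            if key in self.aggregates and self.aggregates[key] != val:
                raise RuntimeError(
                    f"aggregate {key!r} inconsistent with per-sample records"
                )
        self.aggregates.update(recomputed)
        self.frame().to_csv(directory / f"{self.design}_records.csv", index=False)
        manifest = {
            "design": self.design,
            "seed": self.seed,
            "config": self.config,
            "aggregates": self.aggregates,
        }
        with open(directory / f"{self.design}_manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# shared plumbing


def _prepare(
    epg: Epg,
    cfg: SimulationConfig,
    panel: LocusPanel,
    at: AnalyticalThresholds,
    engine: str = "semi_continuous",
) -> Epg:
    """Threshold and stutter-filter a raw simulated EPG for an engine.

    The semi-continuous engine models no stutter, so every stutter type is
    filtered; the quantitative engine models back and forward stutter, so
    only the unmodeled types are removed and back/forward peaks stay in.
    """
    out = apply_analytical_threshold(epg, at, panel)
    stutter = cfg.stutter_model(panel)
    types = set(STUTTER_OFFSETS)
    if engine == "quantitative":
        types -= {"back", "forward"}
    return filter_unmodeled_stutter(out, stutter, types, panel)


def _true_donor_lr(
    replicates: list[Epg],
    donor: ReferenceProfile,
    noc: int,
    freqs: AlleleFrequencyTable,
    cfg: SimulationConfig,
    engine: str = "semi_continuous",
    panel: LocusPanel | None = None,
    seed: int = 0,
    engine_kwargs: dict | None = None,
) -> LRResult:
    hp = Hypothesis([donor], noc - 1, theta=freqs.theta)
    hd = Hypothesis([], noc, theta=freqs.theta)
    kwargs = dict(engine_kwargs or {})
    if engine == "semi_continuous":
        kwargs.setdefault("drop_in_rate", cfg.drop_in_rate)
        return SemiContinuousModel(replicates, hp, hd, freqs, **kwargs).fit()
    return QuantitativeModel(
        replicates, hp, hd, freqs, panel or default_panel(), seed=seed, **kwargs
    ).fit()


def _simulate_prepared(
    donors,
    cells,
    cfg,
    panel,
    at,
    seed,
    sample_id,
    freqs,
    engine: str = "semi_continuous",
) -> Epg:
    pairs = list(zip(donors, cells))
    raw = simulate_subsample(pairs, cfg, panel, seed, sample_id=sample_id, freqs=freqs)
    return _prepare(raw, cfg, panel, at, engine=engine)


# ---------------------------------------------------------------------------
# experiments


def absent_dropin_allele(epg: Epg, locus: str = "D5S818", preferred: float = 8.0) -> float:
    """The preferred artificial drop-in allele, or the nearest absent one."""
    present = {round(p.allele, 1) for p in epg.peaks(locus)}
    allele = preferred
    while round(allele, 1) in present:
        allele -= 1.0
        if allele < 1.0:
            raise ValueError(f"no absent allele found at {locus}")
    return allele


def perturbation_robustness_experiment(
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    panel: LocusPanel | None = None,
    freqs: AlleleFrequencyTable | None = None,
    n_starts: int = 6,
    degradation_max: float = 0.9,
) -> ExperimentReport:
    """Quantitative-engine LR stability under artificial sample insults.

    A high-quality three-cell single-source subsample (the kind of complete
    profile such tests are run on) is analysed intact and after artificial
    degradation (−80% high-MW / −5% low-MW), inhibition (−40% at four
    loci) and a 15,000-RFU drop-in; degradation is modelled with a free
    per-contributor decay slope.  Reports the log10 LR of each variant and
    its change from the intact profile.
    """
    from .simulate import perturb_profile

    from .stutter import simple_stutter_model

    panel = panel or default_panel()
    freqs = freqs or synthetic_frequencies(panel)
    if cfg is None:
        # flat (mean-SR) stutter matches the engine's single back/forward
        # proportion, as for standard-quality samples
        cfg = SimulationConfig(
            cv_peak=0.5, lsae_sd=0.1,
            stutter=simple_stutter_model(back_slope=0.0, back_intercept=0.07,
                                         forward_mean=0.03,
                                         loci=panel.names),
        )
    at = AnalyticalThresholds()
    d_seed, s_seed, f_seed = child_seeds(seed, 3)
    donor = sample_reference_profiles(freqs, 1, d_seed)[0]
    donor.donor_id = "DONOR000"
    raw = simulate_subsample([(donor, 3)], cfg, panel, s_seed,
                             sample_id="threecell", freqs=freqs)
    base = _prepare(raw, cfg, panel, at, engine="quantitative")
    dropin_allele = absent_dropin_allele(base)
    variants = {
        "original": base,
        "degraded": _prepare(perturb_profile(raw, "degrade"), cfg, panel, at,
                             engine="quantitative"),
        "inhibited": _prepare(perturb_profile(raw, "inhibit"), cfg, panel, at,
                              engine="quantitative"),
        "drop_in": perturb_profile(base, "drop_in",
                                   {"allele": dropin_allele}, panel=panel),
    }
    report = ExperimentReport(design="perturbation_robustness", seed=seed,
                              config=cfg.to_dict())
    hp = Hypothesis([donor], 0, theta=freqs.theta)
    hd = Hypothesis([], 1, theta=freqs.theta)
    lrs = {}
    for name, epg in variants.items():
        res = QuantitativeModel(
            [epg], hp, hd, freqs, panel, at=at, seed=f_seed,
            degradation_max=degradation_max, n_starts=n_starts,
        ).fit()
        lrs[name] = res.log10_lr_total
        report.records.append(
            dict(sample_id=epg.sample_id, **{"class": "perturbation"}, model=name,
                 donor=donor.donor_id, is_contributor=True, noc=1,
                 log10_lr=res.log10_lr_total, status=res.status, seed=f_seed)
        )
    report = report.finalize()
    report.aggregates["max_abs_delta"] = max(
        abs(lrs[name] - lrs["original"]) for name in lrs if name != "original"
    )
    return report


def constructed_dropout_case(
    seed: int = 0,
    panel: LocusPanel | None = None,
    freqs: AlleleFrequencyTable | None = None,
    sister_height: float = 25000.0,
):
    """A single-source profile with one extreme missing-sister locus.

    Returns (epg, donor, locus): a good-quality three-cell profile edited
    so that at one heterozygous locus only one sister allele remains, at a
    height far beyond the calibrated heterozygote-balance bounds — the
    pattern that excludes a true donor when the contributor number is
    understated.
    """
    from .profiles import Peak, alleles_equal

    panel = panel or default_panel()
    freqs = freqs or synthetic_frequencies(panel)
    at = AnalyticalThresholds()
    cfg = SimulationConfig(cv_peak=0.25, lsae_sd=0.1, drop_in_rate=0.0)
    d_seed, s_seed = child_seeds(seed, 2)
    donor = sample_reference_profiles(freqs, 1, d_seed)[0]
    donor.donor_id = "DONOR000"
    raw = simulate_subsample([(donor, 3)], cfg, panel, s_seed,
                             sample_id="adocase", freqs=freqs)
    epg = _prepare(raw, cfg, panel, at, engine="quantitative")
    for locus in panel.names:
        if not donor.is_het(locus):
            continue
        a, b = donor.genotype(locus)
        kept = [p for p in epg.peaks(locus) if alleles_equal(p.allele, a)]
        if kept:
            epg.peaks_by_locus[locus] = [
                Peak(kept[0].allele, sister_height, kept[0].size)
            ]
            return epg, donor, locus
    raise RuntimeError("no heterozygous locus with a surviving sister found")


def sensitivity_specificity_experiment(
    cfg: SimulationConfig,
    n_1cell: int = 20,
    n_2cell_ss: int = 16,
    n_2cell_mix: int = 10,
    db_size: int = 50,
    engine: str = "semi_continuous",
    seed: int = 0,
    panel: LocusPanel | None = None,
    freqs: AlleleFrequencyTable | None = None,
    n_replicate_groups: int = 20,
    db_subsample_stride: int = 10,
) -> ExperimentReport:
    """Sensitivity/specificity of single- and two-cell subsample LRs.

    Simulates 1-cell and 2-cell single-source subsamples and 2-cell
    mini-mixtures, computes true-donor LRs, joins same-donor subsamples
    into replicate groups (sizes 3–5, screened at log10 LR > 1), and
    searches a known non-contributor database for false positives.  Rates
    are tabulated at the log10 LR thresholds 0 and 6.
    """
    for n in (n_1cell, n_2cell_ss, n_2cell_mix, db_size):
        if n < 1:
            raise ValueError("all counts must be >= 1")
    panel = panel or default_panel()
    freqs = freqs or synthetic_frequencies(panel)
    at = AnalyticalThresholds()
    seeds = iter(child_seeds(seed, 8))
    donor_seed, db_seed, s1, s2, s3, grp_seed, db_search_seed, _ = [next(seeds) for _ in range(8)]
    n_donors = max(4, n_replicate_groups)
    donors = sample_reference_profiles(freqs, n_donors, donor_seed)
    for i, d in enumerate(donors):
        d.donor_id = f"DONOR{i:03d}"
    database = sample_reference_profiles(freqs, db_size, db_seed)
    for i, d in enumerate(database):
        d.donor_id = f"NC{i:04d}"

    report = ExperimentReport(
        design="sensitivity_specificity", seed=seed, config=cfg.to_dict()
    )
    by_donor: dict[str, list[tuple[Epg, float, int]]] = {}

    def run_class(cls: str, n: int, cells: list[int], class_seed: int) -> None:
        sub_seeds = child_seeds(class_seed, n)
        for i in range(n):
            if cls == "mix_2cell":
                d1 = donors[i % len(donors)]
                d2 = donors[(i + 1) % len(donors)]
                use = [d1, d2]
                noc = 2
            else:
                use = [donors[i % len(donors)]]
                noc = 1
            epg = _simulate_prepared(
                use, cells, cfg, panel, at, sub_seeds[i], f"{cls}-{i:03d}", freqs
            )
            for donor in use:
                res = _true_donor_lr([epg], donor, noc, freqs, cfg, engine, panel, sub_seeds[i])
                report.records.append(
                    dict(
                        sample_id=epg.sample_id,
                        **{"class": cls},
                        model="subsample",
                        donor=donor.donor_id,
                        is_contributor=True,
                        noc=noc,
                        n_alleles=epg.n_peaks(),
                        log10_lr=res.log10_lr_total,
                        status=res.status,
                        seed=sub_seeds[i],
                    )
                )
                if noc == 1 and res.log10_lr_total > 1.0:  # replicate screening
                    by_donor.setdefault(donor.donor_id, []).append(
                        (epg, res.log10_lr_total, sub_seeds[i])
                    )

    run_class("ss_1cell", n_1cell, [1], s1)
    run_class("ss_2cell", n_2cell_ss, [2], s2)
    run_class("mix_2cell", n_2cell_mix, [1, 1], s3)

    # replicate groups of 3-5 same-donor subsamples
    rng = np.random.default_rng(grp_seed)
    donor_map = {d.donor_id: d for d in donors}
    groups_done = 0
    for donor_id, items in by_donor.items():
        if groups_done >= n_replicate_groups or len(items) < 2:
            continue
        size = min(len(items), int(rng.integers(3, 6)))
        chosen = [items[j] for j in rng.choice(len(items), size=size, replace=False)]
        reps = [e for e, _, _ in chosen]
        res = _true_donor_lr(reps, donor_map[donor_id], 1, freqs, cfg, engine, panel, grp_seed)
        report.records.append(
            dict(
                sample_id=f"replicate-{donor_id}",
                **{"class": "replicate"},
                model="replicate",
                donor=donor_id,
                is_contributor=True,
                noc=1,
                n_alleles=max(e.n_peaks() for e in reps),
                log10_lr=res.log10_lr_total,
                status=res.status,
                seed=grp_seed,
            )
        )
        groups_done += 1

    # non-contributor database search on a stride of subsamples
    search_items = [
        (rec["sample_id"], rec["seed"]) for rec in report.records if rec["model"] == "subsample"
    ][::db_subsample_stride]
    sub_lookup: dict[str, Epg] = {}
    for cls, n, cells, class_seed in (
        ("ss_1cell", n_1cell, [1], s1),
        ("ss_2cell", n_2cell_ss, [2], s2),
    ):
        sub_seeds = child_seeds(class_seed, n)
        for i in range(n):
            sid = f"{cls}-{i:03d}"
            use = [donors[i % len(donors)]]
            sub_lookup[sid] = _simulate_prepared(
                use, cells, cfg, panel, at, sub_seeds[i], sid, freqs
            )
    for sid, sseed in search_items:
        if sid not in sub_lookup:
            continue
        epg = sub_lookup[sid]
        results = database_search(
            [epg], database, freqs, model="semi_continuous",
            drop_in_rate=cfg.drop_in_rate,
        )
        for res in results:
            report.records.append(
                dict(
                    sample_id=sid,
                    **{"class": "noncontributor"},
                    model="database",
                    donor=res.hp.known_contributors[0].donor_id,
                    is_contributor=False,
                    noc=1,
                    n_alleles=epg.n_peaks(),
                    log10_lr=res.log10_lr_total,
                    status=res.status,
                    seed=sseed,
                )
            )
    return report.finalize()


def noc_misspecification_experiment(
    cfg: SimulationConfig,
    n_single_source: int = 35,
    n_minimix: int = 35,
    engine: str = "semi_continuous",
    seed: int = 0,
    panel: LocusPanel | None = None,
    freqs: AlleleFrequencyTable | None = None,
) -> ExperimentReport:
    """Paired LRs under the stated and the misspecified contributor number.

    Single-source subsamples are evaluated at N=1 and N=2 (overstatement);
    2-cell mini-mixtures at N=2 and N=1 (understatement).  Sign changes
    and LR-of-zero cases rescued by N+1 are counted.
    """
    panel = panel or default_panel()
    freqs = freqs or synthetic_frequencies(panel)
    at = AnalyticalThresholds()
    d_seed, ss_seed, mm_seed = child_seeds(seed, 3)
    donors = sample_reference_profiles(freqs, max(8, 4), d_seed)
    for i, d in enumerate(donors):
        d.donor_id = f"DONOR{i:03d}"
    report = ExperimentReport(design="noc_misspecification", seed=seed, config=cfg.to_dict())

    ss_seeds = child_seeds(ss_seed, n_single_source)
    for i in range(n_single_source):
        donor = donors[i % len(donors)]
        epg = _simulate_prepared([donor], [1], cfg, panel, at, ss_seeds[i], f"ss-{i:03d}", freqs)
        for noc, label in ((1, "stated"), (2, "overstated")):
            res = _true_donor_lr([epg], donor, noc, freqs, cfg, engine, panel, ss_seeds[i])
            report.records.append(
                dict(
                    sample_id=epg.sample_id,
                    **{"class": f"single_source_{label}"},
                    model=label,
                    donor=donor.donor_id,
                    is_contributor=True,
                    noc=noc,
                    log10_lr=res.log10_lr_total,
                    status=res.status,
                    seed=ss_seeds[i],
                )
            )

    mm_seeds = child_seeds(mm_seed, n_minimix)
    for i in range(n_minimix):
        d1 = donors[i % len(donors)]
        d2 = donors[(i + 3) % len(donors)]
        if d1.donor_id == d2.donor_id:
            d2 = donors[(i + 4) % len(donors)]
        epg = _simulate_prepared([d1, d2], [1, 1], cfg, panel, at, mm_seeds[i], f"mm-{i:03d}", freqs)
        for noc, label in ((2, "stated"), (1, "understated")):
            res = _true_donor_lr([epg], d1, noc, freqs, cfg, engine, panel, mm_seeds[i])
            report.records.append(
                dict(
                    sample_id=epg.sample_id,
                    **{"class": f"minimix_{label}"},
                    model=label,
                    donor=d1.donor_id,
                    is_contributor=True,
                    noc=noc,
                    log10_lr=res.log10_lr_total,
                    status=res.status,
                    seed=mm_seeds[i],
                )
            )

    df = report.frame()
    paired = {}
    for cls_a, cls_b, name in (
        ("single_source_stated", "single_source_overstated", "overstatement"),
        ("minimix_stated", "minimix_understated", "understatement"),
    ):
        a = df[df["class"] == cls_a].set_index("sample_id")["log10_lr"]
        b = df[df["class"] == cls_b].set_index("sample_id")["log10_lr"]
        joined = pd.concat([a, b], axis=1, keys=["stated", "alt"]).dropna(how="all")
        sign_changes = int(((joined["stated"] > 0) != (joined["alt"] > 0)).sum())
        rescued = int(((joined["stated"] == -math.inf) & (joined["alt"] > 0)).sum())
        excluded = int(((joined["stated"] > 0) & (joined["alt"] <= 0)).sum())
        paired[name] = dict(sign_changes=sign_changes, zero_rescued_by_alt=rescued,
                            true_donor_excluded_by_alt=excluded, n=len(joined))
    report = report.finalize()
    report.aggregates.update({f"paired/{k}/{kk}": vv for k, v in paired.items() for kk, vv in v.items()})
    return report


def replicate_misclassification_experiment(
    cfg: SimulationConfig,
    group_spec: dict | None = None,
    intruder_spec: list[dict] | None = None,
    engine: str = "quantitative",
    seed: int = 0,
    panel: LocusPanel | None = None,
    freqs: AlleleFrequencyTable | None = None,
    engine_kwargs: dict | None = None,
) -> ExperimentReport:
    """Effect of adding a wrong-donor subsample to a replicate group.

    ``group_spec``: {"n_replicates": int, "cells": int} for the correct
    donor; ``intruder_spec``: list of {"donor": index, "cells": int,
    optional "cv_peak", "label": str} wrong-donor subsamples of varying
    quality.  The replicate LR for the true donor is reported with and
    without each intruder; engine model failures are recorded as the
    distinct outcome "FAIL".  The height-aware quantitative engine with an
    exponential drop-in height law is the default: explaining away a
    misclassified donor's tall peaks as drop-in is what collapses the LR,
    while a sparse low-level wrong-donor profile has little effect.
    """
    panel = panel or default_panel()
    freqs = freqs or synthetic_frequencies(panel)
    at = AnalyticalThresholds()
    group_spec = group_spec or {"n_replicates": 3, "cells": 2}
    intruder_spec = intruder_spec or [
        {"donor": 1, "cells": 1, "cv_peak": 4.0, "label": "poor"},
        {"donor": 1, "cells": 5, "label": "high_quality"},
    ]
    if engine == "quantitative":
        engine_kwargs = {"dropin_law": "exponential", **(engine_kwargs or {})}
    d_seed, g_seed, i_seed = child_seeds(seed, 3)
    donors = sample_reference_profiles(freqs, 6, d_seed)
    for i, d in enumerate(donors):
        d.donor_id = f"DONOR{i:03d}"
    true_donor = donors[0]
    report = ExperimentReport(design="replicate_misclassification", seed=seed, config=cfg.to_dict())

    g_seeds = child_seeds(g_seed, group_spec["n_replicates"])
    group = [
        _simulate_prepared([true_donor], [group_spec["cells"]], cfg, panel, at, s,
                           f"grp-{j:02d}", freqs, engine=engine)
        for j, s in enumerate(g_seeds)
    ]
    base = _true_donor_lr(group, true_donor, 1, freqs, cfg, engine, panel, g_seed,
                          engine_kwargs)
    report.records.append(
        dict(sample_id="baseline", **{"class": "replicate"}, model="baseline",
             donor=true_donor.donor_id, is_contributor=True, noc=1,
             intruder="", intruder_alleles=0,
             log10_lr=base.log10_lr_total, status=base.status, seed=g_seed)
    )
    i_seeds = child_seeds(i_seed, len(intruder_spec))
    for j, spec in enumerate(intruder_spec):
        wrong = donors[spec["donor"]]
        icfg = cfg
        if "cv_peak" in spec:
            data = cfg.to_dict()
            data["cv_peak"] = spec["cv_peak"]
            from .io import simulation_config_from_dict

            icfg = simulation_config_from_dict(data)
        intruder = _simulate_prepared(
            [wrong], [spec["cells"]], icfg, panel, at, i_seeds[j],
            f"intruder-{spec.get('label', j)}", freqs, engine=engine
        )
        res = _true_donor_lr(group + [intruder], true_donor, 1, freqs, cfg, engine,
                             panel, i_seeds[j], engine_kwargs)
        report.records.append(
            dict(sample_id=intruder.sample_id, **{"class": "replicate"},
                 model="with_intruder", donor=true_donor.donor_id, is_contributor=True,
                 noc=1, intruder=spec.get("label", str(j)),
                 intruder_alleles=intruder.n_peaks(),
                 log10_lr=res.log10_lr_total, status=res.status, seed=i_seeds[j])
        )
    report = report.finalize()
    report.aggregates["baseline_log10_lr"] = base.log10_lr_total
    return report


def mixture_deconvolution_experiment(
    cfg: SimulationConfig,
    noc_list: list[int] | None = None,
    engine: str = "semi_continuous",
    seed: int = 0,
    panel: LocusPanel | None = None,
    freqs: AlleleFrequencyTable | None = None,
    n_subsamples_per_donor: int = 3,
    bulk_max_noc: int = 3,
) -> ExperimentReport:
    """Single-cell subsampling deconvolution vs bulk analysis vs ceiling.

    For each equimolar mixture size: the per-donor reference ceiling
    log10(1/RMP), the replicate LR from that donor's simulated single-cell
    subsamples, and — where the bulk engine supports the contributor
    number — the standard bulk-mixture LR.  Larger mixtures record a
    "not supported" refusal for bulk analysis.
    """
    panel = panel or default_panel()
    freqs = freqs or synthetic_frequencies(panel)
    at = AnalyticalThresholds()
    noc_list = noc_list or [2, 3, 4, 5, 6]
    report = ExperimentReport(design="mixture_deconvolution", seed=seed, config=cfg.to_dict())
    mix_seeds = child_seeds(seed, len(noc_list))
    for noc, mseed in zip(noc_list, mix_seeds):
        d_seed, sub_seed, bulk_seed = child_seeds(mseed, 3)
        donors = sample_reference_profiles(freqs, noc, d_seed)
        for i, d in enumerate(donors):
            d.donor_id = f"M{noc}D{i}"
        sub_seeds = child_seeds(sub_seed, noc * n_subsamples_per_donor)
        bulk = _simulate_prepared(donors, [2] * noc, cfg, panel, at, bulk_seed,
                                  f"bulk-{noc}p", freqs)
        for di, donor in enumerate(donors):
            ceiling = single_source_profile_lr(donor, freqs).log10_lr_total
            reps = [
                _simulate_prepared([donor], [1], cfg, panel, at,
                                   sub_seeds[di * n_subsamples_per_donor + j],
                                   f"m{noc}-d{di}-s{j}", freqs)
                for j in range(n_subsamples_per_donor)
            ]
            dscs = _true_donor_lr(reps, donor, 1, freqs, cfg, engine, panel, mseed)
            common = dict(donor=donor.donor_id, is_contributor=True, seed=mseed)
            report.records.append(
                dict(sample_id=f"m{noc}-{donor.donor_id}", **{"class": f"mix{noc}"},
                     model="reference_ceiling", noc=1, log10_lr=ceiling, status="ok",
                     **common)
            )
            report.records.append(
                dict(sample_id=f"m{noc}-{donor.donor_id}", **{"class": f"mix{noc}"},
                     model="dscs_replicate", noc=1, log10_lr=dscs.log10_lr_total,
                     status=dscs.status, **common)
            )
            if noc <= bulk_max_noc:
                res = _true_donor_lr([bulk], donor, noc, freqs, cfg, engine, panel, bulk_seed)
                report.records.append(
                    dict(sample_id=f"m{noc}-{donor.donor_id}", **{"class": f"mix{noc}"},
                         model="bulk_standard", noc=noc, log10_lr=res.log10_lr_total,
                         status=res.status, **common)
                )
            else:
                report.records.append(
                    dict(sample_id=f"m{noc}-{donor.donor_id}", **{"class": f"mix{noc}"},
                         model="bulk_standard", noc=noc, log10_lr=math.nan,
                         status="not supported", **common)
                )
    return report.finalize()
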