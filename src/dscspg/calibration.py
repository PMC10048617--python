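"""Calibration of interpretation parameters from control and known samples.

Five empirically determined quantities drive low-template STR
interpretation and are estimated here:

* **analytical threshold** per dye: AT = 2 x (highest baseline peak -
  lowest baseline trough) over a set of negative-control injections;
* **stutter-ratio regressions** per locus and stutter type, SR linear in
  parent allele number (or a flat mean), with max-SR caps;
* **drop-in rate**: drop-in events / (loci scored x samples) over
  truth-free negative controls, with a suggested drop-in height cap;
* **instrument saturation**: the observed height beyond which the observed
  allele height Oa consistently under-reports the expected height
  Ea = back-stutter height / predicted SR;
* **heterozygote-balance variance**: C^2, the 50th-percentile allelic
  peak-height variance, giving 95% bounds +/- k*sqrt(C^2/APH) on log10 Hb.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm

from .panel import LocusPanel
from .profiles import AnalyticalThresholds, Epg, ReferenceProfile, alleles_equal
from .simulate import NoiseRecord
from .stutter import STUTTER_OFFSETS, StutterFit, StutterModel, stutter_position

#: Median of the chi-square(1) distribution; rescales a median of squared
#: Gaussian deviations into a consistent variance estimate.
CHI2_1_MEDIAN = 0.45493642311957283


@dataclass
class DropInEstimate:
    rate: float
    events: int
    opportunities: int
    cap_suggested: float
    rate_exact: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        assert self.rate == self.events / self.opportunities


@dataclass
class HbBounds:
    """Heterozygote-balance variance summary.

    ``bounds(aph)`` returns the half-width of the central log10 Hb band at
    average peak height ``aph``; ``within_bounds_fraction`` is the share of
    calibration observations falling inside +/- that half-width.
    """

    c_squared: float
    k: float
    within_bounds_fraction: float
    n: int

    def bounds(self, aph: float) -> float:
        return self.k * math.sqrt(self.c_squared / aph)


@dataclass
class CalibrationResult:
    at: AnalyticalThresholds
    stutter: StutterModel
    drop_in: DropInEstimate
    saturation_rfu: float | None
    hb: HbBounds

    @property
    def drop_in_rate(self) -> float:
        return self.drop_in.rate

    @property
    def c_squared(self) -> float:
        return self.hb.c_squared


def estimate_analytical_threshold(controls: Sequence[NoiseRecord]) -> AnalyticalThresholds:
    """Per-dye AT = 2 x (max highest peak - min lowest trough) over controls."""
    if not controls:
        raise ValueError("at least one negative control is required")
    dyes = set()
    for c in controls:
        dyes.update(c.highest_peak)
    by_dye = {}
    for dye in sorted(dyes):
        highs = [c.highest_peak[dye] for c in controls if dye in c.highest_peak]
        lows = [c.lowest_trough[dye] for c in controls if dye in c.lowest_trough]
        by_dye[dye] = 2.0 * (max(highs) - min(lows))
    return AnalyticalThresholds(by_dye=by_dye)


def _stutter_observations(
    epg: Epg,
    truth: ReferenceProfile,
    panel: LocusPanel,
    stutter_types: Sequence[str],
) -> dict[str, dict[str, list[tuple[float, float]]]]:
    """(parent allele, SR) observations per locus and type.

    A stutter position is usable only when it is unambiguous: not shared
    with a true allele of the donor and not a stutter position of any other
    (parent, type) candidate at the locus.
    """
    out: dict[str, dict[str, list[tuple[float, float]]]] = {}
    for locus_rec in panel:
        locus = locus_rec.name
        try:
            g = truth.genotype(locus)
        except KeyError:
            continue
        parents = sorted(set(g))
        peaks = {p.allele: p.height for p in epg.peaks(locus)}

        def height_at(allele: float) -> float | None:
            for a, h in peaks.items():
                if alleles_equal(a, allele):
                    return h
            return None

        candidates = []
        for parent in parents:
            for st in stutter_types:
                pos = stutter_position(parent, st, locus_rec.repeat_bp)
                candidates.append((parent, st, pos))
        for parent, st, pos in candidates:
            if any(alleles_equal(pos, a) for a in parents):
                continue
            n_at_pos = sum(1 for _, _, q in candidates if alleles_equal(q, pos))
            if n_at_pos > 1:
                continue
            parent_h = height_at(parent)
            if parent_h is None:
                continue
            # a present parent with no called stutter peak scores SR = 0
            stutter_h = height_at(pos) or 0.0
            out.setdefault(locus, {}).setdefault(st, []).append(
                (parent, stutter_h / parent_h)
            )
    return out


def fit_stutter_model(
    subsamples: Sequence[Epg],
    truths: Sequence[ReferenceProfile],
    panel: LocusPanel,
    stutter_types: Sequence[str] = tuple(STUTTER_OFFSETS),
    max_sr: dict[str, float] | None = None,
    linear_p_threshold: float = 0.05,
) -> StutterModel:
    """Fit per-locus, per-type SR regressions from single-source subsamples.

    A locus/type is fitted as SR linear in parent allele number when at
    least three distinct parent alleles are observed and the slope is
    significant at ``linear_p_threshold``; otherwise the mean SR is used.
    Loci/types with no usable observation are left absent and downstream
    prediction falls back to the panel-wide mean for the type.
    """
    if len(subsamples) != len(truths):
        raise ValueError("subsamples and truths must align")
    pooled: dict[str, dict[str, list[tuple[float, float]]]] = {}
    for epg, truth in zip(subsamples, truths):
        obs = _stutter_observations(epg, truth, panel, stutter_types)
        for locus, by_type in obs.items():
            for st, pairs in by_type.items():
                pooled.setdefault(locus, {}).setdefault(st, []).extend(pairs)

    model = StutterModel()
    if max_sr:
        model.max_sr.update(max_sr)
    for locus, by_type in pooled.items():
        for st, pairs in by_type.items():
            alleles = np.array([a for a, _ in pairs], dtype=float)
            srs = np.array([sr for _, sr in pairs], dtype=float)
            n = len(pairs)
            distinct = len(np.unique(alleles))
            fit = None
            if distinct >= 3:
                X = sm.add_constant(alleles)
                ols = sm.OLS(srs, X).fit()
                slope_p = float(ols.pvalues[1]) if len(ols.pvalues) > 1 else 1.0
                if np.isfinite(slope_p) and slope_p < linear_p_threshold:
                    fit = StutterFit(
                        kind="linear",
                        slope=float(ols.params[1]),
                        intercept=float(ols.params[0]),
                        r_squared=float(ols.rsquared),
                        n=n,
                        slope_se=float(ols.bse[1]),
                        intercept_se=float(ols.bse[0]),
                    )
            if fit is None:
                fit = StutterFit(
                    kind="mean",
                    mean_sr=float(srs.mean()),
                    r_squared=float("nan"),
                    n=n,
                )
            model.set_fit(locus, st, fit)
    return model


def estimate_drop_in_rate(
    controls: Sequence[Epg],
    panel: LocusPanel,
    cap_floor: float = 1000.0,
    max_events_per_profile: int = 2,
) -> DropInEstimate:
    """Drop-in rate = events / (loci scored x samples) over negative controls.

    Any surviving allelic peak in a truth-free control counts as a drop-in
    event, at most ``max_events_per_profile`` per control; more triggers a
    contamination warning and the excess is not counted as drop-in.  The
    suggested cap is the smallest round thousand RFU above the highest
    observed drop-in height.
    """
    if not controls:
        raise ValueError("zero drop-in opportunities: no controls supplied")
    opportunities = len(panel) * len(controls)
    events = 0
    max_height = 0.0
    for epg in controls:
        peaks = [p for peaks in epg.peaks_by_locus.values() for p in peaks]
        if len(peaks) > max_events_per_profile:
            warnings.warn(
                f"control {epg.sample_id!r} shows {len(peaks)} peaks; "
                f"more than {max_events_per_profile} suggests contamination, "
                "excess not counted as drop-in",
                stacklevel=2,
            )
        counted = sorted(peaks, key=lambda p: -p.height)[:max_events_per_profile]
        events += len(counted)
        for p in counted:
            max_height = max(max_height, p.height)
    rate = Fraction(events, opportunities)
    cap = max(cap_floor, math.ceil(max_height / 1000.0) * 1000.0) if events else cap_floor
    return DropInEstimate(
        rate=events / opportunities,
        events=events,
        opportunities=opportunities,
        cap_suggested=float(cap),
        rate_exact=rate,
    )


def estimate_saturation_threshold(
    standards: Sequence[Epg],
    truths: Sequence[ReferenceProfile],
    stutter: StutterModel,
    panel: LocusPanel,
    bin_width: float = 2000.0,
    divergence_tol: float = 0.10,
    min_pairs: int = 50,
) -> float | None:
    """Detect the detector saturation ceiling from (Oa, Ea) divergence.

    For every parent allele with a measurable, unambiguous back-stutter
    peak at a simple-repeat locus, the expected height is back-calculated
    as Ea = stutter height / predicted SR.  Pairs are binned by Oa in
    ``bin_width``-RFU bins; the estimate is the lower edge of the first bin
    from which the median Oa/Ea stays below 1 - divergence_tol in every
    subsequent non-empty bin.  Returns None when no divergence is seen.
    """
    if len(standards) != len(truths):
        raise ValueError("standards and truths must align")
    simple = [loc for loc in panel if loc.simple_repeat]
    simple_panel = LocusPanel(simple)
    pairs: list[tuple[float, float]] = []
    for epg, truth in zip(standards, truths):
        obs = _stutter_observations(epg, truth, simple_panel, ("back",))
        for locus, by_type in obs.items():
            for parent, sr_obs in by_type.get("back", []):
                if sr_obs <= 0:
                    continue  # no measurable stutter peak
                sr_pred = stutter.predict(locus, "back", parent)
                if sr_pred <= 0:
                    continue
                parent_h = next(
                    p.height for p in epg.peaks(locus) if alleles_equal(p.allele, parent)
                )
                ea = (sr_obs * parent_h) / sr_pred  # = stutter height / SR
                pairs.append((parent_h, ea))
    if len(pairs) < min_pairs:
        raise ValueError(
            f"only {len(pairs)} usable (Oa, Ea) pairs; at least {min_pairs} required"
        )
    oa = np.array([o for o, _ in pairs])
    ratio = np.array([o / e for o, e in pairs])
    bins = np.floor(oa / bin_width).astype(int)
    medians = {
        b: float(np.median(ratio[bins == b])) for b in np.unique(bins)
    }
    ordered = sorted(medians)
    threshold_bin = None
    for i, b in enumerate(ordered):
        if all(medians[bb] < 1.0 - divergence_tol for bb in ordered[i:]):
            threshold_bin = b
            break
    if threshold_bin is None:
        return None
    return float(threshold_bin * bin_width)


def heterozygote_balance_bounds(
    subsamples: Sequence[Epg],
    truths: Sequence[ReferenceProfile],
    k: float = 1.96,
    min_obs: int = 30,
) -> HbBounds:
    """C^2 and 95% heterozygote-balance bounds from known-donor subsamples.

    Under the variance model var(log10 Hb) = C^2 / APH, each observation's
    (log10 Hb)^2 * APH estimates C^2; the median of those, rescaled by the
    chi-square(1) median, is the 50th-percentile variance estimate.  The
    bounds at a given APH are +/- k * sqrt(C^2 / APH).
    """
    if len(subsamples) != len(truths):
        raise ValueError("subsamples and truths must align")
    from .profiles import log_hb

    obs: list[tuple[float, float]] = []
    for epg, truth in zip(subsamples, truths):
        for locus in epg.peaks_by_locus:
            try:
                rec = log_hb(epg, truth, locus)
            except KeyError:
                continue
            if rec is not None:
                obs.append(rec)
    if not obs:
        raise ValueError("no heterozygous observations with both sister alleles present")
    if len(obs) < min_obs:
        warnings.warn(
            f"only {len(obs)} heterozygote observations (< {min_obs}); "
            "C^2 estimate will be unstable",
            stacklevel=2,
        )
    aph = np.array([a for a, _ in obs])
    lhb = np.array([h for _, h in obs])
    c2 = float(np.median(lhb**2 * aph) / CHI2_1_MEDIAN)
    if c2 <= 0:
        within = 1.0
    else:
        half = k * np.sqrt(c2 / aph)
        within = float(np.mean(np.abs(lhb) <= half))
    return HbBounds(c_squared=c2, k=k, within_bounds_fraction=within, n=len(obs))


def calibrate(
    noise_controls: Sequence[NoiseRecord],
    drop_in_controls: Sequence[Epg],
    stutter_subsamples: Sequence[Epg],
    stutter_truths: Sequence[ReferenceProfile],
    saturation_standards: Sequence[Epg],
    saturation_truths: Sequence[ReferenceProfile],
    panel: LocusPanel,
    k: float = 1.96,
) -> CalibrationResult:
    """Run the full calibration battery and assemble a CalibrationResult."""
    at = estimate_analytical_threshold(noise_controls)
    stutter = fit_stutter_model(stutter_subsamples, stutter_truths, panel)
    drop_in = estimate_drop_in_rate(drop_in_controls, panel)
    try:
        saturation = estimate_saturation_threshold(
            saturation_standards, saturation_truths, stutter, panel
        )
    except ValueError:
        saturation = None
    hb = heterozygote_balance_bounds(stutter_subsamples, stutter_truths, k=k)
    return CalibrationResult(at=at, stutter=stutter, drop_in=drop_in,
                             saturation_rfu=saturation, hb=hb)


def write_calibration(result: CalibrationResult, path) -> None:
    """Serialize a CalibrationResult to a YAML file the engines can load."""
    import yaml

    data = {
        "analytical_thresholds": dict(result.at.by_dye),
        "stutter": {
            "max_sr": dict(result.stutter.max_sr),
            "fits": {
                locus: {st: vars(fit) for st, fit in by_type.items()}
                for locus, by_type in result.stutter.fits.items()
            },
        },
        "drop_in": {
            "rate": result.drop_in.rate,
            "events": result.drop_in.events,
            "opportunities": result.drop_in.opportunities,
            "cap_suggested": result.drop_in.cap_suggested,
        },
        "saturation_rfu": result.saturation_rfu,
        "hb": {
            "c_squared": result.hb.c_squared,
            "k": result.hb.k,
            "within_bounds_fraction": result.hb.within_bounds_fraction,
            "n": result.hb.n,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_calibration(path) -> CalibrationResult:
    """Load a CalibrationResult written by :func:`write_calibration`."""
    import yaml

    from .profiles import AnalyticalThresholds

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    stutter = StutterModel()
    stutter.max_sr.update(data["stutter"].get("max_sr") or {})
    for locus, by_type in (data["stutter"].get("fits") or {}).items():
        for st, fit in by_type.items():
            stutter.set_fit(locus, st, StutterFit(**fit))
    di = data["drop_in"]
    drop_in = DropInEstimate(
        rate=di["events"] / di["opportunities"],
        events=di["events"],
        opportunities=di["opportunities"],
        cap_suggested=di["cap_suggested"],
        rate_exact=Fraction(di["events"], di["opportunities"]),
    )
    hb = HbBounds(
        c_squared=data["hb"]["c_squared"], k=data["hb"]["k"],
        within_bounds_fraction=data["hb"]["within_bounds_fraction"],
        n=data["hb"]["n"],
    )
    return CalibrationResult(
        at=AnalyticalThresholds(by_dye=dict(data["analytical_thresholds"])),
        stutter=stutter,
        drop_in=drop_in,
        saturation_rfu=data["saturation_rfu"],
        hb=hb,
    )


def export_stutter_table(model: StutterModel, path) -> None:
    """Write the stutter model as a per-locus regression table (CSV)."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["Locus", "Type", "Kind", "Slope", "Intercept", "MeanSR", "MaxSR", "R2", "N"]
        )
        for locus, by_type in sorted(model.fits.items()):
            for st, fit in sorted(by_type.items()):
                writer.writerow(
                    [
                        locus,
                        st,
                        fit.kind,
                        f"{fit.slope:.6g}",
                        f"{fit.intercept:.6g}",
                        f"{fit.mean_sr:.6g}",
                        f"{model.cap(st):.3g}",
                        "" if math.isnan(fit.r_squared) else f"{fit.r_squared:.4f}",
                        fit.n,
                    ]
                )
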