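"""Synthetic low-template STR electropherograms.

Generates reference profiles, 1–5-cell subsample EPGs, mini-mixtures,
negative controls, and the standard artificial perturbations (degradation,
inhibition, drop-in) with the statistical structure the calibration and LR
stages assume: per-allele gamma peak heights whose variance grows as the
template shrinks (so drop-out and extreme heterozygote imbalance emerge at
one cell), a shared per-locus amplification-efficiency factor, size-dependent
degradation, per-locus inhibition, multi-type stutter, drop-in, and
saturation clipping.

The peak-height law is gamma: each allele copy of a donor with ``c`` cells
contributes Gamma(shape=c/cv_peak^2, mean=c * mean_height_per_cell * m)
where ``m`` collects the locus LSAE factor, the donor's degradation decay
and any inhibition multiplier.  ``cv_peak`` is therefore the coefficient of
variation of a single-cell single-copy peak; at c cells the CV shrinks as
1/sqrt(c).  Alleles whose realized height falls below the minimum dye
analytical threshold are not called: drop-out is emergent, not a coin flip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .panel import LocusPanel
from .profiles import (
    AnalyticalThresholds,
    Epg,
    Peak,
    ReferenceProfile,
    AlleleFrequencyTable,
    alleles_equal,
)
from .stutter import STUTTER_OFFSETS, StutterModel, simple_stutter_model, stutter_position

#: Loci inhibited in the artificial-inhibition perturbation.
INHIBITION_LOCI = ("D22S1045", "D21S11", "D13S317", "D2S1338")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds by indexed splitting (all < 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass
class SimulationConfig:
    """Study conditions for the few-cell amplification workflow.

    Defaults emulate a 32-cycle few-cell direct amplification read on a
    3500-class analyzer: ~3000 RFU per cell per allele at the reference
    size, saturation clipping at 30,000 RFU, drop-in at the calibrated
    per-locus rate with heights capped at 5,000 RFU.
    """

    mean_height_per_cell: float = 3000.0
    cv_peak: float = 2.4
    lsae_sd: float = 0.25
    dropout_shape: tuple[float, float] | None = None  # (h50, slope) extra logistic
    stutter: StutterModel | None = None
    stutter_sr_sd: float = 0.02
    drop_in_rate: float = 0.0164
    drop_in_law: str = "exponential"  # or "uniform"
    drop_in_scale: float = 400.0
    drop_in_floor: float = 50.0
    drop_in_cap: float = 5000.0
    degradation: float = 1.0  # decay per 100 bp, in (0, 1]
    size_ref: float = 125.0
    inhibition: dict[str, float] = field(default_factory=dict)
    saturation: float = 30000.0
    call_floor: float = 46.0  # minimum dye AT: peaks below are never called
    baseline_sd: float = 4.0
    trace_points: int = 200
    cycles_note: str = "32-cycle direct amplification"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.drop_in_rate <= 1:
            raise ValueError("drop_in_rate must be in [0, 1]")
        if not 0 < self.degradation <= 1:
            raise ValueError("degradation must be in (0, 1]")
        for locus, m in self.inhibition.items():
            if not 0 < m <= 1:
                raise ValueError(f"inhibition multiplier for {locus} must be in (0, 1]")
        if self.drop_in_law not in ("exponential", "uniform"):
            raise ValueError("drop_in_law must be 'exponential' or 'uniform'")

    def stutter_model(self, panel: LocusPanel) -> StutterModel:
        if self.stutter is not None:
            return self.stutter
        return simple_stutter_model(loci=panel.names)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.stutter is not None:
            d["stutter"] = {
                "max_sr": dict(self.stutter.max_sr),
                "fits": {
                    locus: {
                        st: vars(fit) for st, fit in by_type.items()
                    }
                    for locus, by_type in self.stutter.fits.items()
                },
            }
        return d


@dataclass
class NoiseRecord:
    """Baseline summary of a negative-control injection, per dye."""

    sample_id: str
    highest_peak: dict[str, float]
    lowest_trough: dict[str, float]
    drop_in: Epg


def sample_reference_profiles(
    freqs: AlleleFrequencyTable, n: int, seed
) -> list[ReferenceProfile]:
    """Draw n reference profiles under Hardy–Weinberg equilibrium.

    Genotypes are drawn per locus from the frequency table, independently
    across loci and individuals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    loci = freqs.loci
    allele_arrays = {}
    for locus in loci:
        alleles = freqs.alleles(locus)
        if not alleles:
            raise ValueError(f"locus {locus!r} has no alleles")
        p = np.array([freqs.frequency(locus, a) for a in alleles], dtype=float)
        allele_arrays[locus] = (np.array(alleles, dtype=float), p / p.sum())
    out = []
    for i in range(n):
        geno = {}
        for locus in loci:
            alleles, p = allele_arrays[locus]
            pair = rng.choice(alleles, size=2, p=p)
            geno[locus] = (float(pair[0]), float(pair[1]))
        out.append(ReferenceProfile(donor_id=f"SIM{i:04d}", genotype_by_locus=geno))
    return out


def _expected_height(
    cfg: SimulationConfig,
    cells: int,
    size: float,
    lsae: float,
    inhibition: float,
) -> float:
    decay = cfg.degradation ** ((size - cfg.size_ref) / 100.0)
    return cfg.mean_height_per_cell * cells * lsae * decay * inhibition


def simulate_subsample(
    donors: Sequence[tuple[ReferenceProfile, int]],
    cfg: SimulationConfig,
    panel: LocusPanel,
    seed,
    sample_id: str = "sim",
    freqs: AlleleFrequencyTable | None = None,
) -> Epg:
    """Simulate one subsample EPG from (reference profile, cell count) pairs.

    Shared alleles sum their contributions; stutter peaks are generated per
    modelled type at the predicted SR plus truncated-Gaussian noise;
    drop-in peaks are added per locus at ``cfg.drop_in_rate``; all heights
    are clipped at ``cfg.saturation``.  Peaks below ``cfg.call_floor`` are
    not called.
    """
    for _, cells in donors:
        if cells < 0:
            raise ValueError("negative cell count")
    rng = _rng(seed)
    stutter_model = cfg.stutter_model(panel)
    k0 = 1.0 / (cfg.cv_peak**2)
    peaks_by_locus: dict[str, list[Peak]] = {}
    for locus_rec in panel:
        locus = locus_rec.name
        lsae = float(np.exp(rng.normal(0.0, cfg.lsae_sd))) if cfg.lsae_sd > 0 else 1.0
        inhib = cfg.inhibition.get(locus, 1.0)
        heights: dict[float, float] = {}

        def add(allele: float, h: float) -> None:
            for existing in heights:
                if alleles_equal(existing, allele):
                    heights[existing] += h
                    return
            heights[allele] = h

        # allelic contributions
        for donor, cells in donors:
            if cells == 0:
                continue
            a, b = donor.genotype(locus)
            copies = [a, b]
            for allele in copies:
                size = locus_rec.size_of(allele)
                mean = _expected_height(cfg, cells, size, lsae, inhib)
                if cfg.dropout_shape is not None:
                    h50, slope = cfg.dropout_shape
                    p_do = 1.0 / (1.0 + (mean / h50) ** slope)
                    if rng.random() < p_do:
                        continue
                shape = cells * k0
                h = float(rng.gamma(shape, mean / shape))
                add(allele, h)

        # stutter from realized parent heights
        stutter_add: dict[float, float] = {}
        for allele, parent_h in list(heights.items()):
            for st in STUTTER_OFFSETS:
                if stutter_model.get_fit(locus, st) is None:
                    continue  # only modelled types produce stutter
                sr_mean = stutter_model.predict(locus, st, allele)
                sr = rng.normal(sr_mean, cfg.stutter_sr_sd)
                sr = min(max(sr, 0.0), stutter_model.cap(st))
                if sr <= 0:
                    continue
                pos = stutter_position(allele, st, locus_rec.repeat_bp)
                stutter_add[pos] = stutter_add.get(pos, 0.0) + sr * parent_h
        for pos, h in stutter_add.items():
            add(pos, h)

        # drop-in
        if rng.random() < cfg.drop_in_rate:
            if cfg.drop_in_law == "uniform":
                h = float(rng.uniform(cfg.drop_in_floor, cfg.drop_in_cap))
            else:
                h = cfg.drop_in_floor + float(rng.exponential(cfg.drop_in_scale))
            h = min(h, cfg.drop_in_cap)
            if freqs is not None and locus in freqs.freq_by_locus:
                alleles = freqs.alleles(locus)
                p = np.array([freqs.frequency(locus, a) for a in alleles])
                allele = float(rng.choice(np.array(alleles), p=p / p.sum()))
            else:
                allele = float(rng.integers(6, 21))
            add(allele, h)

        peaks = []
        for allele, h in heights.items():
            h = min(h, cfg.saturation)
            if h < cfg.call_floor:
                continue
            peaks.append(Peak(allele=allele, height=h, size=locus_rec.size_of(allele)))
        peaks_by_locus[locus] = sorted(peaks, key=lambda p: p.allele)

    return Epg(
        sample_id=sample_id,
        peaks_by_locus=peaks_by_locus,
        cell_count=sum(c for _, c in donors),
        truth=[d.donor_id for d, c in donors if c > 0],
        at_applied=False,
    )


def simulate_negative_control(
    cfg: SimulationConfig,
    panel: LocusPanel,
    seed,
    sample_id: str = "neg",
    freqs: AlleleFrequencyTable | None = None,
) -> NoiseRecord:
    """Simulate a 0-cell control: baseline trace extremes plus any drop-in."""
    rng = _rng(seed)
    highest: dict[str, float] = {}
    lowest: dict[str, float] = {}
    dyes = sorted({loc.dye for loc in panel})
    for dye in dyes:
        if cfg.baseline_sd > 0:
            trace = rng.normal(0.0, cfg.baseline_sd, size=cfg.trace_points)
            highest[dye] = float(trace.max())
            lowest[dye] = float(trace.min())
        else:
            highest[dye] = 0.0
            lowest[dye] = 0.0
    drop_in = simulate_subsample([], cfg, panel, rng, sample_id=sample_id, freqs=freqs)
    return NoiseRecord(
        sample_id=sample_id, highest_peak=highest, lowest_trough=lowest, drop_in=drop_in
    )


def perturb_profile(epg: Epg, mode: str, params: dict | None = None, panel: LocusPanel | None = None) -> Epg:
    """Apply an artificial degradation, inhibition or drop-in perturbation.

    degrade: heights of alleles above ``split_bp`` multiplied by
    ``high_factor`` (default 0.20, i.e. −80%), below by ``low_factor``
    (default 0.95, i.e. −5%).  inhibit: heights at the configured loci
    multiplied by ``factor`` (default 0.60, i.e. −40%).  drop_in: a new
    peak (default allele 8 at D5S818, 15,000 RFU) inserted; inserting onto
    an existing allele is an error since the peaks would merge.
    """
    params = dict(params or {})
    new = epg.copy()
    if mode == "degrade":
        split = float(params.get("split_bp", 220.0))
        hi = float(params.get("high_factor", 0.20))
        lo = float(params.get("low_factor", 0.95))
        for locus, peaks in new.peaks_by_locus.items():
            new.peaks_by_locus[locus] = [
                Peak(p.allele, p.height * (hi if p.size > split else lo), p.size)
                for p in peaks
            ]
    elif mode == "inhibit":
        loci = tuple(params.get("loci", INHIBITION_LOCI))
        factor = float(params.get("factor", 0.60))
        for locus in loci:
            if locus in new.peaks_by_locus:
                new.peaks_by_locus[locus] = [
                    Peak(p.allele, p.height * factor, p.size)
                    for p in new.peaks_by_locus[locus]
                ]
    elif mode == "drop_in":
        locus = str(params.get("locus", "D5S818"))
        allele = float(params.get("allele", 8.0))
        height = float(params.get("height", 15000.0))
        existing = new.peaks_by_locus.get(locus, [])
        if any(alleles_equal(p.allele, allele) for p in existing):
            raise ValueError(
                f"allele {allele} already present at {locus}: drop-in would merge"
            )
        if panel is not None and locus in panel:
            size = panel.size_of(locus, allele)
        else:
            size = float(params.get("size", 100.0))
        new.peaks_by_locus[locus] = sorted(
            existing + [Peak(allele, height, size)], key=lambda p: p.allele
        )
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    return new


def synthetic_frequencies(
    panel: LocusPanel,
    seed: int = 20230308,
    n_alleles: int = 8,
    theta: float = 0.01,
    database_size: int = 1000,
) -> AlleleFrequencyTable:
    """A plausible per-locus allele-frequency table for simulation studies.

    Allele frequencies are Dirichlet-distributed over a contiguous run of
    designations per locus, roughly triangular so that central alleles are
    common, mirroring the shape of forensic population databases.
    """
    rng = np.random.default_rng(seed)
    table: dict[str, dict[float, float]] = {}
    for locus_rec in panel:
        start = int(rng.integers(6, 12))
        alleles = [float(start + i) for i in range(n_alleles)]
        centre = (n_alleles - 1) / 2.0
        conc = np.array([8.0 - 1.5 * abs(i - centre) for i in range(n_alleles)])
        conc = np.clip(conc, 0.5, None)
        p = rng.dirichlet(conc)
        p = np.clip(p, 1e-3, None)
        p = p / p.sum()
        table[locus_rec.name] = {a: float(round(f, 5)) for a, f in zip(alleles, p)}
        # repair rounding so the locus sums to 1 within tolerance
        total = sum(table[locus_rec.name].values())
        first = alleles[0]
        table[locus_rec.name][first] = round(table[locus_rec.name][first] + (1.0 - total), 5)
    return AlleleFrequencyTable(table, theta=theta, database_size=database_size)


def clean_epg_from_reference(
    profile: ReferenceProfile,
    panel: LocusPanel,
    height: float = 1500.0,
    sample_id: str | None = None,
    cell_count: int = 3,
) -> Epg:
    """A noise-free EPG showing exactly the reference genotype at every locus."""
    peaks_by_locus: dict[str, list[Peak]] = {}
    for locus_rec in panel:
        a, b = profile.genotype(locus_rec.name)
        if alleles_equal(a, b):
            peaks = [Peak(a, 2 * height, locus_rec.size_of(a))]
        else:
            peaks = [
                Peak(a, height, locus_rec.size_of(a)),
                Peak(b, height, locus_rec.size_of(b)),
            ]
        peaks_by_locus[locus_rec.name] = peaks
    return Epg(
        sample_id=sample_id or f"clean-{profile.donor_id}",
        peaks_by_locus=peaks_by_locus,
        cell_count=cell_count,
        truth=[profile.donor_id],
        at_applied=True,
    )
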