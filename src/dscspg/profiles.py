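"""Profile domain types and pre-interpretation filtering.

An :class:`Epg` holds the called peaks of one amplification (one subsample):
per locus, a list of (allele designation, height in RFU, fragment size in
bp).  Filtering before interpretation consists of an analytical threshold
applied per dye channel and, optionally, removal of stutter types a
downstream model does not handle (e.g. half-back and double-back stutter
before a back/forward-only quantitative model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .panel import LocusPanel
from .stutter import STUTTER_OFFSETS, StutterModel, stutter_position

#: Tolerance (repeat units) for comparing allele designations after text
#: round-trips.
ALLELE_TOL = 0.05

#: Per-dye analytical thresholds of the study workflow (RFU).
DEFAULT_AT = {"Blue": 53.0, "Green": 86.0, "Yellow": 46.0, "Red": 63.0, "Purple": 63.0}


def alleles_equal(a: float, b: float, tol: float = ALLELE_TOL) -> bool:
    return abs(a - b) <= tol


@dataclass(frozen=True)
class Peak:
    """A called peak: allele designation, height (RFU), size (bp)."""

    allele: float
    height: float
    size: float

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError(f"peak height must be > 0, got {self.height}")
        if self.size <= 0:
            raise ValueError(f"peak size must be > 0, got {self.size}")


@dataclass
class AnalyticalThresholds:
    """Minimum scored peak height per dye channel (RFU)."""

    by_dye: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AT))

    def __post_init__(self) -> None:
        for dye, at in self.by_dye.items():
            if at < 0:
                raise ValueError(f"analytical threshold for {dye} must be >= 0")

    def threshold(self, dye: str) -> float:
        try:
            return self.by_dye[dye]
        except KeyError:
            raise KeyError(f"no analytical threshold configured for dye {dye!r}") from None

    @property
    def minimum(self) -> float:
        return min(self.by_dye.values())


@dataclass
class Epg:
    """One subsample's electropherogram as called peaks per locus."""

    sample_id: str
    peaks_by_locus: dict[str, list[Peak]]
    cell_count: int = 0
    truth: list[str] | None = None
    at_applied: bool = False

    def __post_init__(self) -> None:
        if self.cell_count < 0:
            raise ValueError("cell_count must be >= 0")
        for locus, peaks in self.peaks_by_locus.items():
            alleles = [p.allele for p in peaks]
            for i, a in enumerate(alleles):
                for b in alleles[i + 1 :]:
                    if alleles_equal(a, b):
                        raise ValueError(
                            f"duplicate allele {a} at locus {locus} in sample {self.sample_id}"
                        )

    def peaks(self, locus: str) -> list[Peak]:
        return self.peaks_by_locus.get(locus, [])

    def alleles(self, locus: str) -> list[float]:
        return [p.allele for p in self.peaks(locus)]

    def n_peaks(self) -> int:
        return sum(len(v) for v in self.peaks_by_locus.values())

    def copy(self) -> "Epg":
        return Epg(
            sample_id=self.sample_id,
            peaks_by_locus={k: list(v) for k, v in self.peaks_by_locus.items()},
            cell_count=self.cell_count,
            truth=list(self.truth) if self.truth is not None else None,
            at_applied=self.at_applied,
        )


@dataclass
class ReferenceProfile:
    """A typed donor: an unordered allele pair per locus (equal = homozygote)."""

    donor_id: str
    genotype_by_locus: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for locus, pair in self.genotype_by_locus.items():
            if len(pair) != 2:
                raise ValueError(f"genotype at {locus} must have exactly two alleles")
            self.genotype_by_locus[locus] = tuple(sorted(pair))  # type: ignore[assignment]

    def genotype(self, locus: str) -> tuple[float, float]:
        try:
            return self.genotype_by_locus[locus]
        except KeyError:
            raise KeyError(f"locus {locus!r} missing from reference {self.donor_id}") from None

    def is_het(self, locus: str) -> bool:
        a, b = self.genotype(locus)
        return not alleles_equal(a, b)


class AlleleFrequencyTable:
    """Per-locus allele frequencies with a theta and a rare-allele policy.

    Unobserved alleles queried through :meth:`frequency` receive the minimum
    frequency 5/(2N) for a database of N individuals (default N=1000), the
    standard forensic floor for alleles absent from the reference database.
    """

    def __init__(
        self,
        freq_by_locus: dict[str, dict[float, float]],
        theta: float = 0.01,
        database_size: int = 1000,
        validate_sums: bool = True,
    ) -> None:
        if not 0 <= theta < 1:
            raise ValueError("theta must be in [0, 1)")
        for locus, freqs in freq_by_locus.items():
            if not freqs:
                raise ValueError(f"locus {locus!r} has no alleles")
            for allele, f in freqs.items():
                if not 0 < f <= 1:
                    raise ValueError(f"frequency {f} for allele {allele} at {locus} not in (0, 1]")
            total = sum(freqs.values())
            if validate_sums and not (0.99 <= total <= 1.01):
                raise ValueError(f"frequencies at locus {locus!r} sum to {total:.4f}, not ~1")
        self.freq_by_locus = freq_by_locus
        self.theta = theta
        self.database_size = database_size

    @property
    def loci(self) -> list[str]:
        return list(self.freq_by_locus)

    @property
    def min_frequency(self) -> float:
        return 5.0 / (2.0 * self.database_size)

    def alleles(self, locus: str) -> list[float]:
        return sorted(self._locus(locus))

    def frequency(self, locus: str, allele: float) -> float:
        """Frequency of an allele; the 5/(2N) floor for unseen alleles."""
        freqs = self._locus(locus)
        for a, f in freqs.items():
            if alleles_equal(a, allele):
                return f
        return self.min_frequency

    def _locus(self, locus: str) -> dict[float, float]:
        try:
            return self.freq_by_locus[locus]
        except KeyError:
            raise KeyError(f"locus {locus!r} not in frequency table") from None


def apply_analytical_threshold(
    epg: Epg, at: AnalyticalThresholds, panel: LocusPanel
) -> Epg:
    """Remove peaks below the dye-specific analytical threshold.

    Peaks exactly at the threshold are retained (>= comparison).  Returns a
    new Epg with ``at_applied`` set; the input is unmodified.  Idempotent.
    """
    out: dict[str, list[Peak]] = {}
    for locus, peaks in epg.peaks_by_locus.items():
        threshold = at.threshold(panel.dye_of(locus))
        out[locus] = [p for p in peaks if p.height >= threshold]
    new = epg.copy()
    new.peaks_by_locus = out
    new.at_applied = True
    return new


def filter_unmodeled_stutter(
    epg: Epg,
    stutter: StutterModel,
    types_to_remove: set[str],
    panel: LocusPanel,
) -> Epg:
    """Remove peaks attributable to stutter types a downstream model ignores.

    A peak is removed when it sits at a removed-type stutter position
    relative to a strictly larger same-locus parent peak and its ratio to
    that parent does not exceed the type's max-SR cap.  Parent peaks are
    never touched.
    """
    for st in types_to_remove:
        if st not in STUTTER_OFFSETS:
            raise ValueError(f"unknown stutter type {st!r}")
    out: dict[str, list[Peak]] = {}
    for locus, peaks in epg.peaks_by_locus.items():
        repeat_bp = panel.locus(locus).repeat_bp
        kept: list[Peak] = []
        for peak in peaks:
            removed = False
            for parent in peaks:
                if parent.height <= peak.height:
                    continue
                for st in types_to_remove:
                    pos = stutter_position(parent.allele, st, repeat_bp)
                    if alleles_equal(peak.allele, pos):
                        if peak.height / parent.height <= stutter.cap(st):
                            removed = True
                            break
                if removed:
                    break
            if not removed:
                kept.append(peak)
        out[locus] = kept
    new = epg.copy()
    new.peaks_by_locus = out
    return new


def total_alleles(epg: Epg) -> int:
    """Total number of called allelic peaks across loci (profile quality)."""
    return epg.n_peaks()


def log_hb(epg: Epg, truth: ReferenceProfile, locus: str) -> tuple[float, float] | None:
    """(APH, log10 Hb) for a heterozygous locus with both sisters present.

    Hb is the larger-size allele height over the smaller-size allele height;
    APH is their mean.  Returns None when the locus is homozygous in the
    reference or either sister is missing.
    """
    if not truth.is_het(locus):
        return None
    a, b = truth.genotype(locus)
    peak_a = next((p for p in epg.peaks(locus) if alleles_equal(p.allele, a)), None)
    peak_b = next((p for p in epg.peaks(locus) if alleles_equal(p.allele, b)), None)
    if peak_a is None or peak_b is None:
        return None
    lo, hi = (peak_a, peak_b) if peak_a.size < peak_b.size else (peak_b, peak_a)
    aph = (lo.height + hi.height) / 2.0
    return aph, math.log10(hi.height / lo.height)
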