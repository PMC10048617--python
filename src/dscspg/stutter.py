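"""Stutter-ratio models.

PCR stutter produces artifact peaks at fixed repeat offsets from a parent
allele.  The stutter ratio SR = stutter height / parent allele height is
modelled per locus and stutter type, either as a linear function of parent
allele number (SR = slope * allele + intercept) or as a flat mean, with a
per-type maximum allowable SR cap.  Low-template few-cell amplification
shows strongly elevated stutter, hence the high default caps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Repeat-unit offset of each modelled stutter type relative to the parent.
STUTTER_OFFSETS: dict[str, float] = {
    "back": -1.0,
    "forward": +1.0,
    "double_back": -2.0,
    "half_back": -0.5,
    "half_forward": +0.5,
    "minus_1p5": -1.5,
}

#: Default maximum allowable stutter ratio per type (few-cell amplification).
DEFAULT_MAX_SR: dict[str, float] = {
    "back": 0.7,
    "forward": 0.7,
    "double_back": 0.3,
    "half_back": 0.5,
    "half_forward": 0.15,
    "minus_1p5": 0.15,
}

STUTTER_TYPES = tuple(STUTTER_OFFSETS)


def stutter_position(allele: float, stutter_type: str, repeat_bp: float) -> float:
    """Allele designation of the stutter position for a parent allele.

    Half-repeat offsets only have a conventional designation at
    tetranucleotide loci (offset ±0.2 in designation units = 2 bp).
    """
    offset = STUTTER_OFFSETS[stutter_type]
    whole = int(offset) if float(offset).is_integer() else None
    if whole is not None:
        return allele + whole
    # fractional repeat offset: express the basepair shift in the
    # GeneMapper fractional-designation convention (tenths = basepairs)
    bp_shift = offset * repeat_bp
    whole_repeats = int(bp_shift // repeat_bp) if bp_shift >= 0 else -int(-bp_shift // repeat_bp + (0 if (-bp_shift) % repeat_bp == 0 else 1))
    rem_bp = bp_shift - whole_repeats * repeat_bp
    return round(allele + whole_repeats + rem_bp / 10.0, 1)


@dataclass
class StutterFit:
    """Fitted SR law for one locus and stutter type."""

    kind: str  # "linear" or "mean"
    slope: float = 0.0
    intercept: float = 0.0
    mean_sr: float = 0.0
    r_squared: float = float("nan")
    n: int = 0
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def predict(self, allele: float) -> float:
        if self.kind == "linear":
            return self.slope * allele + self.intercept
        return self.mean_sr


@dataclass
class StutterModel:
    """Per-locus, per-type stutter-ratio model with max-SR caps.

    ``predict`` truncates the fitted SR to [0, cap].  Loci/types with no
    usable fit fall back to the panel-wide mean for that type (or 0).
    """

    fits: dict[str, dict[str, StutterFit]] = field(default_factory=dict)
    max_sr: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MAX_SR))

    def set_fit(self, locus: str, stutter_type: str, fit: StutterFit) -> None:
        self._check_type(stutter_type)
        self.fits.setdefault(locus, {})[stutter_type] = fit

    def get_fit(self, locus: str, stutter_type: str) -> StutterFit | None:
        self._check_type(stutter_type)
        return self.fits.get(locus, {}).get(stutter_type)

    def cap(self, stutter_type: str) -> float:
        self._check_type(stutter_type)
        return self.max_sr[stutter_type]

    def predict(self, locus: str, stutter_type: str, allele: float) -> float:
        """Expected SR for a parent allele, truncated to [0, cap]."""
        fit = self.get_fit(locus, stutter_type)
        if fit is None:
            fit = self._fallback(stutter_type)
        if fit is None:
            return 0.0
        sr = fit.predict(allele)
        return float(min(max(sr, 0.0), self.cap(stutter_type)))

    def _fallback(self, stutter_type: str) -> StutterFit | None:
        means = [
            f.predict(12.0)
            for by_type in self.fits.values()
            if (f := by_type.get(stutter_type)) is not None
        ]
        if not means:
            return None
        return StutterFit(kind="mean", mean_sr=float(sum(means) / len(means)))

    def _check_type(self, stutter_type: str) -> None:
        if stutter_type not in STUTTER_OFFSETS:
            raise ValueError(f"unknown stutter type {stutter_type!r}")


def simple_stutter_model(
    back_slope: float = 0.012,
    back_intercept: float = -0.06,
    forward_mean: float = 0.03,
    double_back_mean: float = 0.01,
    loci: list[str] | None = None,
) -> StutterModel:
    """A generic stutter model applied uniformly across loci.

    Convenience constructor for simulation defaults: back stutter linear in
    allele number, forward and double-back flat.
    """
    model = StutterModel()
    for locus in loci or []:
        model.set_fit(locus, "back", StutterFit("linear", slope=back_slope, intercept=back_intercept))
        model.set_fit(locus, "forward", StutterFit("mean", mean_sr=forward_mean))
        model.set_fit(locus, "double_back", StutterFit("mean", mean_sr=double_back_mean))
    return model
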