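"""STR locus panels.

A :class:`LocusPanel` describes the typed loci of an amplification kit: the
dye channel each locus is read in, its repeat-unit length, and an affine
allele-number → fragment-size mapping ``size = base_bp + repeat_bp * allele``.
The default panel is the 21 autosomal STR loci of a GlobalFiler-style
six-dye multiplex (sex-typing and Y markers are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

DYE_CHANNELS = ("Blue", "Green", "Yellow", "Red", "Purple")

#: Loci with simple (uninterrupted) repeat structure, suitable for
#: saturation diagnostics via back-stutter back-calculation.
SIMPLE_REPEAT_LOCI = frozenset(
    {"D16S539", "CSF1PO", "TPOX", "D5S818", "D13S317", "D7S820", "D10S1248"}
)


@dataclass(frozen=True)
class Locus:
    """One STR locus: name, dye, repeat length and size mapping."""

    name: str
    dye: str
    repeat_bp: float
    base_bp: float
    simple_repeat: bool = False

    def __post_init__(self) -> None:
        if self.dye not in DYE_CHANNELS:
            raise ValueError(f"unknown dye channel {self.dye!r} for locus {self.name}")
        if self.repeat_bp <= 0:
            raise ValueError(f"repeat_bp must be > 0 for locus {self.name}")

    def size_of(self, allele: float) -> float:
        """Fragment size (bp) of an allele designation.

        Fractional designations (e.g. 9.3) follow GeneMapper convention:
        the fractional part is a basepair count, not a repeat fraction.
        """
        whole = int(allele)
        frac_bp = round((allele - whole) * 10)
        return self.base_bp + self.repeat_bp * whole + frac_bp


@dataclass
class LocusPanel:
    """Ordered collection of loci with unique names."""

    loci: list[Locus] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        self._by_name = {loc.name: loc for loc in self.loci}

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def locus(self, name: str) -> Locus:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"locus {name!r} not in panel") from None

    def dye_of(self, name: str) -> str:
        return self.locus(name).dye

    def size_of(self, name: str, allele: float) -> float:
        return self.locus(name).size_of(allele)


def _gf(name: str, dye: str, repeat: float, base: float) -> Locus:
    return Locus(name, dye, repeat, base, simple_repeat=name in SIMPLE_REPEAT_LOCI)


def default_panel() -> LocusPanel:
    """The 21 autosomal loci of a GlobalFiler-style panel.

    Size mappings are affine approximations adequate for dye assignment,
    degradation curves and molecular-weight ordering; they are not
    instrument bin definitions.
    """
    return LocusPanel(
        [
            _gf("D3S1358", "Blue", 4, 63),
            _gf("vWA", "Blue", 4, 100),
            _gf("D16S539", "Blue", 4, 212),
            _gf("CSF1PO", "Blue", 4, 277),
            _gf("TPOX", "Blue", 4, 309),
            _gf("D8S1179", "Green", 4, 167),
            _gf("D21S11", "Green", 4, 85),
            _gf("D18S51", "Green", 4, 197),
            _gf("D2S441", "Yellow", 4, 128),
            _gf("D19S433", "Yellow", 4, 46),
            _gf("TH01", "Yellow", 4, 145),
            _gf("FGA", "Yellow", 4, 128),
            _gf("D22S1045", "Red", 3, 55),
            _gf("D5S818", "Red", 4, 90),
            _gf("D13S317", "Red", 4, 172),
            _gf("D7S820", "Red", 4, 221),
            _gf("SE33", "Purple", 4, 234),
            _gf("D10S1248", "Purple", 4, 42),
            _gf("D1S1656", "Purple", 4, 115),
            _gf("D12S391", "Purple", 4, 142),
            _gf("D2S1338", "Purple", 4, 220),
        ]
    )
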