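"""Delimited-text readers and writers.

Two genotype-table dialects are accepted, auto-detected from the header:

* **wide** (genotyping-software export style): one row per sample per
  marker with numbered parallel columns ``Allele 1..k``, ``Height 1..k``,
  ``Size 1..k``;
* **long**: one row per peak with columns ``Sample,Marker,Allele,Height,Size``.

Frequency tables are long-format ``Locus,Allele,Frequency`` files.  All
files are comma-delimited UTF-8 with a header row.
"""

from __future__ import annotations

import csv
from pathlib import Path

import yaml

from .panel import Locus, LocusPanel
from .profiles import AlleleFrequencyTable, Epg, Peak
from .simulate import SimulationConfig
from .stutter import StutterFit, StutterModel


def parse_allele(text: str) -> float:
    return float(text)


def format_allele(allele: float) -> str:
    if float(allele).is_integer():
        return str(int(allele))
    return f"{allele:.1f}"


def _format_num(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# genotype tables


def read_genotype_table(path: str | Path, panel: LocusPanel) -> list[Epg]:
    """Read a genotype table (wide or long dialect) into Epgs.

    Loci of the panel absent from the file are present in each Epg as
    empty peak lists.  Unknown marker names and ragged allele/height/size
    arity are errors.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        return _parse_genotype_rows(fh, panel)


def _parse_genotype_rows(fh, panel: LocusPanel) -> list[Epg]:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        return []
    header = [h.strip() for h in header]
    wide = any(h.lower().startswith("allele ") for h in header)
    samples: dict[str, dict[str, list[Peak]]] = {}
    order: list[str] = []

    def peaks_of(sample: str) -> dict[str, list[Peak]]:
        if sample not in samples:
            samples[sample] = {}
            order.append(sample)
        return samples[sample]

    lower = [h.lower() for h in header]

    def col(*names: str) -> int:
        for name in names:
            if name in lower:
                return lower.index(name)
        raise ValueError(f"missing column {names[0]!r} in genotype table")

    i_sample = col("sample name", "sample")
    i_marker = col("marker", "locus")
    if wide:
        allele_cols = [i for i, h in enumerate(lower) if h.startswith("allele ")]
        height_cols = [i for i, h in enumerate(lower) if h.startswith("height ")]
        size_cols = [i for i, h in enumerate(lower) if h.startswith("size ")]
    else:
        i_allele = col("allele")
        i_height = col("height")
        i_size = col("size")

    for row_num, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        sample = row[i_sample].strip()
        marker = row[i_marker].strip()
        if marker not in panel:
            raise ValueError(f"unknown marker {marker!r} at row {row_num}")
        by_locus = peaks_of(sample)
        if wide:
            vals = lambda cols: [row[i].strip() for i in cols if i < len(row) and row[i].strip()]
            alleles, heights, sizes = vals(allele_cols), vals(height_cols), vals(size_cols)
            if not (len(alleles) == len(heights) == len(sizes)):
                raise ValueError(
                    f"allele/height/size arity mismatch at row {row_num}: "
                    f"{len(alleles)}/{len(heights)}/{len(sizes)}"
                )
            peaks = [
                Peak(parse_allele(a), float(h), float(s))
                for a, h, s in zip(alleles, heights, sizes)
            ]
            by_locus.setdefault(marker, []).extend(peaks)
        else:
            by_locus.setdefault(marker, []).append(
                Peak(parse_allele(row[i_allele]), float(row[i_height]), float(row[i_size]))
            )

    out = []
    for sample in order:
        by_locus = {name: samples[sample].get(name, []) for name in panel.names}
        out.append(Epg(sample_id=sample, peaks_by_locus=by_locus))
    return out


def write_genotype_table(
    epgs: list[Epg], path: str | Path, dialect: str = "wide"
) -> None:
    """Write Epgs as a genotype table in the wide or long dialect."""
    if dialect not in ("wide", "long"):
        raise ValueError("dialect must be 'wide' or 'long'")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if dialect == "long":
            writer.writerow(["Sample", "Marker", "Allele", "Height", "Size"])
            for epg in epgs:
                for locus, peaks in epg.peaks_by_locus.items():
                    for p in peaks:
                        writer.writerow(
                            [epg.sample_id, locus, format_allele(p.allele),
                             _format_num(p.height), _format_num(p.size)]
                        )
        else:
            k = max(
                (len(peaks) for epg in epgs for peaks in epg.peaks_by_locus.values()),
                default=1,
            )
            k = max(k, 1)
            header = ["Sample Name", "Marker"]
            header += [f"Allele {i}" for i in range(1, k + 1)]
            header += [f"Height {i}" for i in range(1, k + 1)]
            header += [f"Size {i}" for i in range(1, k + 1)]
            writer.writerow(header)
            for epg in epgs:
                for locus, peaks in epg.peaks_by_locus.items():
                    pad = [""] * (k - len(peaks))
                    row = [epg.sample_id, locus]
                    row += [format_allele(p.allele) for p in peaks] + pad
                    row += [_format_num(p.height) for p in peaks] + pad
                    row += [_format_num(p.size) for p in peaks] + pad
                    writer.writerow(row)


# ---------------------------------------------------------------------------
# frequency tables


def read_frequency_table(
    path: str | Path, theta: float = 0.01, database_size: int = 1000
) -> AlleleFrequencyTable:
    """Read a ``Locus,Allele,Frequency`` table.

    Frequencies outside (0, 1] and duplicate (locus, allele) rows are
    errors; per-locus sums are validated to within 1%.
    """
    table: dict[str, dict[float, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        reader.fieldnames = [f.strip().lower() for f in reader.fieldnames or []]
        for row_num, row in enumerate(reader, start=2):
            locus = row["locus"].strip()
            allele = parse_allele(row["allele"])
            freq = float(row["frequency"])
            if not 0 < freq <= 1:
                raise ValueError(
                    f"frequency {freq} not in (0, 1] at row {row_num} ({locus} allele {allele})"
                )
            by_allele = table.setdefault(locus, {})
            if allele in by_allele:
                raise ValueError(f"duplicate entry for {locus} allele {allele} at row {row_num}")
            by_allele[allele] = freq
    return AlleleFrequencyTable(table, theta=theta, database_size=database_size)


def write_frequency_table(freqs: AlleleFrequencyTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Locus", "Allele", "Frequency"])
        for locus in freqs.loci:
            for allele in freqs.alleles(locus):
                writer.writerow([locus, format_allele(allele), repr(freqs.frequency(locus, allele))])


# ---------------------------------------------------------------------------
# panel and run-configuration files


def read_panel(path: str | Path) -> LocusPanel:
    """Read a YAML panel description (list of locus records)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    loci = [
        Locus(
            name=rec["name"],
            dye=rec["dye"],
            repeat_bp=float(rec["repeat_bp"]),
            base_bp=float(rec["base_bp"]),
            simple_repeat=bool(rec.get("simple_repeat", False)),
        )
        for rec in data["loci"]
    ]
    return LocusPanel(loci)


def write_panel(panel: LocusPanel, path: str | Path) -> None:
    data = {
        "loci": [
            {
                "name": loc.name,
                "dye": loc.dye,
                "repeat_bp": loc.repeat_bp,
                "base_bp": loc.base_bp,
                "simple_repeat": loc.simple_repeat,
            }
            for loc in panel
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_run_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML run-configuration file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return simulation_config_from_dict(data)


def simulation_config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    stutter_spec = data.pop("stutter", None)
    if data.get("dropout_shape") is not None:
        data["dropout_shape"] = tuple(data["dropout_shape"])
    cfg = SimulationConfig(**data)
    if stutter_spec:
        model = StutterModel()
        model.max_sr.update(stutter_spec.get("max_sr") or {})
        for locus, by_type in (stutter_spec.get("fits") or {}).items():
            for st, fit in by_type.items():
                model.set_fit(locus, st, StutterFit(**fit))
        cfg.stutter = model
    return cfg


def save_run_config(cfg: SimulationConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
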