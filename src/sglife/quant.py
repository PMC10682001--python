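"""Data model, readers and record-level filtering for quantitative proteomics tables.

The central container is :class:`IntensityMatrix`: a proteins x samples table of
TMT reporter intensities plus per-protein record metadata and a per-sample
design (time point, replicate, bait). Two pull-down datasets ("G3BP1" and
"CAPRIN1") are handled as separate matrices that share the protein universe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TIME_LABELS",
    "HS_WINDOW_LABELS",
    "SampleDesign",
    "ProteinRecord",
    "IntensityMatrix",
    "QuantLoadError",
    "read_design_table",
    "read_quant_table",
    "write_quant_table",
    "prefilter_records",
    "read_gene_list",
    "annotate_membership",
]

#: Canonical ordering of the heat-shock / recovery conditions.
TIME_LABELS = ("HS0", "HS10", "HS20", "HS30", "HS60", "HS120", "HS180", "Re5", "Re10", "SGls")

#: The HS10..Re10 window used by the fold-change rule and the SG-ls score.
HS_WINDOW_LABELS = ("HS10", "HS20", "HS30", "HS60", "HS120", "HS180", "Re5", "Re10")

_MINUTES = {
    "HS0": 0.0, "HS10": 10.0, "HS20": 20.0, "HS30": 30.0, "HS60": 60.0,
    "HS120": 120.0, "HS180": 180.0, "Re5": 5.0, "Re10": 10.0,
}
_PHASE = {"Re5": "recovery", "Re10": "recovery", "SGls": "sgls"}
_COMBAT_GROUP = {
    "HS0": "early", "HS10": "early",
    "HS20": "middle", "HS30": "middle", "HS60": "middle",
    "HS120": "late", "HS180": "late", "Re5": "late", "Re10": "late",
    # SG-ls columns carry their own covariate level: they are unstressed
    # condensates, not part of the heat-shock course.
    "SGls": "sgls",
}


class QuantLoadError(ValueError):
    """Raised for malformed quant/design tables (names the offending column/row)."""


@dataclass(frozen=True)
class SampleDesign:
    """One labeled TMT channel: condition, replicate and bait."""

    sample_id: str
    time_label: str
    replicate: int
    bait: str

    def __post_init__(self) -> None:
        if self.time_label not in TIME_LABELS:
            raise QuantLoadError(f"unknown time label {self.time_label!r} for sample {self.sample_id!r}")
        if self.bait not in ("G3BP1", "CAPRIN1"):
            raise QuantLoadError(f"unknown bait {self.bait!r} for sample {self.sample_id!r}")
        if self.replicate < 1:
            raise QuantLoadError(f"replicate must be >=1 for sample {self.sample_id!r}")
        if self.time_label == "SGls" and self.bait != "G3BP1":
            raise QuantLoadError(f"SGls sample {self.sample_id!r} must belong to the G3BP1 pull-down")

    @property
    def minutes(self) -> float | None:
        """Heat-shock (or recovery) minutes; None for SG-ls samples."""
        return _MINUTES.get(self.time_label)

    @property
    def phase(self) -> str:
        return _PHASE.get(self.time_label, "hs")

    @property
    def combat_group(self) -> str:
        return _COMBAT_GROUP[self.time_label]


@dataclass(frozen=True)
class ProteinRecord:
    """Per-protein identification metadata used by the prefilter."""

    accession: str
    gene_name: str = ""
    is_mitochondrial: bool = False
    is_keratin: bool = False
    fdr_confidence: str = "high"
    unique_peptides_per_replicate: tuple[int, ...] = ()


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity table with design metadata.

    ``values`` is a float array of shape ``(len(records), len(samples))``;
    missing measurements are NaN, retained values are >= 0.
    """

    records: list[ProteinRecord]
    samples: list[SampleDesign]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.records), len(self.samples)):
            raise QuantLoadError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.records)} records x {len(self.samples)} samples"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise QuantLoadError(f"duplicate sample ids: {dup}")
        acc = [r.accession for r in self.records]
        if len(set(acc)) != len(acc):
            dup = sorted({a for a in acc if acc.count(a) > 1})
            raise QuantLoadError(f"duplicate accessions: {dup}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise QuantLoadError("negative intensities are not allowed")

    # -- convenience accessors -------------------------------------------------

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accessions, columns=self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise KeyError(sample_id)

    def columns_for(self, time_label: str) -> list[int]:
        return [i for i, s in enumerate(self.samples) if s.time_label == time_label]

    def time_label_means(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        """Replicate-mean intensity per time label (NaN-aware mean over channels)."""
        labels = list(labels) if labels is not None else [
            t for t in TIME_LABELS if self.columns_for(t)
        ]
        out = {}
        for t in labels:
            cols = self.columns_for(t)
            if not cols:
                raise KeyError(f"no samples with time label {t!r}")
            block = self.values[:, cols]
            counts = np.isfinite(block).sum(axis=1)
            sums = np.nansum(block, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            out[t] = means
        return pd.DataFrame(out, index=self.accessions)

    def subset_records(self, keep: Sequence[int]) -> "IntensityMatrix":
        keep = list(keep)
        return IntensityMatrix(
            records=[self.records[i] for i in keep],
            samples=list(self.samples),
            values=self.values[keep, :].copy(),
        )

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(list(self.records), list(self.samples), self.values.copy())


# -- readers / writers ---------------------------------------------------------

_RECORD_COLUMNS = [
    "accession", "gene_name", "is_mitochondrial", "is_keratin",
    "fdr_confidence", "unique_peptides",
]


def read_design_table(path: str | Path) -> list[SampleDesign]:
    """Read a sample-design TSV with columns sample_id, time_label, replicate, bait."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "time_label", "replicate", "bait"}
    missing = required - set(df.columns)
    if missing:
        raise QuantLoadError(f"design table {path} missing columns {sorted(missing)}")
    designs = []
    for _, row in df.iterrows():
        designs.append(SampleDesign(
            sample_id=str(row["sample_id"]).strip(),
            time_label=str(row["time_label"]).strip(),
            replicate=int(row["replicate"]),
            bait=str(row["bait"]).strip(),
        ))
    return designs


def _parse_bool(x: object, column: str, row: str) -> bool:
    s = str(x).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no", "", "nan"):
        return False
    raise QuantLoadError(f"unparseable boolean {x!r} in column {column!r}, row {row!r}")


def read_quant_table(path: str | Path, design_path: str | Path) -> IntensityMatrix:
    """Read a protein quant TSV against a sample-design table.

    The first columns hold record fields (see ``_RECORD_COLUMNS``); every
    remaining column must name a sample in the design. "NA"/empty cells are
    preserved as missing.
    """
    designs = read_design_table(design_path)
    by_id = {d.sample_id: d for d in designs}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=["NA", "nan", ""])
    missing_rec = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing_rec:
        raise QuantLoadError(f"quant table {path} missing record columns {missing_rec}")
    sample_cols = [c for c in df.columns if c not in _RECORD_COLUMNS]
    unknown = [c for c in sample_cols if c not in by_id]
    if unknown:
        raise QuantLoadError(f"quant table column(s) {unknown} absent from design table")

    records: list[ProteinRecord] = []
    for _, row in df.iterrows():
        acc = str(row["accession"]).strip() if pd.notna(row["accession"]) else ""
        if not acc:
            raise QuantLoadError("row with empty accession")
        pep_field = row["unique_peptides"]
        peps: tuple[int, ...]
        if pd.isna(pep_field) or str(pep_field).strip() == "":
            peps = ()
        else:
            try:
                peps = tuple(int(p) for p in re.split(r"[;,]", str(pep_field)) if p.strip() != "")
            except ValueError as e:
                raise QuantLoadError(f"bad unique_peptides {pep_field!r} for {acc}") from e
        records.append(ProteinRecord(
            accession=acc,
            gene_name="" if pd.isna(row["gene_name"]) else str(row["gene_name"]).strip(),
            is_mitochondrial=_parse_bool(row["is_mitochondrial"], "is_mitochondrial", acc),
            is_keratin=_parse_bool(row["is_keratin"], "is_keratin", acc),
            fdr_confidence=("high" if pd.isna(row["fdr_confidence"])
                            else str(row["fdr_confidence"]).strip().lower()),
            unique_peptides_per_replicate=peps,
        ))

    try:
        values = df[sample_cols].astype(float).to_numpy()
    except ValueError as e:
        raise QuantLoadError(f"non-numeric intensity in {path}: {e}") from e
    samples = [by_id[c] for c in sample_cols]
    return IntensityMatrix(records=records, samples=samples, values=values)


def write_quant_table(m: IntensityMatrix, path: str | Path) -> None:
    """Write an IntensityMatrix back to the TSV interchange format (round-trips)."""
    rows = []
    for rec, vals in zip(m.records, m.values):
        row: dict[str, object] = {
            "accession": rec.accession,
            "gene_name": rec.gene_name,
            "is_mitochondrial": rec.is_mitochondrial,
            "is_keratin": rec.is_keratin,
            "fdr_confidence": rec.fdr_confidence,
            "unique_peptides": ";".join(str(p) for p in rec.unique_peptides_per_replicate),
        }
        for s, v in zip(m.samples, vals):
            row[s.sample_id] = "" if not np.isfinite(v) else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


# -- filtering -----------------------------------------------------------------

@dataclass
class FilterTally:
    """Per-rule count of removed records. A record removed by several rules is
    counted under each rule it fails."""

    low_fdr: int = 0
    low_unique_peptides: int = 0
    mitochondrial: int = 0
    keratin: int = 0
    no_gene_name: int = 0

    @property
    def total_removed(self) -> int:
        return self._removed

    _removed: int = field(default=0, repr=False)


def prefilter_records(
    m: IntensityMatrix,
    min_unique_peptides: int = 1,
    require_high_fdr: bool = True,
) -> tuple[IntensityMatrix, FilterTally]:
    """Apply the identification-quality and contaminant filters.

    Removes records with non-high FDR confidence, any replicate below
    ``min_unique_peptides`` unique peptides, mitochondrial proteins, keratins,
    and records without an annotated gene name. Returns the filtered copy and
    a per-rule removal tally.
    """
    tally = FilterTally()
    keep: list[int] = []
    removed = 0
    for i, rec in enumerate(m.records):
        bad = False
        if require_high_fdr and rec.fdr_confidence != "high":
            tally.low_fdr += 1
            bad = True
        if rec.unique_peptides_per_replicate and any(
            p < min_unique_peptides for p in rec.unique_peptides_per_replicate
        ):
            tally.low_unique_peptides += 1
            bad = True
        if rec.is_mitochondrial:
            tally.mitochondrial += 1
            bad = True
        if rec.is_keratin:
            tally.keratin += 1
            bad = True
        if not rec.gene_name.strip():
            tally.no_gene_name += 1
            bad = True
        if bad:
            removed += 1
        else:
            keep.append(i)
    tally._removed = removed
    return m.subset_records(keep), tally


# -- annotation lists ----------------------------------------------------------

def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list ('#' comments allowed), upper-cased."""
    symbols: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.add(line.upper())
    if not symbols:
        raise QuantLoadError(f"gene list {path} is empty")
    return symbols


def annotate_membership(
    gene_names: Iterable[str], reference_list: str | Path | set[str]
) -> tuple[dict[str, bool], int]:
    """Flag each gene for membership in a reference list (case-insensitive exact
    symbol match); returns per-gene flags and the overlap count."""
    ref = reference_list if isinstance(reference_list, set) else read_gene_list(reference_list)
    ref = {g.strip().upper() for g in ref}
    flags = {g: g.strip().upper() in ref for g in gene_names}
    return flags, sum(flags.values())
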