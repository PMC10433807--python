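"""Readers, writers and validated containers for the tabular and sequence
formats the pipeline touches.

The central objects are :class:`FeatureTable` (ASV read counts with derived
relative abundances), :class:`DyadCohort` (the mother-infant pairing
structure every downstream stage consumes) and :class:`GenomeSet`
(assemblies or a whole-genome alignment with dyad labels).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SAMPLE_TYPES = ("maternal_vaginal", "infant_stool")
TIME_POINTS = ("delivery", "10_days", "3_months")
DELIVERY_MODES = ("vaginal", "elective_CS", "emergency_CS")
ANTIBIOTIC_LEVELS = ("exposed", "unexposed", "unknown")

IUPAC_GAP = set("ACGTRYSWKMBDHVN-acgtryswkmbdhvn.")


class ValidationError(ValueError):
    """Raised when an input file violates the documented contract."""


@dataclass
class FeatureTable:
    """Read counts per (sample, ASV) with derived relative abundances.

    ``counts`` is a samples x ASVs DataFrame of non-negative integers.
    ``rel_abundance`` is derived as count / sample total; rows for samples
    with zero total reads are all-zero and listed in ``zero_total_samples``.
    """

    counts: pd.DataFrame
    rel_abundance: pd.DataFrame = field(init=False)
    zero_total_samples: list[str] = field(init=False)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate ASV identifiers: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("feature table contains non-numeric cells")
        if (arr < 0).any():
            raise ValidationError("feature table contains negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("feature table contains non-integer counts")
        self.counts = c.astype(np.int64)
        totals = self.counts.sum(axis=1)
        self.zero_total_samples = totals.index[totals == 0].tolist()
        safe = totals.replace(0, 1)
        self.rel_abundance = self.counts.div(safe, axis=0).astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def asv_ids(self) -> list[str]:
        return self.counts.columns.tolist()


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample: which dyad it belongs to and its labels."""

    sample_id: str
    dyad_id: str
    sample_type: str
    time_point: str
    delivery_mode: str = "vaginal"
    ip_antibiotics: str = "unknown"

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"{self.sample_id}: sample_type {self.sample_type!r} not in {SAMPLE_TYPES}"
            )
        if self.time_point not in TIME_POINTS:
            raise ValidationError(
                f"{self.sample_id}: time_point {self.time_point!r} not in {TIME_POINTS}"
            )
        if self.sample_type == "maternal_vaginal" and self.time_point != "delivery":
            raise ValidationError(
                f"{self.sample_id}: maternal samples must have time_point 'delivery'"
            )
        if self.delivery_mode not in DELIVERY_MODES:
            raise ValidationError(
                f"{self.sample_id}: delivery_mode {self.delivery_mode!r} not in {DELIVERY_MODES}"
            )
        if self.ip_antibiotics not in ANTIBIOTIC_LEVELS:
            raise ValidationError(
                f"{self.sample_id}: ip_antibiotics {self.ip_antibiotics!r} not in {ANTIBIOTIC_LEVELS}"
            )


@dataclass
class Dyad:
    """One mother-infant pair: a maternal sample and up to two infant samples."""

    dyad_id: str
    maternal: str
    ten_day: str | None = None
    three_month: str | None = None
    delivery_mode: str = "vaginal"
    ip_antibiotics: str = "unknown"

    @property
    def infant_samples(self) -> dict[str, str]:
        out = {}
        if self.ten_day is not None:
            out["10_days"] = self.ten_day
        if self.three_month is not None:
            out["3_months"] = self.three_month
        return out

    @property
    def has_infant(self) -> bool:
        return bool(self.infant_samples)


@dataclass
class DyadCohort:
    """Dyad-structured view of the cohort.

    ``dyads`` holds only dyads eligible for transfer analysis (maternal
    sample plus at least one infant sample); dyads excluded for lack of
    infant samples are counted in ``report``.
    """

    dyads: dict[str, Dyad]
    report: dict[str, int]

    def __len__(self) -> int:
        return len(self.dyads)

    def group_labels(self, column: str) -> dict[str, str]:
        """Per-dyad value of a grouping column (delivery_mode / ip_antibiotics)."""
        return {d.dyad_id: getattr(d, column) for d in self.dyads.values()}


@dataclass
class TaxonomyTable:
    """ASV -> (taxon label, percent identity to closest reference)."""

    taxa: dict[str, tuple[str, float]]

    def __post_init__(self) -> None:
        for asv, (_, pct) in self.taxa.items():
            if not 0 <= pct <= 100:
                raise ValidationError(f"{asv}: percent identity {pct} outside [0, 100]")

    def label(self, asv_id: str) -> str:
        return self.taxa.get(asv_id, ("unassigned", float("nan")))[0]

    def pct_identity(self, asv_id: str) -> float:
        return self.taxa.get(asv_id, ("unassigned", float("nan")))[1]


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    sequence: str
    dyad_id: str | None = None
    origin: str | None = None  # maternal | infant
    species: str | None = None
    delivery_mode: str | None = None


@dataclass
class GenomeSet:
    """A collection of genome sequences, optionally a whole-genome alignment."""

    records: dict[str, GenomeRecord]
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("empty genome set")
        for rec in self.records.values():
            if not rec.sequence:
                raise ValidationError(f"{rec.genome_id}: empty sequence")
            bad = set(rec.sequence) - IUPAC_GAP
            if bad:
                raise ValidationError(
                    f"{rec.genome_id}: illegal characters {sorted(bad)!r}"
                )
        if self.aligned:
            lengths = {len(r.sequence) for r in self.records.values()}
            if len(lengths) > 1:
                raise ValidationError(
                    f"alignment mode requires equal lengths, got {sorted(lengths)}"
                )

    @property
    def genome_ids(self) -> list[str]:
        return list(self.records)

    def relabel(self, labels: Mapping[str, Mapping[str, str | None]]) -> "GenomeSet":
        """Attach dyad/origin/species labels from a mapping keyed by genome_id."""
        new = {}
        for gid, rec in self.records.items():
            info = labels.get(gid, {})
            new[gid] = dataclasses.replace(
                rec,
                dyad_id=info.get("dyad_id", rec.dyad_id),
                origin=info.get("origin", rec.origin),
                species=info.get("species", rec.species),
                delivery_mode=info.get("delivery_mode", rec.delivery_mode),
            )
        return GenomeSet(records=new, aligned=self.aligned)


# ---------------------------------------------------------------------------
# readers / writers


def read_feature_table(
    path: str | Path, orientation: str = "samples_as_rows", sep: str = "\t"
) -> FeatureTable:
    """Read an ASV count table from TSV/CSV.

    ``orientation`` declares whether samples are rows or columns; the file's
    layout is never guessed.
    """
    if orientation not in ("samples_as_rows", "samples_as_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "samples_as_columns":
        df = df.T
    for col in df.columns:
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValidationError(
                f"non-numeric cell at row {bad.index[0]!r}, column {col!r}: {bad.iloc[0]!r}"
            )
    return FeatureTable(counts=df)


def write_feature_table(table: FeatureTable, path: str | Path, sep: str = "\t") -> None:
    table.counts.to_csv(path, sep=sep)


def read_sample_meta(path: str | Path, sep: str = "\t") -> list[SampleMeta]:
    """Read sample metadata TSV with the SampleMeta column names."""
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("unknown")
    required = {"sample_id", "dyad_id", "sample_type", "time_point"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    fields = [f.name for f in dataclasses.fields(SampleMeta)]
    return [
        SampleMeta(**{k: row[k] for k in fields if k in df.columns})
        for _, row in df.iterrows()
    ]


def write_sample_meta(meta: Iterable[SampleMeta], path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame([dataclasses.asdict(m) for m in meta]).to_csv(path, sep=sep, index=False)


def read_taxonomy(path: str | Path, sep: str = "\t") -> TaxonomyTable:
    """Read a taxonomy TSV with columns asv_id, taxon, pct_identity."""
    df = pd.read_csv(path, sep=sep, dtype={"asv_id": str, "taxon": str})
    if df["asv_id"].duplicated().any():
        raise ValidationError("duplicate asv_id rows in taxonomy table")
    return TaxonomyTable(
        taxa={
            str(r.asv_id): (str(r.taxon), float(r.pct_identity))
            for r in df.itertuples()
        }
    )


def build_cohort(table: FeatureTable, meta: Iterable[SampleMeta]) -> DyadCohort:
    """Assemble dyads from sample metadata, validating against the table.

    Every metadata ``sample_id`` must exist in the feature table (hard
    error otherwise). Extra table samples are allowed and reported. Dyads
    without any infant sample are excluded from the transfer analysis but
    counted in the validation report, as are infant samples referencing a
    dyad with no maternal sample (dropped with a warning).
    """
    meta = list(meta)
    table_samples = set(table.sample_ids)
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in metadata")
    missing = [i for i in ids if i not in table_samples]
    if missing:
        raise ValidationError(
            f"metadata references sample_ids absent from the table: {missing[:5]}"
        )

    by_dyad: dict[str, list[SampleMeta]] = {}
    for m in meta:
        by_dyad.setdefault(m.dyad_id, []).append(m)

    dyads: dict[str, Dyad] = {}
    n_no_infant = 0
    n_orphan_infants = 0
    n_by_availability = {"10_days_only": 0, "3_months_only": 0, "both": 0}
    for dyad_id, members in sorted(by_dyad.items()):
        maternal = [m for m in members if m.sample_type == "maternal_vaginal"]
        infants = [m for m in members if m.sample_type == "infant_stool"]
        if len(maternal) > 1:
            raise ValidationError(f"dyad {dyad_id}: {len(maternal)} maternal samples")
        if not maternal:
            n_orphan_infants += len(infants)
            warnings.warn(
                f"dyad {dyad_id}: infant sample(s) with no maternal sample, dropped",
                stacklevel=2,
            )
            continue
        by_tp: dict[str, str] = {}
        for m in infants:
            if m.time_point in by_tp:
                raise ValidationError(
                    f"dyad {dyad_id}: two infant samples at {m.time_point}"
                )
            by_tp[m.time_point] = m.sample_id
        mm = maternal[0]
        if not by_tp:
            n_no_infant += 1
            continue
        if "10_days" in by_tp and "3_months" in by_tp:
            n_by_availability["both"] += 1
        elif "10_days" in by_tp:
            n_by_availability["10_days_only"] += 1
        else:
            n_by_availability["3_months_only"] += 1
        dyads[dyad_id] = Dyad(
            dyad_id=dyad_id,
            maternal=mm.sample_id,
            ten_day=by_tp.get("10_days"),
            three_month=by_tp.get("3_months"),
            delivery_mode=mm.delivery_mode,
            ip_antibiotics=mm.ip_antibiotics,
        )
    report = {
        "n_dyads": len(dyads),
        "n_dyads_no_infant_excluded": n_no_infant,
        "n_orphan_infant_samples_dropped": n_orphan_infants,
        "n_table_samples_without_metadata": len(table_samples - set(ids)),
        **{f"n_dyads_{k}": v for k, v in n_by_availability.items()},
    }
    return DyadCohort(dyads=dyads, report=report)


def read_alignment(path: str | Path, aligned: bool = True) -> GenomeSet:
    """Read a (multi-)FASTA of genomes; ``aligned=True`` enforces equal lengths."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"duplicate genome id {rec.id!r}")
        records[rec.id] = GenomeRecord(genome_id=rec.id, sequence=str(rec.seq))
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return GenomeSet(records=records, aligned=aligned)


def write_fasta(genomes: GenomeSet, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=gid, description="")
        for gid, r in genomes.records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_genome_labels(path: str | Path, sep: str = "\t") -> dict[str, dict[str, str | None]]:
    """Read a genome labels TSV: genome_id, dyad_id, origin[, species, delivery_mode]."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    out: dict[str, dict[str, str | None]] = {}
    for _, row in df.iterrows():
        out[row["sample_id"] if "sample_id" in row else row["genome_id"]] = {
            k: (None if pd.isna(row.get(k)) else row.get(k))
            for k in ("dyad_id", "origin", "species", "delivery_mode")
        }
    return out


def read_gene_matrix(
    path: str | Path, dialect: str = "binary", first_genome_column: int | None = None
) -> pd.DataFrame:
    """Read a gene presence/absence matrix as genes x genomes booleans.

    ``dialect='binary'`` expects a plain 0/1 CSV with gene rows and genome
    columns. ``dialect='roary'`` expects a Roary ``gene_presence_absence.csv``
    where metadata columns precede genome columns; ``first_genome_column``
    gives the 0-based index of the first genome column (Roary's default
    layout has 14 metadata columns) and any non-empty cell marks presence.
    """
    if dialect == "binary":
        df = pd.read_csv(path, index_col=0)
        return df.astype(float).astype(bool)
    if dialect == "roary":
        idx = 14 if first_genome_column is None else first_genome_column
        df = pd.read_csv(path, index_col=0, dtype=str)
        genome_cols = df.columns[idx - 1 :]  # index_col consumed one column
        return df[genome_cols].notna() & (df[genome_cols] != "")
    raise ValueError(f"unknown gene matrix dialect {dialect!r}")


def write_gene_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.astype(int).to_csv(path)
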