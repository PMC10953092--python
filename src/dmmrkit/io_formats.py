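"""Readers/writers for the tabular and sequence formats the pipeline consumes.

All TSVs are UTF-8, tab-delimited; lines starting with ``#`` are comments.
Genomic positions are 1-based inclusive in files (VCF convention) and
converted to 0-based half-open coordinates at this boundary.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .sbs96 import SBS96_CONTEXTS

MISSING = "n.A"


class TableValidationError(ValueError):
    """A file violated its schema; the message names the offending cell."""


# ---------------------------------------------------------------------------
# Cohort table (clinical staging/grading)
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "id", "sex", "age_arrival", "age_death", "diagnosis_mode", "fob",
    "imaging", "t_stage", "n_stage", "m_stage", "grade", "fibrosis",
    "subtype", "localization", "comorbidities",
)


@dataclass(frozen=True)
class CohortTableDialect:
    """Column names and coded values of the clinical cohort TSV."""

    columns: tuple[str, ...] = COHORT_COLUMNS
    sex_codes: tuple[str, ...] = ("f", "m")
    diagnosis_codes: tuple[str, ...] = ("Biopsy", "Necropsy")
    fob_codes: tuple[str, ...] = ("pos", "neg")
    fibrosis_codes: tuple[str, ...] = ("pos", "neg")
    imaging_separator: str = " & "
    stage_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "t_stage": (0, 4), "n_stage": (0, 2), "m_stage": (0, 1),
            "grade": (1, 3),
        }
    )


DEFAULT_DIALECT = CohortTableDialect()


@dataclass(frozen=True)
class ClinicalRecord:
    """One animal's staging, grading and clinical flags."""

    id: str
    sex: str | None
    age_arrival: float | None
    age_death: float | None
    diagnosis_mode: str | None  # "biopsy" | "necropsy"
    fob: str | None             # "pos" | "neg" | None (missing)
    imaging: frozenset[str]
    t_stage: int | None
    n_stage: int | None
    m_stage: int | None
    grade: int | None
    fibrosis: str | None
    subtype: str | None
    localization: str | None
    comorbidities: str | None

    def __post_init__(self) -> None:
        if (
            self.age_arrival is not None
            and self.age_death is not None
            and self.age_death < self.age_arrival
        ):
            raise TableValidationError(
                f"{self.id}: age_death {self.age_death} < age_arrival "
                f"{self.age_arrival}"
            )


def _missing(token: str) -> bool:
    return token.strip() in ("", MISSING)


def _read_tsv_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    with open(path, encoding="utf-8", newline="") as handle:
        lines = [ln for ln in handle if not ln.startswith("#") and ln.strip()]
    reader = csv.reader(io.StringIO("".join(lines)), delimiter="\t")
    rows = list(reader)
    if not rows:
        raise TableValidationError(f"{path}: empty file, header required")
    return rows[0], rows[1:]


def read_cohort_table(
    path: str | Path, dialect: CohortTableDialect = DEFAULT_DIALECT
) -> list[ClinicalRecord]:
    header, rows = _read_tsv_rows(path)
    if tuple(header) != dialect.columns:
        raise TableValidationError(
            f"{path}: header {header} does not match dialect "
            f"{list(dialect.columns)}"
        )
    records: list[ClinicalRecord] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows, start=2):
        cell = dict(zip(dialect.columns, row))

        def fail(column: str, msg: str) -> TableValidationError:
            return TableValidationError(
                f"{path}:{lineno} column {column!r}: {msg}"
            )

        rid = cell.get("id", "").strip()
        if not rid:
            raise fail("id", "empty animal ID")
        if rid in seen:
            raise fail("id", f"duplicate animal ID {rid!r}")
        seen.add(rid)

        def coded(column: str, codes: tuple[str, ...]) -> str | None:
            token = cell.get(column, "")
            if _missing(token):
                return None
            if token not in codes:
                raise fail(column, f"unknown code {token!r}, expected {codes}")
            return token

        def number(column: str) -> float | None:
            token = cell.get(column, "")
            if _missing(token):
                return None
            try:
                return float(token)
            except ValueError:
                raise fail(column, f"not a number: {token!r}") from None

        def stage(column: str) -> int | None:
            token = cell.get(column, "")
            if _missing(token):
                return None
            lo, hi = dialect.stage_ranges[column]
            try:
                value = int(token)
            except ValueError:
                raise fail(column, f"not an integer: {token!r}") from None
            if not lo <= value <= hi:
                raise fail(column, f"{value} outside [{lo}, {hi}]")
            return value

        diagnosis = coded("diagnosis_mode", dialect.diagnosis_codes)
        imaging_token = cell.get("imaging", "")
        imaging = (
            frozenset()
            if _missing(imaging_token)
            else frozenset(
                part.strip()
                for part in imaging_token.split(dialect.imaging_separator)
            )
        )
        free = {
            col: (None if _missing(cell.get(col, "")) else cell[col].strip())
            for col in ("subtype", "localization", "comorbidities")
        }
        records.append(
            ClinicalRecord(
                id=rid,
                sex=coded("sex", dialect.sex_codes),
                age_arrival=number("age_arrival"),
                age_death=number("age_death"),
                diagnosis_mode=diagnosis.lower() if diagnosis else None,
                fob=coded("fob", dialect.fob_codes),
                imaging=imaging,
                t_stage=stage("t_stage"),
                n_stage=stage("n_stage"),
                m_stage=stage("m_stage"),
                grade=stage("grade"),
                fibrosis=coded("fibrosis", dialect.fibrosis_codes),
                **free,
            )
        )
    return records


def write_cohort_table(
    records: Iterable[ClinicalRecord],
    path: str | Path,
    dialect: CohortTableDialect = DEFAULT_DIALECT,
) -> None:
    def encode(value: object) -> str:
        if value is None:
            return MISSING
        return str(value)

    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(dialect.columns)
        for rec in records:
            imaging = (
                dialect.imaging_separator.join(sorted(rec.imaging))
                if rec.imaging
                else MISSING
            )
            diagnosis = (
                rec.diagnosis_mode.capitalize() if rec.diagnosis_mode else None
            )
            writer.writerow(
                [
                    rec.id,
                    encode(rec.sex),
                    encode(rec.age_arrival),
                    encode(rec.age_death),
                    encode(diagnosis),
                    encode(rec.fob),
                    imaging,
                    encode(rec.t_stage),
                    encode(rec.n_stage),
                    encode(rec.m_stage),
                    encode(rec.grade),
                    encode(rec.fibrosis),
                    encode(rec.subtype),
                    encode(rec.localization),
                    encode(rec.comorbidities),
                ]
            )


# ---------------------------------------------------------------------------
# Variant tables and minimal VCF
# ---------------------------------------------------------------------------

_PROTEIN_RE = re.compile(r"^p\.([A-Z])(\d+)(?:([A-Z])?(_fs)|([A-Z])|(\*))$")


@dataclass(frozen=True)
class ProteinChange:
    """Parsed HGVS-p-style token: ``p.<refAA><pos>(<altAA>|*|[<altAA>]_fs)``.

    For frameshifts ``alt`` is ``"fs"``; the first altered residue (the AA
    printed before ``_fs``, if any) is kept in ``fs_residue`` for display.
    """

    ref_aa: str
    position: int
    alt: str  # single amino acid, "*" (stop gain) or "fs" (frameshift)
    fs_residue: str | None = None

    @property
    def is_frameshift(self) -> bool:
        return self.alt == "fs"

    @property
    def is_stop_gain(self) -> bool:
        return self.alt == "*"

    def __str__(self) -> str:
        if self.alt == "fs":
            suffix = (self.fs_residue or "") + "_fs"
        else:
            suffix = self.alt
        return f"p.{self.ref_aa}{self.position}{suffix}"


def parse_protein_change(token: str) -> ProteinChange:
    match = _PROTEIN_RE.match(token.strip())
    if match is None:
        raise TableValidationError(f"unparseable protein change: {token!r}")
    ref_aa, pos, fs_residue, fs, alt_aa, stop = match.groups()
    position = int(pos)
    if position < 1:
        raise TableValidationError(f"protein position must be >= 1: {token!r}")
    if fs:
        return ProteinChange(
            ref_aa=ref_aa, position=position, alt="fs", fs_residue=fs_residue
        )
    alt = alt_aa if alt_aa else "*"
    return ProteinChange(ref_aa=ref_aa, position=position, alt=alt)


COMPARTMENTS = ("somatic", "germline")
VARIANT_CLASSES = ("SNV", "insertion", "deletion", "other")


@dataclass(frozen=True)
class VariantRecord:
    """One variant, from a curated table or a VCF.

    ``pos`` is 1-based (file convention); ``pos0`` exposes the 0-based
    coordinate for internal arithmetic.
    """

    sample: str
    gene: str | None = None
    protein_change: ProteinChange | None = None
    compartment: str = "somatic"
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    variant_class: str | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise TableValidationError(
                f"compartment must be one of {COMPARTMENTS}: "
                f"{self.compartment!r}"
            )
        if self.variant_class == "SNV":
            if (
                self.ref is None or self.alt is None
                or len(self.ref) != 1 or len(self.alt) != 1
                or self.ref == self.alt
            ):
                raise TableValidationError(
                    f"SNV requires single differing ref/alt bases, got "
                    f"{self.ref!r}>{self.alt!r}"
                )

    @property
    def pos0(self) -> int | None:
        return None if self.pos is None else self.pos - 1


VARIANT_COLUMNS = ("sample", "gene", "protein_change", "compartment")


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    header, rows = _read_tsv_rows(path)
    required = set(VARIANT_COLUMNS)
    if not required.issubset(header):
        raise TableValidationError(
            f"{path}: header must contain {sorted(required)}, got {header}"
        )
    records = []
    for lineno, row in enumerate(rows, start=2):
        cell = dict(zip(header, row))
        try:
            change = parse_protein_change(cell["protein_change"])
        except TableValidationError as exc:
            raise TableValidationError(f"{path}:{lineno}: {exc}") from None
        genomic = {}
        if cell.get("chrom") and not _missing(cell.get("chrom", "")):
            genomic = dict(
                chrom=cell["chrom"],
                pos=int(cell["pos"]),
                ref=cell["ref"],
                alt=cell["alt"],
            )
        records.append(
            VariantRecord(
                sample=cell["sample"],
                gene=cell["gene"],
                protein_change=change,
                compartment=cell["compartment"],
                **genomic,
            )
        )
    return records


def write_variant_table(
    records: Iterable[VariantRecord], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.sample, rec.gene, str(rec.protein_change),
                 rec.compartment]
            )


def fetch_sequence(
    genome: Mapping[str, object], chrom: str, start0: int, end0: int
) -> str:
    """Fetch [start0, end0) from a pyfaidx.Fasta or a plain dict of strings."""
    try:
        contig = genome[chrom]
    except KeyError:
        raise TableValidationError(
            f"contig {chrom!r} missing from genome"
        ) from None
    if start0 < 0:
        raise IndexError(f"negative start {start0} on {chrom}")
    seq = str(contig[start0:end0]).upper()
    if len(seq) != end0 - start0:
        raise IndexError(
            f"window [{start0}, {end0}) beyond end of {chrom}"
        )
    return seq


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1 and ref != alt and alt in "ACGT":
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "other"


def read_vcf_minimal(
    path: str | Path,
    genome: Mapping[str, object],
    sample: str | None = None,
) -> list[VariantRecord]:
    """Read an uncompressed VCF into variant records.

    Multi-allelic records are split; REF alleles are validated against the
    genome. SNVs are eligible for spectrum analysis; indels are flagged and
    passed through for burden counting.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        default_sample = sample or (
            list(vcf.header.samples)[0] if vcf.header.samples else Path(path).stem
        )
        for rec in vcf:
            ref = rec.ref.upper()
            observed = fetch_sequence(
                genome, rec.chrom, rec.pos - 1, rec.pos - 1 + len(ref)
            )
            if observed != ref:
                raise TableValidationError(
                    f"{path}: REF mismatch at {rec.chrom}:{rec.pos} "
                    f"(VCF {ref!r}, genome {observed!r})"
                )
            for alt in rec.alts or ():
                records.append(
                    VariantRecord(
                        sample=default_sample,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=ref,
                        alt=alt.upper(),
                        variant_class=classify_alleles(ref, alt.upper()),
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Signature matrices (96 x n)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignatureMatrix:
    """Named SBS96 signatures; each column sums to one."""

    table: pd.DataFrame  # index: canonical contexts; columns: signature names

    def __post_init__(self) -> None:
        if list(self.table.index) != list(SBS96_CONTEXTS):
            raise TableValidationError(
                "signature matrix index must be the canonical SBS96 order"
            )
        values = self.table.to_numpy()
        if (values < 0).any():
            raise TableValidationError("negative entry in signature matrix")
        sums = values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise TableValidationError(
                f"signature columns must sum to 1 within 1e-6, got {sums}"
            )

    @property
    def names(self) -> list[str]:
        return list(self.table.columns)

    def vector(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if frame.shape[0] != 96:
        raise TableValidationError(
            f"{path}: expected 96 context rows, got {frame.shape[0]}"
        )
    missing = set(SBS96_CONTEXTS) - set(frame.index)
    if missing:
        raise TableValidationError(
            f"{path}: missing contexts, e.g. {sorted(missing)[:3]}"
        )
    frame = frame.loc[list(SBS96_CONTEXTS)].astype(float)
    if (frame.to_numpy() < 0).any():
        raise TableValidationError(f"{path}: negative entry")
    sums = frame.sum(axis=0)
    off = (sums - 1.0).abs()
    if (off >= 1e-3).any():
        bad = sums[off >= 1e-3]
        raise TableValidationError(
            f"{path}: column sums deviate from 1 by >= 1e-3: {dict(bad)}"
        )
    frame = frame / sums
    return SignatureMatrix(table=frame)


def write_signature_matrix(matrix: SignatureMatrix, path: str | Path) -> None:
    matrix.table.to_csv(path, sep="\t", index_label="context")


# ---------------------------------------------------------------------------
# Aligned binding-site sets (FASTA)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteSet:
    """Equal-length aligned binding sites for one motif."""

    name: str
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise TableValidationError(f"site set {self.name!r} is empty")
        length = len(self.sequences[0])
        if length < 4:
            raise TableValidationError(
                f"site set {self.name!r}: sites shorter than 4 bp"
            )
        for seq in self.sequences:
            if len(seq) != length:
                raise TableValidationError(
                    f"site set {self.name!r}: unequal site lengths"
                )
            if set(seq) - set("ACGT"):
                raise TableValidationError(
                    f"site set {self.name!r}: non-ACGT base in {seq!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0])


def read_site_set(path: str | Path, name: str | None = None) -> SiteSet:
    sequences = tuple(
        str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    )
    return SiteSet(name=name or Path(path).stem, sequences=sequences)


# ---------------------------------------------------------------------------
# qPCR plate tables
# ---------------------------------------------------------------------------

UNDETERMINED = "undetermined"
WELL_ROLES = (
    "methylation-specific", "control", "expression", "reference-gene"
)
TISSUES = ("tumor", "normal", "calibrator")


@dataclass(frozen=True)
class QpcrWell:
    sample: str
    tissue: str
    assay: str
    role: str
    ct: float | None  # None encodes "undetermined"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise TableValidationError(f"unknown tissue {self.tissue!r}")
        if self.role not in WELL_ROLES:
            raise TableValidationError(f"unknown well role {self.role!r}")
        if self.ct is not None and self.ct <= 0:
            raise TableValidationError(
                f"Ct must be positive or {UNDETERMINED!r}, got {self.ct}"
            )


PLATE_COLUMNS = ("sample", "tissue", "assay", "role", "ct", "replicate")


def read_qpcr_plate(path: str | Path) -> list[QpcrWell]:
    header, rows = _read_tsv_rows(path)
    if not set(PLATE_COLUMNS[:5]).issubset(header):
        raise TableValidationError(
            f"{path}: header must contain {PLATE_COLUMNS[:5]}"
        )
    wells = []
    for lineno, row in enumerate(rows, start=2):
        cell = dict(zip(header, row))
        token = cell["ct"].strip().lower()
        ct = None if token == UNDETERMINED else float(cell["ct"])
        try:
            wells.append(
                QpcrWell(
                    sample=cell["sample"],
                    tissue=cell["tissue"],
                    assay=cell["assay"],
                    role=cell["role"],
                    ct=ct,
                    replicate=int(cell.get("replicate", 1) or 1),
                )
            )
        except TableValidationError as exc:
            raise TableValidationError(f"{path}:{lineno}: {exc}") from None
    _check_plate_controls(wells, path)
    return wells


def _check_plate_controls(wells: Sequence[QpcrWell], path: str | Path) -> None:
    with_ms = {
        (w.sample, w.tissue) for w in wells if w.role == "methylation-specific"
    }
    with_control = {(w.sample, w.tissue) for w in wells if w.role == "control"}
    orphans = with_ms - with_control
    if orphans:
        raise TableValidationError(
            f"{path}: samples with methylation-specific wells but no control "
            f"assay: {sorted(orphans)}"
        )


def write_qpcr_plate(wells: Iterable[QpcrWell], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PLATE_COLUMNS)
        for w in wells:
            ct = UNDETERMINED if w.ct is None else f"{w.ct:.6g}"
            writer.writerow(
                [w.sample, w.tissue, w.assay, w.role, ct, w.replicate]
            )


# ---------------------------------------------------------------------------
# Packaged fixtures (in-paper tables)
# ---------------------------------------------------------------------------


def _fixture_path(filename: str) -> Path:
    return Path(resources.files("dmmrkit.data") / filename)


def load_cohort_fixture() -> list[ClinicalRecord]:
    """The packaged 24-animal clinical cohort table."""
    return read_cohort_table(_fixture_path("table1_cohort.tsv"))


def load_variant_fixture() -> list[VariantRecord]:
    """The packaged per-tumor curated variant table (16 tumors)."""
    return read_variant_table(_fixture_path("table2_variants.tsv"))


def load_tmb_fixture() -> pd.DataFrame:
    """Per-tumor mutational burden values (sample, tmb_mut_per_mbp)."""
    return pd.read_csv(
        _fixture_path("table2_tmb.tsv"), sep="\t", comment="#"
    )
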