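"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (config, seed) built on
``numpy.random.default_rng`` and emits a ground-truth sidecar so recovery
tests never re-derive truth. The default cohort mirrors the structure of
the study it emulates: 16 tumors, MLH1 hypermethylated in all of them,
mixed CIMP markers, mostly MSI-high samples and an SBS6-like spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import sbs96
from .io_formats import (
    ClinicalRecord,
    QpcrWell,
    SignatureMatrix,
    SiteSet,
    VariantRecord,
    classify_alleles,
)
from .methylation_cimp import CIMP_PANEL, MLH1_PROBES
from .msi_calling import DEFAULT_PANEL
from .shape_topology import (
    EXTENDED_COMPLEMENT,
    PentamerShape,
    ShapeTable,
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# TFAP2A-like palindromic consensus with a CpG at offset 4 and two
# degenerate positions for site-to-site variety.
DEFAULT_MOTIF_CONSENSUS = "GCCYCGGGCR"
DEFAULT_MOTIF_CPG_OFFSET = 4


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    cohort_size: int = 16
    # microsatellite traces
    instability_prob: float = 0.8
    stutter_ratio: float = 0.15
    # variants
    snv_count: int = 2000
    genome_length: int = 100_000
    gc_fraction: float = 0.5
    signature_weights: tuple[float, ...] | None = None  # default SBS6-like
    # qPCR
    qpcr_sigma: float = 0.2
    qpcr_efficiency: float = 1.0  # 1.0 = perfect doubling
    mlh1_tumor_fraction: float = 0.8
    cimp_marker_prob: float = 0.5
    # shape
    prot_shift: float = -4.0
    roll_shift: float = 3.0
    motif_consensus: str = DEFAULT_MOTIF_CONSENSUS
    motif_cpg_offset: int = DEFAULT_MOTIF_CPG_OFFSET
    promoter_length: int = 2000

    def __post_init__(self) -> None:
        for name in ("instability_prob", "gc_fraction", "cimp_marker_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.qpcr_sigma < 0:
            raise ValueError("qpcr_sigma must be nonnegative")
        if self.signature_weights is not None:
            w = np.asarray(self.signature_weights, dtype=float)
            if w.shape != (96,) or (w < 0).any():
                raise ValueError("signature_weights must be 96 nonnegatives")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("signature_weights must sum to 1")


# ---------------------------------------------------------------------------
# Signature weights and a small reference signature matrix
# ---------------------------------------------------------------------------


def sbs6_like_weights() -> np.ndarray:
    """C>T-dominated weights with a strong NCG enrichment."""
    w = np.full(96, 0.0025)
    for i, label in enumerate(sbs96.SBS96_CONTEXTS):
        if "[C>T]" in label:
            w[i] += 0.015
            if label.endswith("G"):
                w[i] += 0.12
    return w / w.sum()


def _block_weights(substitution: str) -> np.ndarray:
    w = np.full(96, 0.001)
    for i, label in enumerate(sbs96.SBS96_CONTEXTS):
        if f"[{substitution}]" in label:
            w[i] += 0.05
    return w / w.sum()


def default_signature_matrix() -> SignatureMatrix:
    """A compact 5-signature reference panel for matching tests and demos."""
    columns = {
        "SBS6like": sbs6_like_weights(),
        "CtoA": _block_weights("C>A"),
        "TtoC": _block_weights("T>C"),
        "TtoG": _block_weights("T>G"),
        "Flat": np.full(96, 1.0 / 96.0),
    }
    frame = pd.DataFrame(columns, index=list(sbs96.SBS96_CONTEXTS))
    return SignatureMatrix(table=frame)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


def gen_reference_sequence(length: int, gc: float, seed: int) -> str:
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc fraction must lie in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                handle.write(seq[i : i + 80] + "\n")


def gen_reference_fasta(
    length: int, gc: float, seed: int, path: str | Path, name: str = "chrS"
) -> dict[str, str]:
    genome = {name: gen_reference_sequence(length, gc, seed)}
    write_fasta(genome, path)
    return genome


# ---------------------------------------------------------------------------
# Variants drawn from trinucleotide-context weights
# ---------------------------------------------------------------------------


def _context_index(
    genome: Mapping[str, str]
) -> dict[str, list[tuple[str, int, bool]]]:
    """Map collapsed pyrimidine trinucleotide -> (chrom, pos0, on_pyr_strand)."""
    index: dict[str, list[tuple[str, int, bool]]] = {}
    for chrom, seq in genome.items():
        seq = seq.upper()
        for i in range(1, len(seq) - 1):
            tri = seq[i - 1 : i + 2]
            if set(tri) - set("ACGT"):
                continue
            if tri[1] in "CT":
                index.setdefault(tri, []).append((chrom, i, True))
            else:
                index.setdefault(sbs96.reverse_complement(tri), []).append(
                    (chrom, i, False)
                )
    return index


def gen_variants(
    genome: Mapping[str, str],
    n: int,
    weights: Sequence[float] | None,
    seed: int,
    sample: str = "S1",
) -> list[VariantRecord]:
    """Draw SNVs by sampling an SBS96 category, then a uniform matching
    genomic context; REF always agrees with the genome."""
    w = (
        sbs6_like_weights()
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if w.shape != (96,) or (w < 0).any():
        raise ValueError("weights must be 96 nonnegative values")
    w = w / w.sum()
    index = _context_index(genome)
    for i in np.flatnonzero(w > 0):
        label = sbs96.SBS96_CONTEXTS[i]
        key = label[0] + label[2] + label[6]
        if key not in index:
            raise ValueError(
                f"no genomic context available for weighted category {label}"
            )
    rng = np.random.default_rng(seed)
    draws = rng.choice(96, size=n, p=w)
    records = []
    for i in draws:
        label = sbs96.SBS96_CONTEXTS[i]
        key = label[0] + label[2] + label[6]
        alt_pyr = label[4]
        sites = index[key]
        chrom, pos0, on_pyr = sites[rng.integers(len(sites))]
        ref = genome[chrom][pos0]
        alt = alt_pyr if on_pyr else sbs96.COMPLEMENT[alt_pyr]
        records.append(
            VariantRecord(
                sample=sample,
                chrom=chrom,
                pos=pos0 + 1,
                ref=ref,
                alt=alt,
                variant_class=classify_alleles(ref, alt),
            )
        )
    return sorted(records, key=lambda r: (r.chrom, r.pos))


def write_vcf(
    records: Sequence[VariantRecord],
    genome: Mapping[str, str],
    path: str | Path,
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        for chrom, seq in genome.items():
            handle.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            handle.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\n"
            )


# ---------------------------------------------------------------------------
# Microsatellite traces
# ---------------------------------------------------------------------------

_LOCUS_BASE_LENGTH = {
    locus: 100 + 12 * i for i, locus in enumerate(DEFAULT_PANEL)
}


def _ladder(
    allele: int, amplitude: float, stutter_ratio: float
) -> dict[int, float]:
    """Main peak plus a two-rung geometric stutter shoulder."""
    return {
        allele: amplitude,
        allele - 1: amplitude * stutter_ratio,
        allele - 2: amplitude * stutter_ratio**2,
    }


def gen_msi_traces(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired healthy/tumor traces plus a ground-truth table.

    Unstable tumor loci gain a novel allele shifted by 2-4 bp (either
    direction, shortening favored) on top of the retained normal allele.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    truth = []
    for s in range(1, config.cohort_size + 1):
        sample = f"SIM_{s}"
        n_unstable = 0
        for locus in DEFAULT_PANEL:
            allele = _LOCUS_BASE_LENGTH[locus]
            unstable = bool(rng.random() < config.instability_prob)
            normal = _ladder(allele, 100.0, config.stutter_ratio)
            tumor = _ladder(allele, 60.0, config.stutter_ratio)
            shift = 0
            if unstable:
                shift = int(rng.choice([-4, -3, -2, -2, 2, 3]))
                for length, value in _ladder(
                    allele + shift, 80.0, config.stutter_ratio
                ).items():
                    tumor[length] = tumor.get(length, 0.0) + value
                n_unstable += 1
            for tissue, trace in (("normal", normal), ("tumor", tumor)):
                for length in sorted(trace):
                    rows.append(
                        (sample, tissue, locus, length, round(trace[length], 4))
                    )
            truth.append((sample, locus, int(unstable), shift))
        truth_category = (
            "MSS" if n_unstable == 0
            else "MSI-low" if n_unstable == 1
            else "MSI-high"
        )
        truth.append((sample, "__category__", n_unstable, truth_category))
    traces = pd.DataFrame(
        rows, columns=["sample", "tissue", "locus", "length_bp", "intensity"]
    )
    truth_frame = pd.DataFrame(
        truth, columns=["sample", "locus", "unstable_or_count", "shift_or_category"]
    )
    return traces, truth_frame


# ---------------------------------------------------------------------------
# qPCR plates from known methylation fractions
# ---------------------------------------------------------------------------

CONTROL_ASSAY = "ACTB"
_MS_INTERCEPT = 24.0
_CONTROL_INTERCEPT = 21.0


def gen_qpcr_plate(
    fractions: Mapping[tuple[str, str, str], float],
    sigma: float = 0.2,
    efficiency: float = 1.0,
    seed: int = 0,
    replicates: int = 1,
) -> list[QpcrWell]:
    """Wells simulated from known (sample, tissue, marker) -> fraction.

    Ct = intercept - log2(input * fraction) / log2(1 + efficiency) + noise;
    a fraction of exactly 0 yields an undetermined Ct. Calibrator wells
    (fraction 1) and per-sample control wells are appended automatically.
    ``replicates`` emits that many wells per assay with independent noise.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    slope = np.log2(1.0 + efficiency)
    wells: list[QpcrWell] = []

    def noise() -> float:
        return float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0

    def emit(sample: str, tissue: str, assay: str, role: str,
             true_ct: float | None) -> None:
        for rep in range(1, replicates + 1):
            ct = None if true_ct is None else true_ct + noise()
            wells.append(
                QpcrWell(
                    sample=sample, tissue=tissue, assay=assay, role=role,
                    ct=ct, replicate=rep,
                )
            )

    markers = sorted({marker for _, _, marker in fractions})
    for (sample, tissue, marker), fraction in sorted(fractions.items()):
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"fraction must lie in [0, 1]: {fraction}")
        true_ct = (
            None if fraction == 0.0
            else _MS_INTERCEPT - float(np.log2(fraction)) / slope
        )
        emit(sample, tissue, marker, "methylation-specific", true_ct)
    for sample, tissue in sorted({(s, t) for s, t, _ in fractions}):
        emit(sample, tissue, CONTROL_ASSAY, "control", _CONTROL_INTERCEPT)
    for marker in markers:
        emit("calibrator", "calibrator", marker, "methylation-specific",
             _MS_INTERCEPT)
    emit("calibrator", "calibrator", CONTROL_ASSAY, "control",
         _CONTROL_INTERCEPT)
    return wells


def gen_cohort_methylation(
    config: SimulationConfig, seed: int | None = None
) -> tuple[dict[tuple[str, str, str], float], pd.DataFrame]:
    """Per-sample methylation fractions with universal MLH1 hypermethylation
    and mixed CIMP markers, plus the implied truth table."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fractions: dict[tuple[str, str, str], float] = {}
    truth_rows = []
    other_markers = [m for m in CIMP_PANEL if m != "MLH1_probe1"]
    for s in range(1, config.cohort_size + 1):
        sample = f"SIM_{s}"
        n_methylated = 1  # MLH1 probe 1 is methylated by construction
        for probe in MLH1_PROBES:
            tumor = config.mlh1_tumor_fraction + rng.uniform(-0.05, 0.1)
            fractions[(sample, "tumor", probe)] = float(np.clip(tumor, 0, 1))
            fractions[(sample, "normal", probe)] = 0.02
        for marker in other_markers:
            methylated = bool(rng.random() < config.cimp_marker_prob)
            tumor = (
                float(rng.uniform(0.5, 0.9)) if methylated
                else float(rng.uniform(0.0, 0.08))
            )
            fractions[(sample, "tumor", marker)] = tumor
            fractions[(sample, "normal", marker)] = 0.02
            n_methylated += int(methylated)
            truth_rows.append((sample, marker, int(methylated)))
        category = (
            "negative" if n_methylated <= 2
            else "low" if n_methylated == 3
            else "high"
        )
        truth_rows.append((sample, "__category__", category))
        truth_rows.append((sample, "MLH1_probe1", 1))
    truth = pd.DataFrame(truth_rows, columns=["sample", "marker", "truth"])
    return fractions, truth


# ---------------------------------------------------------------------------
# Motif sites, shape tables, promoters
# ---------------------------------------------------------------------------


def expand_consensus(consensus: str) -> list[str]:
    """Per-position allowed bases of an IUPAC consensus."""
    try:
        return [IUPAC[c] for c in consensus.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in consensus: {exc}") from None


def gen_motif_sites(
    consensus: str, n: int, seed: int, name: str = "motif"
) -> SiteSet:
    """Sample aligned sites uniformly over each position's allowed bases."""
    allowed = expand_consensus(consensus)
    rng = np.random.default_rng(seed)
    sequences = tuple(
        "".join(bases[rng.integers(len(bases))] for bases in allowed)
        for _ in range(n)
    )
    return SiteSet(name=name, sequences=sequences)


def _demethylate(pentamer: str) -> str:
    return pentamer.replace("M", "C").replace("W", "G")


def gen_shape_table(
    seed: int,
    prot_shift: float = -4.0,
    roll_shift: float = 3.0,
) -> ShapeTable:
    """A complete, strand-symmetric pentamer table over ACGTMW.

    Plain pentamers get random values in physically plausible ranges;
    pentamers containing M/W inherit the values of their demethylated
    counterpart with the declared ProT and Roll effect sizes applied.
    """
    rng = np.random.default_rng(seed)
    values: dict[str, PentamerShape] = {}
    bases = "ACGT"
    plain = [
        a + b + c + d + e
        for a in bases for b in bases for c in bases
        for d in bases for e in bases
    ]
    for penta in plain:
        if penta in values:
            continue
        shape = PentamerShape(
            mgw=float(rng.uniform(4.0, 6.5)),
            prot=float(rng.uniform(-16.0, -4.0)),
            helt1=float(rng.uniform(31.0, 38.0)),
            helt2=float(rng.uniform(31.0, 38.0)),
            roll1=float(rng.uniform(-4.0, 8.0)),
            roll2=float(rng.uniform(-4.0, 8.0)),
        )
        values[penta] = shape
        rc = "".join(EXTENDED_COMPLEMENT[b] for b in reversed(penta))
        if rc not in values:
            values[rc] = PentamerShape(
                mgw=shape.mgw, prot=shape.prot,
                helt1=shape.helt2, helt2=shape.helt1,
                roll1=shape.roll2, roll2=shape.roll1,
            )
    extended = "ACGTMW"
    for a in extended:
        for b in extended:
            for c in extended:
                for d in extended:
                    for e in extended:
                        penta = a + b + c + d + e
                        if penta in values:
                            continue
                        base = values[_demethylate(penta)]
                        values[penta] = PentamerShape(
                            mgw=base.mgw,
                            prot=base.prot + prot_shift,
                            helt1=base.helt1,
                            helt2=base.helt2,
                            roll1=base.roll1 + roll_shift,
                            roll2=base.roll2 + roll_shift,
                        )
    return ShapeTable(values=values)


@dataclass(frozen=True)
class SyntheticPromoter:
    sequence: str
    motif_start: int  # 0-based
    motif_sequence: str
    cpg_positions: tuple[int, ...]  # CpG starts inside the motif, 0-based


def gen_promoter(
    config: SimulationConfig, seed: int | None = None
) -> SyntheticPromoter:
    """Random promoter-length sequence with one embedded motif instance
    whose CpG position is recorded."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    length = config.promoter_length
    allowed = expand_consensus(config.motif_consensus)
    motif = "".join(bases[rng.integers(len(bases))] for bases in allowed)
    offset = config.motif_cpg_offset
    if motif[offset : offset + 2] != "CG":
        raise ValueError(
            "motif consensus must fix a CpG at motif_cpg_offset"
        )
    background = "".join(
        rng.choice(list("ACGT"), size=length, p=[0.3, 0.2, 0.2, 0.3])
    )
    start = length // 2
    sequence = (
        background[:start] + motif + background[start + len(motif):]
    )
    return SyntheticPromoter(
        sequence=sequence,
        motif_start=start,
        motif_sequence=motif,
        cpg_positions=(start + offset,),
    )


# ---------------------------------------------------------------------------
# Synthetic clinical cohort
# ---------------------------------------------------------------------------


def gen_cohort_table(
    config: SimulationConfig, seed: int | None = None
) -> list[ClinicalRecord]:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = []
    for s in range(1, config.cohort_size + 1):
        age = float(np.round(rng.uniform(12.0, 26.0), 1))
        records.append(
            ClinicalRecord(
                id=f"SIM_{s}",
                sex="f" if rng.random() < 0.75 else "m",
                age_arrival=age,
                age_death=float(np.round(age + rng.uniform(0.1, 2.0), 1)),
                diagnosis_mode="biopsy" if rng.random() < 0.6 else "necropsy",
                fob=str(rng.choice(["pos", "pos", "pos", "neg"])),
                imaging=frozenset({"US", "CT"}),
                t_stage=int(rng.choice([2, 3, 3, 4])),
                n_stage=int(rng.choice([0, 0, 1])),
                m_stage=int(rng.choice([0, 0, 0, 1])),
                grade=int(rng.choice([1, 1, 2, 3])),
                fibrosis=str(rng.choice(["pos"] * 9 + ["neg"])),
                subtype="AdenoCa",
                localization="Ileocecal junction",
                comorbidities=None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic input plus truth sidecars into ``outdir``."""
    from .io_formats import write_cohort_table, write_qpcr_plate
    from .io_formats import write_signature_matrix
    from .shape_topology import write_shape_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rng = np.random.default_rng(config.seed)

    paths["reference"] = out / "reference.fa"
    genome = gen_reference_fasta(
        config.genome_length, config.gc_fraction,
        int(rng.integers(2**31)), paths["reference"],
    )

    weights = (
        sbs6_like_weights()
        if config.signature_weights is None
        else np.asarray(config.signature_weights)
    )
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for s in range(1, config.cohort_size + 1):
        sample = f"SIM_{s}"
        records = gen_variants(
            genome, config.snv_count, weights,
            int(rng.integers(2**31)), sample=sample,
        )
        write_vcf(records, genome, vcf_dir / f"{sample}.vcf")
    paths["vcf_dir"] = vcf_dir

    paths["signatures"] = out / "signatures.tsv"
    write_signature_matrix(default_signature_matrix(), paths["signatures"])

    traces, msi_truth = gen_msi_traces(config, int(rng.integers(2**31)))
    paths["traces"] = out / "traces.tsv"
    traces.to_csv(paths["traces"], sep="\t", index=False)
    paths["traces_truth"] = out / "traces.truth.tsv"
    msi_truth.to_csv(paths["traces_truth"], sep="\t", index=False)

    fractions, meth_truth = gen_cohort_methylation(
        config, int(rng.integers(2**31))
    )
    wells = gen_qpcr_plate(
        fractions, sigma=config.qpcr_sigma,
        efficiency=config.qpcr_efficiency, seed=int(rng.integers(2**31)),
    )
    paths["plate"] = out / "plate.tsv"
    write_qpcr_plate(wells, paths["plate"])
    paths["plate_truth"] = out / "plate.truth.tsv"
    meth_truth.to_csv(paths["plate_truth"], sep="\t", index=False)

    sites = gen_motif_sites(
        config.motif_consensus, 200, int(rng.integers(2**31)), name="motif"
    )
    paths["sites"] = out / "sites.fa"
    write_fasta(
        {f"site_{i}": seq for i, seq in enumerate(sites.sequences)},
        paths["sites"],
    )

    table = gen_shape_table(
        int(rng.integers(2**31)),
        prot_shift=config.prot_shift,
        roll_shift=config.roll_shift,
    )
    paths["shape_table"] = out / "shape_table.tsv"
    write_shape_table(table, paths["shape_table"])

    promoter = gen_promoter(config, int(rng.integers(2**31)))
    paths["promoter"] = out / "promoter.fa"
    write_fasta({"promoter": promoter.sequence}, paths["promoter"])
    paths["promoter_truth"] = out / "promoter.truth.tsv"
    pd.DataFrame(
        [
            (
                promoter.motif_start,
                promoter.motif_sequence,
                ",".join(map(str, promoter.cpg_positions)),
            )
        ],
        columns=["motif_start", "motif_sequence", "cpg_positions"],
    ).to_csv(paths["promoter_truth"], sep="\t", index=False)

    cohort = gen_cohort_table(config, int(rng.integers(2**31)))
    paths["cohort"] = out / "cohort.tsv"
    write_cohort_table(cohort, paths["cohort"])
    return paths
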