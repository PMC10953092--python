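"""TMB, SBS96 spectrum construction, signature matching, hotspot mapping."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import sbs96
from .io_formats import SignatureMatrix, VariantRecord, fetch_sequence


@dataclass(frozen=True)
class Sbs96Spectrum:
    """96 nonnegative substitution counts in canonical order."""

    counts: np.ndarray
    n_skipped: int = 0  # SNVs dropped for missing flank (contig edge)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (96,):
            raise ValueError("spectrum requires exactly 96 counts")
        if (counts < 0).any():
            raise ValueError("spectrum counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        total = self.total
        if total == 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return self.counts / total

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(sbs96.SBS96_CONTEXTS))


def compute_spectrum(
    variants: Sequence[VariantRecord], genome: Mapping[str, object]
) -> Sbs96Spectrum:
    """Count SNVs into pyrimidine-collapsed trinucleotide categories.

    Non-SNVs are ignored; an SNV whose flanking base falls off the contig is
    skipped and tallied in ``n_skipped``; a REF/genome disagreement raises.
    """
    counts = np.zeros(96)
    skipped = 0
    for var in variants:
        if var.variant_class != "SNV":
            continue
        pos0 = var.pos0
        assert var.chrom is not None and pos0 is not None
        try:
            context = fetch_sequence(genome, var.chrom, pos0 - 1, pos0 + 2)
        except IndexError:
            skipped += 1
            continue
        if context[1] != var.ref.upper():
            raise ValueError(
                f"REF mismatch at {var.chrom}:{var.pos}: variant "
                f"{var.ref!r}, genome {context[1]!r}"
            )
        label = sbs96.category(var.ref, var.alt, context[0], context[2])
        counts[sbs96.category_index(label)] += 1
    return Sbs96Spectrum(counts=counts, n_skipped=skipped)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("vectors must be nonnegative")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass(frozen=True)
class SignatureMatch:
    name: str
    similarity: float
    ranked: pd.DataFrame  # columns: signature, similarity (descending)
    tied: bool


def best_signature(
    spectrum: Sbs96Spectrum, matrix: SignatureMatrix, tie_tol: float = 1e-12
) -> SignatureMatch:
    """Rank signatures by cosine similarity; ties are broken
    lexicographically and flagged."""
    if not matrix.names:
        raise ValueError("empty signature matrix")
    query = spectrum.normalized()
    rows = [
        (name, cosine_similarity(query, matrix.vector(name)))
        for name in matrix.names
    ]
    ranked = pd.DataFrame(rows, columns=["signature", "similarity"])
    ranked = ranked.sort_values(
        ["similarity", "signature"], ascending=[False, True]
    ).reset_index(drop=True)
    best = ranked.iloc[0]
    tied = bool(
        len(ranked) > 1
        and ranked.iloc[1]["similarity"] >= best["similarity"] - tie_tol
    )
    return SignatureMatch(
        name=str(best["signature"]),
        similarity=float(best["similarity"]),
        ranked=ranked,
        tied=tied,
    )


@dataclass(frozen=True)
class TmbResult:
    sample: str
    n_mutations: int
    callable_mbp: float
    threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.callable_mbp <= 0:
            raise ValueError("callable size must be positive (Mbp)")

    @property
    def tmb(self) -> float:
        return self.n_mutations / self.callable_mbp

    @property
    def high(self) -> bool:
        return self.tmb > self.threshold  # strictly above the cutoff


def compute_tmb(
    variants: Sequence[VariantRecord],
    callable_mbp: float,
    threshold: float = 10.0,
    sample: str = "",
    snv_only: bool = False,
) -> TmbResult:
    """Mutations per callable megabase; indels count unless ``snv_only``."""
    eligible = ("SNV",) if snv_only else ("SNV", "insertion", "deletion")
    n = sum(
        1 for v in variants
        if v.variant_class in eligible or v.variant_class is None
    )
    return TmbResult(
        sample=sample,
        n_mutations=n,
        callable_mbp=callable_mbp,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Cross-species hotspot codon mapping
# ---------------------------------------------------------------------------

CatalogEntry = tuple[int, str, str]  # (position, refAA, altAA)


@dataclass(frozen=True)
class HotspotMatchStats:
    n_variants: int
    n_window: int
    n_same_residue: int
    n_exact_change: int
    window: int = 5

    @property
    def fraction_window(self) -> float:
        return self.n_window / self.n_variants if self.n_variants else 0.0

    @property
    def fraction_same_residue(self) -> float:
        return self.n_same_residue / self.n_variants if self.n_variants else 0.0

    @property
    def fraction_exact_change(self) -> float:
        return self.n_exact_change / self.n_variants if self.n_variants else 0.0


def match_hotspots(
    variants: Sequence[VariantRecord],
    catalog: Mapping[str, Sequence[CatalogEntry]],
    window: int = 5,
) -> HotspotMatchStats:
    """Nested match statistics against a per-gene codon catalog.

    window match: a catalog entry for the gene within +/- ``window`` codons;
    same-residue: an entry at the same position with the same reference
    amino acid; exact-change: same position, reference and alternate amino
    acid. Variants whose gene is absent from the catalog count as
    unmatched.
    """
    n = n_window = n_same = n_exact = 0
    for var in variants:
        change = var.protein_change
        if change is None:
            continue
        n += 1
        entries = catalog.get(var.gene or "", ())
        if not entries:
            continue
        if any(abs(change.position - pos) <= window for pos, _, _ in entries):
            n_window += 1
        if any(
            pos == change.position and ref == change.ref_aa
            for pos, ref, _ in entries
        ):
            n_same += 1
        if any(
            pos == change.position
            and ref == change.ref_aa
            and alt == change.alt
            for pos, ref, alt in entries
        ):
            n_exact += 1
    return HotspotMatchStats(
        n_variants=n,
        n_window=n_window,
        n_same_residue=n_same,
        n_exact_change=n_exact,
        window=window,
    )


def read_hotspot_catalog(path) -> dict[str, list[CatalogEntry]]:
    """TSV with columns gene, position, ref_aa, alt_aa."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    catalog: dict[str, list[CatalogEntry]] = {}
    for row in frame.itertuples(index=False):
        catalog.setdefault(row.gene, []).append(
            (int(row.position), row.ref_aa, row.alt_aa)
        )
    return catalog
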