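"""Microsatellite instability calling from paired amplicon-length traces.

The manual electropherogram overlay is operationalized as peak matching:
a locus is unstable when the tumor shows an amplicon length farther than
``tol_bp`` (default 1 bp, fragment-sizing resolution) from every healthy
peak. Loss of a normal allele alone does not trigger instability.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

DEFAULT_PANEL = (
    "RheBAT25", "RheBAT26", "RheBAT40",
    "RheD10S197", "RheD18S58", "RheTGFbRII",
)

MSI_CATEGORIES = ("MSS", "MSI-low", "MSI-high")


@dataclass(frozen=True)
class Electropherogram:
    sample: str
    locus: str
    points: tuple[tuple[int, float], ...]  # (amplicon length bp, intensity)

    def __post_init__(self) -> None:
        lengths = [length for length, _ in self.points]
        if lengths != sorted(set(lengths)):
            raise ValueError(
                f"{self.sample}/{self.locus}: lengths must be strictly "
                "increasing"
            )
        if any(length <= 0 for length in lengths):
            raise ValueError("amplicon lengths must be positive")
        if any(intensity < 0 for _, intensity in self.points):
            raise ValueError("intensities must be nonnegative")
        if not any(intensity > 0 for _, intensity in self.points):
            raise ValueError(
                f"{self.sample}/{self.locus}: all intensities are zero"
            )


@dataclass(frozen=True)
class PeakSet:
    locus: str
    lengths: tuple[int, ...]


@dataclass(frozen=True)
class LocusCall:
    locus: str
    status: str  # "stable" | "unstable"
    evidence: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in ("stable", "unstable"):
            raise ValueError(f"unknown locus status {self.status!r}")
        if self.status == "unstable" and not self.evidence:
            raise ValueError("unstable call requires evidence peaks")


@dataclass(frozen=True)
class MsiResult:
    sample: str
    calls: tuple[LocusCall, ...]
    category: str
    partial_panel: bool

    @property
    def n_unstable(self) -> int:
        return sum(1 for c in self.calls if c.status == "unstable")

    @property
    def n_evaluated(self) -> int:
        return len(self.calls)


def detect_peaks(
    trace: Electropherogram, rel_threshold: float = 0.10
) -> PeakSet:
    """Local maxima at or above ``rel_threshold`` of the trace maximum.

    The trace is treated as sampled on the integer-bp grid with implicit
    zeros in gaps, so isolated spikes count as peaks.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")
    intensity = {length: value for length, value in trace.points}
    ceiling = max(intensity.values())
    cutoff = rel_threshold * ceiling
    peaks = []
    for length, value in trace.points:
        if value < cutoff or value <= 0:
            continue
        left = intensity.get(length - 1, 0.0)
        right = intensity.get(length + 1, 0.0)
        # plateau tie broken toward the shorter fragment
        if value > left and value >= right:
            peaks.append(length)
    return PeakSet(locus=trace.locus, lengths=tuple(peaks))


def call_locus(
    normal: PeakSet, tumor: PeakSet, tol_bp: int = 1
) -> LocusCall:
    """Unstable iff a tumor peak lies farther than ``tol_bp`` from every
    normal peak; the evidence lists those novel lengths."""
    if normal.locus != tumor.locus:
        raise ValueError(
            f"locus mismatch: {normal.locus!r} vs {tumor.locus!r}"
        )
    if not normal.lengths or not tumor.lengths:
        raise ValueError(f"{normal.locus}: empty peak set")
    novel = tuple(
        t for t in tumor.lengths
        if all(abs(t - n) > tol_bp for n in normal.lengths)
    )
    if novel:
        return LocusCall(locus=tumor.locus, status="unstable", evidence=novel)
    return LocusCall(locus=tumor.locus, status="stable")


def classify_msi(
    calls: Sequence[LocusCall],
    sample: str = "",
    panel_size: int = len(DEFAULT_PANEL),
) -> MsiResult:
    """0 unstable loci -> MSS; 1 -> MSI-low; >= 2 -> MSI-high."""
    if not calls:
        raise ValueError("no evaluated loci")
    n_unstable = sum(1 for c in calls if c.status == "unstable")
    if n_unstable == 0:
        category = "MSS"
    elif n_unstable == 1:
        category = "MSI-low"
    else:
        category = "MSI-high"
    return MsiResult(
        sample=sample,
        calls=tuple(calls),
        category=category,
        partial_panel=len(calls) < panel_size,
    )


# ---------------------------------------------------------------------------
# Trace TSV input (sample, tissue, locus, length_bp, intensity)
# ---------------------------------------------------------------------------


def read_traces(path: str | Path) -> dict[tuple[str, str, str], Electropherogram]:
    """Read a long-format trace TSV into per-(sample, tissue, locus) traces."""
    grouped: dict[tuple[str, str, str], list[tuple[int, float]]] = defaultdict(list)
    with open(path, encoding="utf-8", newline="") as handle:
        rows = [
            line for line in handle if not line.startswith("#") and line.strip()
        ]
    reader = csv.DictReader(rows, delimiter="\t")
    for row in reader:
        key = (row["sample"], row["tissue"], row["locus"])
        grouped[key].append((int(row["length_bp"]), float(row["intensity"])))
    return {
        key: Electropherogram(
            sample=key[0], locus=key[2], points=tuple(sorted(points))
        )
        for key, points in grouped.items()
    }


def call_samples(
    traces: dict[tuple[str, str, str], Electropherogram],
    tol_bp: int = 1,
    rel_threshold: float = 0.10,
    panel: Sequence[str] = DEFAULT_PANEL,
) -> list[MsiResult]:
    """Pair healthy/tumor traces per sample and locus and classify."""
    samples = sorted({sample for sample, _, _ in traces})
    results = []
    for sample in samples:
        calls = []
        for locus in panel:
            normal = traces.get((sample, "normal", locus))
            tumor = traces.get((sample, "tumor", locus))
            if normal is None or tumor is None:
                continue
            calls.append(
                call_locus(
                    detect_peaks(normal, rel_threshold),
                    detect_peaks(tumor, rel_threshold),
                    tol_bp=tol_bp,
                )
            )
        if calls:
            results.append(
                classify_msi(calls, sample=sample, panel_size=len(panel))
            )
    return results


def write_msi_results(
    results: Iterable[MsiResult], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["sample", "locus", "status", "evidence_bp", "n_unstable",
             "n_evaluated", "category", "partial_panel"]
        )
        for res in results:
            for call in res.calls:
                writer.writerow(
                    [
                        res.sample, call.locus, call.status,
                        ",".join(map(str, call.evidence)),
                        res.n_unstable, res.n_evaluated, res.category,
                        int(res.partial_panel),
                    ]
                )
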