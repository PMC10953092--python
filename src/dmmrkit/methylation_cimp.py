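"""MethyLight-style percent methylation, paired marker calls, CIMP status,
dual-probe concordance and ddCt relative expression.

Percent methylation follows the PMR convention: the methylation-specific
Ct is normalized by a CpG-free control assay, then referenced against a
fully-methylated calibrator: % = 100 * 2^-((dCt_sample) - (dCt_calibrator)).
An undetermined methylation-specific Ct means no detectable methylated
template (0%); an undetermined control Ct invalidates the well. Replicate
Cts are averaged on the Ct scale.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Mapping, Sequence

from .io_formats import QpcrWell

CIMP_PANEL = ("MLH1_probe1", "CACNA1G", "CDKN2A", "CRABP1", "NEUROG1")
MLH1_PROBES = ("MLH1_probe1", "MLH1_probe2")
CIMP_CATEGORIES = ("negative", "low", "high")


class UndeterminedControlError(ValueError):
    """The normalization (control) assay did not amplify."""


@dataclass(frozen=True)
class DeltaCt:
    sample: str
    assay: str
    delta_ct: float | None  # None: methylation-specific Ct undetermined


@dataclass(frozen=True)
class MethylationMeasurement:
    sample: str
    marker: str
    percent: float  # clipped to [0, 100]
    raw_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent <= 100.0:
            raise ValueError("clipped percent must lie in [0, 100]")
        if self.raw_percent < 0:
            raise ValueError("raw percent must be nonnegative")


@dataclass(frozen=True)
class PairedMarkerCall:
    marker: str
    tumor_percent: float
    normal_percent: float
    threshold: float = 20.0

    @property
    def delta(self) -> float:
        return self.tumor_percent - self.normal_percent

    @property
    def methylated(self) -> bool:
        return self.delta > self.threshold  # strict cutoff


@dataclass(frozen=True)
class CimpResult:
    sample: str
    calls: tuple[PairedMarkerCall, ...]
    category: str

    @property
    def n_methylated(self) -> int:
        return sum(1 for c in self.calls if c.methylated)


def delta_ct(
    ms_cts: Sequence[float | None],
    control_cts: Sequence[float | None],
    sample: str = "",
    assay: str = "",
) -> DeltaCt:
    """Ct(methylation-specific) - Ct(control), replicates averaged on the
    Ct scale. Undetermined replicates are dropped; a fully undetermined
    control invalidates the measurement."""
    controls = [ct for ct in control_cts if ct is not None]
    if not controls:
        raise UndeterminedControlError(
            f"{sample}/{assay}: control assay Ct undetermined"
        )
    targets = [ct for ct in ms_cts if ct is not None]
    if not targets:
        return DeltaCt(sample=sample, assay=assay, delta_ct=None)
    return DeltaCt(
        sample=sample, assay=assay, delta_ct=fmean(targets) - fmean(controls)
    )


def percent_methylation(
    sample_dct: DeltaCt, calibrator_dct: DeltaCt
) -> MethylationMeasurement:
    """PMR from sample and fully-methylated calibrator delta-Cts."""
    if calibrator_dct.delta_ct is None:
        raise UndeterminedControlError(
            f"{sample_dct.assay}: calibrator measurement undetermined"
        )
    if sample_dct.delta_ct is None:
        raw = 0.0
    else:
        raw = 100.0 * 2.0 ** -(sample_dct.delta_ct - calibrator_dct.delta_ct)
    return MethylationMeasurement(
        sample=sample_dct.sample,
        marker=sample_dct.assay,
        percent=min(raw, 100.0),
        raw_percent=raw,
    )


def call_marker(
    tumor: MethylationMeasurement,
    normal: MethylationMeasurement,
    threshold: float = 20.0,
) -> PairedMarkerCall:
    """Methylated iff tumor exceeds the paired normal by more than
    ``threshold`` percentage points (strict)."""
    if tumor.marker != normal.marker:
        raise ValueError(
            f"marker mismatch: {tumor.marker!r} vs {normal.marker!r}"
        )
    return PairedMarkerCall(
        marker=tumor.marker,
        tumor_percent=tumor.percent,
        normal_percent=normal.percent,
        threshold=threshold,
    )


def classify_cimp(
    calls: Sequence[PairedMarkerCall], sample: str = ""
) -> CimpResult:
    """<= 2 methylated markers of 5 -> negative; 3 -> low; >= 4 -> high."""
    markers = sorted(c.marker for c in calls)
    if markers != sorted(CIMP_PANEL):
        raise ValueError(
            f"CIMP classification requires exactly the panel "
            f"{sorted(CIMP_PANEL)}, got {markers}"
        )
    n = sum(1 for c in calls if c.methylated)
    if n <= 2:
        category = "negative"
    elif n == 3:
        category = "low"
    else:
        category = "high"
    return CimpResult(sample=sample, calls=tuple(calls), category=category)


def dual_probe_concordance(
    probe1: PairedMarkerCall, probe2: PairedMarkerCall
) -> str:
    """Agreement of the two promoter probes for the same sample."""
    if probe1.methylated and probe2.methylated:
        return "concordant-methylated"
    if not probe1.methylated and not probe2.methylated:
        return "concordant-unmethylated"
    return "discordant"


def relative_expression(
    target_ct_sample: float,
    reference_ct_sample: float,
    target_ct_reference: float,
    reference_ct_reference: float,
) -> float:
    """2^-ddCt fold change of the sample tissue versus the reference tissue,
    with dCt = Ct(target) - Ct(reference gene)."""
    for ct in (
        target_ct_sample, reference_ct_sample,
        target_ct_reference, reference_ct_reference,
    ):
        if ct is None:
            raise ValueError("all four Ct values must be determined")
    dct_sample = target_ct_sample - reference_ct_sample
    dct_reference = target_ct_reference - reference_ct_reference
    return 2.0 ** -(dct_sample - dct_reference)


# ---------------------------------------------------------------------------
# Plate-level driver
# ---------------------------------------------------------------------------


def _collect(
    wells: Iterable[QpcrWell],
) -> dict[tuple[str, str, str, str], list[float | None]]:
    grouped: dict[tuple[str, str, str, str], list[float | None]] = defaultdict(list)
    for w in wells:
        grouped[(w.sample, w.tissue, w.assay, w.role)].append(w.ct)
    return grouped


def measure_plate(
    wells: Sequence[QpcrWell],
    control_assay: str = "ACTB",
    calibrator_sample: str = "calibrator",
) -> dict[tuple[str, str, str], MethylationMeasurement]:
    """Percent methylation for every (sample, tissue, marker) on a plate.

    The calibrator is a fully-methylated control run once per
    methylation-specific assay under tissue ``calibrator``.
    """
    grouped = _collect(wells)
    markers = sorted({
        assay
        for (_, _, assay, role) in grouped
        if role == "methylation-specific"
    })
    calibrators: dict[str, DeltaCt] = {}
    for marker in markers:
        cal_ms = grouped.get(
            (calibrator_sample, "calibrator", marker, "methylation-specific")
        )
        cal_ctrl = grouped.get(
            (calibrator_sample, "calibrator", control_assay, "control")
        )
        if cal_ms is None or cal_ctrl is None:
            raise ValueError(
                f"plate lacks calibrator wells for assay {marker!r}"
            )
        calibrators[marker] = delta_ct(
            cal_ms, cal_ctrl, sample=calibrator_sample, assay=marker
        )
    out: dict[tuple[str, str, str], MethylationMeasurement] = {}
    for (sample, tissue, assay, role) in grouped:
        if role != "methylation-specific" or tissue == "calibrator":
            continue
        control = grouped.get((sample, tissue, control_assay, "control"))
        if control is None:
            raise ValueError(
                f"{sample}/{tissue}: missing control assay {control_assay!r}"
            )
        dct = delta_ct(
            grouped[(sample, tissue, assay, role)],
            control,
            sample=sample,
            assay=assay,
        )
        out[(sample, tissue, assay)] = percent_methylation(
            dct, calibrators[assay]
        )
    return out


def classify_plate(
    wells: Sequence[QpcrWell],
    threshold: float = 20.0,
    control_assay: str = "ACTB",
    calibrator_sample: str = "calibrator",
) -> tuple[dict[str, CimpResult], dict[str, str]]:
    """Per-sample CIMP results plus the MLH1 dual-probe concordance labels.

    MLH1 enters the 5-marker panel once, through probe 1; probe 2 serves
    only as confirmation.
    """
    measurements = measure_plate(
        wells, control_assay=control_assay,
        calibrator_sample=calibrator_sample,
    )
    samples = sorted({s for s, _, _ in measurements})
    results: dict[str, CimpResult] = {}
    concordance: dict[str, str] = {}
    for sample in samples:
        calls: dict[str, PairedMarkerCall] = {}
        for marker in CIMP_PANEL + ("MLH1_probe2",):
            tumor = measurements.get((sample, "tumor", marker))
            normal = measurements.get((sample, "normal", marker))
            if tumor is None or normal is None:
                continue
            calls[marker] = call_marker(tumor, normal, threshold=threshold)
        panel_calls = [calls[m] for m in CIMP_PANEL if m in calls]
        if len(panel_calls) == len(CIMP_PANEL):
            results[sample] = classify_cimp(panel_calls, sample=sample)
        if "MLH1_probe1" in calls and "MLH1_probe2" in calls:
            concordance[sample] = dual_probe_concordance(
                calls["MLH1_probe1"], calls["MLH1_probe2"]
            )
    return results, concordance
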