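"""Methylation-aware DNA-shape prediction by pentamer lookup, reference
percentile envelopes over binding-site sets, and departure scoring.

Sequences use an extended alphabet: M is 5-methylcytosine on the forward
strand and W the guanine paired to a methylated C on the opposite strand,
so a symmetrically methylated CpG reads "MW". Base-centered features (MGW,
ProT) take the value of the pentamer centered on the position; the two
central steps of each pentamer carry the step-centered features (HelT,
Roll) and interior steps average the two covering pentamers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SiteSet, TableValidationError

EXTENDED_ALPHABET = "ACGTMW"
EXTENDED_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C", "M": "W", "W": "M",
}
BASE_FEATURES = ("MGW", "ProT")
STEP_FEATURES = ("HelT", "Roll")
FEATURES = BASE_FEATURES + STEP_FEATURES
ENVELOPE_PERCENTILES = (5, 25, 50, 75, 95)


class UnknownPentamerError(KeyError):
    def __init__(self, pentamer: str):
        super().__init__(pentamer)
        self.pentamer = pentamer

    def __str__(self) -> str:
        return f"pentamer not declared in shape table: {self.pentamer!r}"


# ---------------------------------------------------------------------------
# Extended sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtendedSequence:
    plain: str
    methylated_cpgs: tuple[int, ...]  # 0-based CpG start positions
    encoded: str

    def __len__(self) -> int:
        return len(self.encoded)

    def reverse_complement(self) -> "ExtendedSequence":
        rc = "".join(
            EXTENDED_COMPLEMENT[b] for b in reversed(self.encoded)
        )
        plain_rc = "".join(
            EXTENDED_COMPLEMENT[b] for b in reversed(self.plain)
        )
        n = len(self.plain)
        positions = tuple(
            sorted(n - 2 - p for p in self.methylated_cpgs)
        )
        return ExtendedSequence(
            plain=plain_rc, methylated_cpgs=positions, encoded=rc
        )


def encode_methylation(
    seq: str, methylated_cpgs: Iterable[int] = ()
) -> ExtendedSequence:
    """Rewrite each listed CpG (0-based start) as MW; validate the sites."""
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"plain sequence must be over ACGT: {seq!r}")
    positions = tuple(sorted(set(int(p) for p in methylated_cpgs)))
    encoded = list(seq)
    for p in positions:
        if p < 0 or p + 1 >= len(seq) or seq[p : p + 2] != "CG":
            raise ValueError(
                f"position {p} does not start a CpG in the sequence"
            )
        encoded[p] = "M"
        encoded[p + 1] = "W"
    return ExtendedSequence(
        plain=seq, methylated_cpgs=positions, encoded="".join(encoded)
    )


# ---------------------------------------------------------------------------
# Shape tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PentamerShape:
    mgw: float
    prot: float
    helt1: float
    helt2: float
    roll1: float
    roll2: float


@dataclass(frozen=True)
class ShapeTable:
    """Pentamer lookup table; a missing pentamer is an error, never a
    silent default."""

    values: Mapping[str, PentamerShape]

    def lookup(self, pentamer: str) -> PentamerShape:
        try:
            return self.values[pentamer]
        except KeyError:
            raise UnknownPentamerError(pentamer) from None


SHAPE_TABLE_COLUMNS = (
    "pentamer", "MGW", "ProT", "HelT1", "HelT2", "Roll1", "Roll2"
)


def read_shape_table(path: str | Path) -> ShapeTable:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"pentamer": str})
    missing = set(SHAPE_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise TableValidationError(
            f"{path}: shape table missing columns {sorted(missing)}"
        )
    values = {}
    for row in frame.itertuples(index=False):
        penta = row.pentamer.upper()
        if len(penta) != 5 or set(penta) - set(EXTENDED_ALPHABET):
            raise TableValidationError(f"{path}: bad pentamer {penta!r}")
        values[penta] = PentamerShape(
            mgw=float(row.MGW), prot=float(row.ProT),
            helt1=float(row.HelT1), helt2=float(row.HelT2),
            roll1=float(row.Roll1), roll2=float(row.Roll2),
        )
    return ShapeTable(values=values)


def write_shape_table(table: ShapeTable, path: str | Path) -> None:
    rows = [
        (p, v.mgw, v.prot, v.helt1, v.helt2, v.roll1, v.roll2)
        for p, v in sorted(table.values.items())
    ]
    pd.DataFrame(rows, columns=SHAPE_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Shape profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeProfile:
    """Per-position feature values; NaN marks undefined edge positions.

    Base-feature arrays have one entry per base (defined 2..L-3, 0-based);
    step-feature arrays have one entry per step between adjacent bases
    (defined 1..L-3).
    """

    features: Mapping[str, np.ndarray]

    @property
    def n_bases(self) -> int:
        return len(self.features["MGW"])

    def window(self, start: int, end: int) -> "ShapeProfile":
        """Restrict to bases [start, end) and the steps between them."""
        out = {}
        for name in BASE_FEATURES:
            out[name] = self.features[name][start:end]
        for name in STEP_FEATURES:
            out[name] = self.features[name][start : end - 1]
        return ShapeProfile(features=out)


def predict_shape(
    eseq: ExtendedSequence,
    table: ShapeTable,
    report: tuple[int, int] | None = None,
) -> ShapeProfile:
    """Sliding pentamer lookup over an (extended) sequence.

    ``report=(start, end)`` returns only that base window — pass the probe
    sequence with flanks and report the central window to obtain values at
    what would otherwise be edge positions.
    """
    s = eseq.encoded
    L = len(s)
    if L < 5:
        raise ValueError("shape prediction needs at least 5 bases")
    mgw = np.full(L, np.nan)
    prot = np.full(L, np.nan)
    helt_sum = np.zeros(L - 1)
    helt_n = np.zeros(L - 1, dtype=int)
    roll_sum = np.zeros(L - 1)
    roll_n = np.zeros(L - 1, dtype=int)
    for k in range(L - 4):
        v = table.lookup(s[k : k + 5])
        mgw[k + 2] = v.mgw
        prot[k + 2] = v.prot
        for step, helt, roll in ((k + 1, v.helt1, v.roll1),
                                 (k + 2, v.helt2, v.roll2)):
            helt_sum[step] += helt
            helt_n[step] += 1
            roll_sum[step] += roll
            roll_n[step] += 1
    with np.errstate(invalid="ignore"):
        helt = np.where(helt_n > 0, helt_sum / np.maximum(helt_n, 1), np.nan)
        roll = np.where(roll_n > 0, roll_sum / np.maximum(roll_n, 1), np.nan)
    profile = ShapeProfile(
        features={"MGW": mgw, "ProT": prot, "HelT": helt, "Roll": roll}
    )
    if report is not None:
        profile = profile.window(*report)
    return profile


def methylation_delta(
    seq: str,
    methylated_cpgs: Iterable[int],
    table: ShapeTable,
) -> Mapping[str, np.ndarray]:
    """Per-feature (methylated - unmethylated) difference profiles.

    Nonzero only at positions whose pentamer window overlaps a rewritten
    base (locality of the pentamer model).
    """
    methylated = predict_shape(encode_methylation(seq, methylated_cpgs), table)
    unmethylated = predict_shape(encode_methylation(seq), table)
    return {
        name: methylated.features[name] - unmethylated.features[name]
        for name in FEATURES
    }


# ---------------------------------------------------------------------------
# Percentile envelopes and departure scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PercentileEnvelope:
    motif: str
    n_sites: int
    percentiles: Mapping[str, Mapping[int, np.ndarray]]
    # raw per-site values backing the percentiles, feature -> (n_sites, L')
    reference: Mapping[str, np.ndarray]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "motif": self.motif,
            "n_sites": self.n_sites,
            "metadata": dict(self.metadata),
            "percentiles": {
                name: {str(q): arr.tolist() for q, arr in per.items()}
                for name, per in self.percentiles.items()
            },
            "reference": {
                name: arr.tolist() for name, arr in self.reference.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PercentileEnvelope":
        payload = json.loads(Path(path).read_text())
        return cls(
            motif=payload["motif"],
            n_sites=payload["n_sites"],
            metadata=payload.get("metadata", {}),
            percentiles={
                name: {
                    int(q): np.asarray(arr, dtype=float)
                    for q, arr in per.items()
                }
                for name, per in payload["percentiles"].items()
            },
            reference={
                name: np.asarray(arr, dtype=float)
                for name, arr in payload["reference"].items()
            },
        )


def build_envelope(
    sites: SiteSet,
    table: ShapeTable,
    flank: tuple[str, str] | None = None,
    min_sites: int = 20,
    allow_small: bool = False,
) -> PercentileEnvelope:
    """Per-position empirical shape percentiles across an aligned site set.

    ``flank`` optionally supplies fixed 5'/3' context sequences so edge
    positions of the sites become defined; the choice is recorded in the
    envelope metadata.
    """
    if len(sites.sequences) < min_sites and not allow_small:
        raise ValueError(
            f"site set has {len(sites.sequences)} sequences, below the floor "
            f"of {min_sites}; pass allow_small=True to override"
        )
    matrices: dict[str, list[np.ndarray]] = {name: [] for name in FEATURES}
    for seq in sites.sequences:
        if flank is not None:
            left, right = flank
            extended = encode_methylation(left + seq + right)
            profile = predict_shape(
                extended, table,
                report=(len(left), len(left) + len(seq)),
            )
        else:
            profile = predict_shape(encode_methylation(seq), table)
        for name in FEATURES:
            matrices[name].append(profile.features[name])
    reference = {name: np.vstack(rows) for name, rows in matrices.items()}
    percentiles = {}
    with np.errstate(invalid="ignore"):
        for name, matrix in reference.items():
            defined = ~np.isnan(matrix[0])
            per: dict[int, np.ndarray] = {}
            for q in ENVELOPE_PERCENTILES:
                arr = np.full(matrix.shape[1], np.nan)
                if defined.any():
                    arr[defined] = np.percentile(
                        matrix[:, defined], q, axis=0
                    )
                per[q] = arr
            percentiles[name] = per
    return PercentileEnvelope(
        motif=sites.name,
        n_sites=len(sites.sequences),
        percentiles=percentiles,
        reference=reference,
        metadata={"flank": None if flank is None else list(flank)},
    )


@dataclass(frozen=True)
class DepartureScore:
    """Per-feature departure of a query profile from a reference envelope.

    mean_rank_deviation: mean over positions of |rank - 50| / 50, where the
    rank is the mid-rank percentile of the query value among the reference
    sites. Exactly zero for a query sitting at the per-position median of a
    tie-free reference; tied reference values (frequent with pentamer
    lookups, where two sites sharing a pentamer share its value) can leave
    a small residual. envelope_exceedance: share of positions where the
    query falls outside [P5, P95].
    """

    mean_rank_deviation: Mapping[str, float]
    envelope_exceedance: Mapping[str, float]


def _midrank_percentile(reference: np.ndarray, value: float) -> float:
    """100 * (count(ref < value) + 0.5 * count(ref = value)) / n."""
    n = reference.size
    below = np.count_nonzero(reference < value)
    equal = np.count_nonzero(reference == value)
    return 100.0 * (below + 0.5 * equal) / n


def departure_score(
    query: ShapeProfile, envelope: PercentileEnvelope
) -> DepartureScore:
    deviations: dict[str, float] = {}
    exceedances: dict[str, float] = {}
    for name in FEATURES:
        q = query.features[name]
        ref = envelope.reference[name]
        if q.shape[0] != ref.shape[1]:
            raise ValueError(
                f"{name}: query has {q.shape[0]} positions, envelope "
                f"{ref.shape[1]}"
            )
        defined = ~np.isnan(q) & ~np.isnan(ref[0])
        if not defined.any():
            deviations[name] = float("nan")
            exceedances[name] = float("nan")
            continue
        ranks = np.array(
            [
                _midrank_percentile(ref[:, i], q[i])
                for i in np.flatnonzero(defined)
            ]
        )
        deviations[name] = float(np.mean(np.abs(ranks - 50.0) / 50.0))
        lo = envelope.percentiles[name][5][defined]
        hi = envelope.percentiles[name][95][defined]
        outside = (q[defined] < lo) | (q[defined] > hi)
        exceedances[name] = float(np.mean(outside))
    return DepartureScore(
        mean_rank_deviation=deviations, envelope_exceedance=exceedances
    )
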