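"""Cohort summaries, Spearman correlation and the DEG-threshold filter."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ClinicalRecord

# Fixed ordinal encodings for categorical parameters entering correlation
# analysis (the source publications leave these unstated).
MSI_ENCODING = {"MSS": 0, "MSI-low": 1, "MSI-high": 2}
CIMP_ENCODING = {"negative": 0, "low": 1, "high": 2}


@dataclass(frozen=True)
class CohortSummary:
    n: int
    n_female: int
    n_male: int
    n_sex_known: int
    mean_age_arrival: float
    min_age_arrival: float
    max_age_arrival: float
    n_age_known: int
    n_fob_pos: int
    n_fob_known: int
    n_fibrosis_pos: int
    n_fibrosis_known: int
    t_stage_counts: Mapping[int, int] = field(default_factory=dict)
    n_stage_counts: Mapping[int, int] = field(default_factory=dict)
    m_stage_counts: Mapping[int, int] = field(default_factory=dict)
    grade_counts: Mapping[int, int] = field(default_factory=dict)

    @property
    def mean_age_arrival_2dp(self) -> float:
        return round(self.mean_age_arrival, 2)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "n", "n_female", "n_male", "n_sex_known", "mean_age_arrival",
                "min_age_arrival", "max_age_arrival", "n_age_known",
                "n_fob_pos", "n_fob_known", "n_fibrosis_pos",
                "n_fibrosis_known",
            )
        }
        out["mean_age_arrival_2dp"] = self.mean_age_arrival_2dp
        for name in ("t_stage", "n_stage", "m_stage", "grade"):
            out[f"{name}_counts"] = {
                str(k): v
                for k, v in sorted(getattr(self, f"{name}_counts").items())
            }
        return out


def summarize_cohort(records: Sequence[ClinicalRecord]) -> CohortSummary:
    """Tabulate the cohort; missing values drop out of each denominator."""
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    ages = [r.age_arrival for r in records if r.age_arrival is not None]
    if not ages:
        raise ValueError("no arrival ages present in cohort")
    sexes = [r.sex for r in records if r.sex is not None]
    fob = [r.fob for r in records if r.fob is not None]
    fibrosis = [r.fibrosis for r in records if r.fibrosis is not None]

    def tally(attr: str) -> dict[int, int]:
        values = [getattr(r, attr) for r in records]
        return {
            v: values.count(v) for v in sorted({x for x in values if x is not None})
        }

    return CohortSummary(
        n=len(records),
        n_female=sexes.count("f"),
        n_male=sexes.count("m"),
        n_sex_known=len(sexes),
        mean_age_arrival=float(np.mean(ages)),
        min_age_arrival=float(min(ages)),
        max_age_arrival=float(max(ages)),
        n_age_known=len(ages),
        n_fob_pos=fob.count("pos"),
        n_fob_known=len(fob),
        n_fibrosis_pos=fibrosis.count("pos"),
        n_fibrosis_known=len(fibrosis),
        t_stage_counts=tally("t_stage"),
        n_stage_counts=tally("n_stage"),
        m_stage_counts=tally("m_stage"),
        grade_counts=tally("grade"),
    )


@dataclass(frozen=True)
class CorrelationResult:
    feature_a: str
    feature_b: str
    rho: float | None
    p_value: float | None
    n: int

    @property
    def missing(self) -> bool:
        return self.rho is None


def _spearman_pair(
    x: np.ndarray, y: np.ndarray, exact: bool
) -> tuple[float | None, float | None]:
    n = x.size
    if n < 3 or np.unique(x).size < 2 or np.unique(y).size < 2:
        return None, None
    rx = stats.rankdata(x)  # average ranks
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if not math.isfinite(rho):
        return None, None
    if exact and n <= 8:
        # exact permutation two-sided p on |rho|
        observed = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= observed - 1e-12:
                count += 1
        return rho, count / total
    # two-sided t approximation with df = n - 2
    if abs(rho) >= 1.0:
        return rho, 0.0 if n > 2 else None
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def spearman_matrix(
    features: pd.DataFrame, exact: bool = False
) -> list[CorrelationResult]:
    """All pairwise Spearman correlations on pairwise-complete samples.

    Ties get average ranks; the two-sided p-value uses the t-approximation
    with df = n - 2 (an exact permutation p is available for n <= 8 via
    ``exact=True``). Pairs with fewer than 3 complete samples or a constant
    column are reported as missing, not as 0.
    """
    results = []
    columns = list(features.columns)
    for a, b in itertools.combinations(columns, 2):
        sub = features[[a, b]].dropna()
        x = sub[a].to_numpy(dtype=float)
        y = sub[b].to_numpy(dtype=float)
        rho, p = _spearman_pair(x, y, exact=exact)
        results.append(
            CorrelationResult(
                feature_a=a, feature_b=b, rho=rho, p_value=p, n=len(sub)
            )
        )
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjustment: adj_i = min over k >= rank(i) of p_(k)*m/k."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass(frozen=True)
class DegPartition:
    up: tuple[str, ...]
    down: tuple[str, ...]
    unchanged: tuple[str, ...]
    adjusted_p: Mapping[str, float] = field(default_factory=dict)

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)


def filter_deg(
    table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> DegPartition:
    """Partition genes into up/down/unchanged.

    ``table`` indexes genes and carries columns ``log2fc`` and ``p``.
    BH adjustment is applied across all rows; a gene is up when
    adj-p < alpha and log2fc > lfc_threshold, down when adj-p < alpha and
    log2fc < -lfc_threshold.
    """
    if table.empty:
        return DegPartition(up=(), down=(), unchanged=(), adjusted_p={})
    adj = benjamini_hochberg(table["p"].to_numpy())
    lfc = table["log2fc"].to_numpy(dtype=float)
    genes = np.asarray(table.index.astype(str))
    significant = adj < alpha
    up = significant & (lfc > lfc_threshold)
    down = significant & (lfc < -lfc_threshold)
    unchanged = ~(up | down)
    return DegPartition(
        up=tuple(genes[up]),
        down=tuple(genes[down]),
        unchanged=tuple(genes[unchanged]),
        adjusted_p=dict(zip(genes, adj)),
    )
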