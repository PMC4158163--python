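"""Cohort summaries and group comparisons of fitted diameter multipliers.

Works on per-patient, per-PEEP alpha values. The packaged fixture carries
the published 10-patient ARDS cohort (alpha and AUC per PEEP level of
5/10/15 cmH2O, diagnoses, auto-PEEP); `load_cohort` returns it as a tidy
DataFrame plus per-patient records.

Quartiles use linear interpolation of order statistics (type 7, the
numpy/Excel default) — stated explicitly because quartile conventions
differ and the choice is part of the reported interquartile range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortRecord",
    "CohortSummary",
    "GroupComparison",
    "load_cohort",
    "summarize_alpha",
    "ranksum_test",
    "ks_test",
    "diagnosis_ranges",
    "compare_copd",
    "summary_table",
]

#: Diagnosis labels appearing in the packaged cohort.
KNOWN_DIAGNOSES = frozenset(
    {"COPD", "Aspiration", "Trauma", "Legionnaires", "Pneumonia", "Peritonitis", "H1N1"}
)


@dataclass(frozen=True)
class CohortRecord:
    """One patient: diagnoses, auto-PEEP and alpha per PEEP level."""

    patient: str
    diagnoses: tuple[str, ...]
    auto_peep: float  # cmH2O
    alphas: dict[float, float] = field(default_factory=dict)  # PEEP -> alpha

    def has(self, label: str) -> bool:
        return label in self.diagnoses


@dataclass(frozen=True)
class CohortSummary:
    mean: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    n_values: int


@dataclass(frozen=True)
class GroupComparison:
    labels: tuple[str, str]
    sizes: tuple[int, int]
    ranksum_p: float
    ks_p: float | None = None


def load_cohort() -> tuple[list[CohortRecord], pd.DataFrame]:
    """Packaged 10-patient cohort: records plus the tidy per-PEEP table."""
    pkg = resources.files("abmps.data")
    with resources.as_file(pkg.joinpath("cohort_alpha.csv")) as p:
        alpha_df = pd.read_csv(p)
    with resources.as_file(pkg.joinpath("cohort_patients.csv")) as p:
        pat_df = pd.read_csv(p)
    df = alpha_df.merge(pat_df, on="patient")
    records = []
    for _, row in pat_df.iterrows():
        sub = alpha_df[alpha_df["patient"] == row["patient"]]
        records.append(
            CohortRecord(
                patient=row["patient"],
                diagnoses=tuple(row["diagnoses"].split(";")),
                auto_peep=float(row["auto_peep_cmH2O"]),
                alphas={
                    float(r["peep_cmH2O"]): float(r["alpha"]) for _, r in sub.iterrows()
                },
            )
        )
    return records, df


def summarize_alpha(values) -> CohortSummary:
    """Mean, median, type-7 quartiles and range of a set of alpha values."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty set of alpha values")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation (type 7)
    return CohortSummary(
        mean=float(np.mean(v)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(np.min(v)),
        max=float(np.max(v)),
        n_values=int(v.size),
    )


def ranksum_test(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Midrank tie handling with the continuity-corrected normal
    approximation; exact enumeration when both samples are small and
    untied (scipy's automatic choice).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)


def ks_test(group_a, group_b) -> float:
    """Two-sided two-sample Kolmogorov-Smirnov p-value.

    Provided for completeness; with values tied at 2-decimal resolution
    the p-value is sensitive to the tie convention.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    return float(stats.ks_2samp(a, b).pvalue)


def diagnosis_ranges(records: list[CohortRecord]) -> dict[str, tuple[float, float]]:
    """Per-diagnosis (min, max) of alpha pooled over PEEP levels.

    Patients with several diagnoses contribute to each; labels outside the
    fixture vocabulary are passed through with a warning.
    """
    pools: dict[str, list[float]] = {}
    for rec in records:
        for label in rec.diagnoses:
            if label not in KNOWN_DIAGNOSES:
                warnings.warn(f"unknown diagnosis label: {label!r}", stacklevel=2)
            pools.setdefault(label, []).extend(rec.alphas.values())
    return {
        label: (float(np.min(v)), float(np.max(v))) for label, v in pools.items() if v
    }


def _pooled(records: list[CohortRecord], predicate) -> list[float]:
    out: list[float] = []
    for rec in records:
        if predicate(rec):
            out.extend(rec.alphas.values())
    return out


def compare_copd(records: list[CohortRecord]) -> GroupComparison:
    """COPD versus the rest of the cohort, alpha pooled over PEEP levels."""
    copd = _pooled(records, lambda r: r.has("COPD"))
    other = _pooled(records, lambda r: not r.has("COPD"))
    return GroupComparison(
        labels=("COPD", "non-COPD"),
        sizes=(len(copd), len(other)),
        ranksum_p=ranksum_test(copd, other),
        ks_p=ks_test(copd, other),
    )


def summary_table(records: list[CohortRecord], df: pd.DataFrame) -> str:
    """Formatted text report: per-patient alphas, cohort summary, groups."""
    lines = ["patient  auto-PEEP  PEEP  alpha"]
    for rec in records:
        for peep in sorted(rec.alphas):
            lines.append(
                f"{rec.patient:<8} {rec.auto_peep:>8.1f} {peep:>5.0f} {rec.alphas[peep]:>6.2f}"
            )
    s = summarize_alpha(df["alpha"])
    lines += [
        "",
        f"alpha over {s.n_values} fits: mean {s.mean:.2f}, median {s.median:.2f}, "
        f"IQR [{s.q1:.2f}, {s.q3:.2f}], range [{s.min:.2f}, {s.max:.2f}]",
    ]
    comp = compare_copd(records)
    lines.append(
        f"{comp.labels[0]} (n={comp.sizes[0]}) vs {comp.labels[1]} (n={comp.sizes[1]}): "
        f"rank-sum p = {comp.ranksum_p:.2e}, KS p = {comp.ks_p:.2e}"
    )
    for label, (lo, hi) in sorted(diagnosis_ranges(records).items()):
        lines.append(f"  {label:<13} alpha {lo:.2f}-{hi:.2f}")
    return "\n".join(lines)
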