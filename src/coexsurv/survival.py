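"""Tail-stratified survival analysis on single-gene and weighted gene-pair scores.

Patients are scored by a weighted sum of standardized (z-scored) gene
expression values — a single gene reduces to its own z-vector, the
EGFR/NTN4-style pair to an equally weighted z-sum by default. The top and
bottom ``fraction`` of patients by score (k = ceil(fraction * n) each; 20%
of 92 patients gives the 19-per-tail design) form the high and low groups;
the middle of the cohort is excluded from testing. Each tail gets a
Kaplan-Meier product-limit curve and the tails are compared by the
two-group log-rank test (chi-square, 1 df). KM and log-rank computations
are delegated to lifelines.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io import SurvivalCohort

__all__ = [
    "ScoreSpec",
    "KMCurve",
    "LogRankResult",
    "StratificationResult",
    "patient_scores",
    "select_tails",
    "km_estimate",
    "logrank",
    "stratified_survival",
]


class DegenerateInputError(ValueError):
    """Scoring or testing is undefined on the given input."""


@dataclasses.dataclass
class ScoreSpec:
    """One- or two-gene expression score: weighted sum of per-gene z-scores.

    ``transform`` is applied before standardization: "log2p1" (log2(1+x),
    for counts-scale expression) or "identity" (already log scale).
    """

    genes: tuple[str, ...]
    weights: tuple[float, ...] | None = None
    transform: Literal["log2p1", "identity"] = "identity"

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if not 1 <= len(self.genes) <= 2:
            raise ValueError("a score uses one or two genes")
        if self.weights is None:
            self.weights = tuple(1.0 / len(self.genes) for _ in self.genes)
        self.weights = tuple(float(w) for w in self.weights)
        if len(self.weights) != len(self.genes):
            raise ValueError("one weight per gene")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")
        total = sum(self.weights)
        self.weights = tuple(w / total for w in self.weights)
        if self.transform not in ("log2p1", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclasses.dataclass
class KMCurve:
    """Product-limit estimate: survival after each distinct event time."""

    event_times: np.ndarray  # strictly increasing, each with >= 1 event
    survival: np.ndarray  # S(t) just after each event time; S(0) == 1 implicit
    at_risk: np.ndarray  # number at risk just before each event time

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=int)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


@dataclasses.dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclasses.dataclass
class StratificationResult:
    scores: pd.Series  # per-patient score, indexed by patient id
    fraction: float
    k: int
    high_ids: list[str]
    low_ids: list[str]
    km_high: KMCurve
    km_low: KMCurve
    logrank: LogRankResult
    long_table: pd.DataFrame  # patient, score components, group, time, event


def patient_scores(cohort: SurvivalCohort, spec: ScoreSpec) -> pd.Series:
    """Weighted sum of per-gene standardized expression, per patient."""
    cols = []
    for gene in spec.genes:
        if gene not in cohort.expr.columns:
            raise KeyError(f"score gene {gene!r} not in cohort expression")
        x = cohort.expr[gene].to_numpy(dtype=float)
        if spec.transform == "log2p1":
            if (x < 0).any():
                raise ValueError(f"log2p1 transform needs non-negative expression ({gene})")
            x = np.log2(1.0 + x)
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError(f"gene {gene!r} is constant across patients")
        cols.append((x - x.mean()) / sd)
    score = sum(w * z for w, z in zip(spec.weights, cols))
    return pd.Series(score, index=pd.Index(cohort.patient_ids, name="patient_id"), name="score")


def select_tails(scores: pd.Series, fraction: float) -> tuple[list[str], list[str]]:
    """Ids of the k = ceil(fraction * n) highest- and lowest-scoring patients.

    Boundary ties are broken by patient id for determinism. Raises if the
    tails would overlap (2k > n).
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(scores)
    k = math.ceil(fraction * n)
    if 2 * k > n:
        raise ValueError(f"tails overlap: n={n}, fraction={fraction} gives k={k}")
    order = pd.DataFrame(
        {"patient_id": scores.index.astype(str), "score": scores.to_numpy()}
    ).sort_values(["score", "patient_id"], kind="mergesort")
    ids = order["patient_id"].tolist()
    return ids[-k:], ids[:k]


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    At each distinct event time t with d events among r at risk, S is
    multiplied by (1 - d/r); patients censored at t stay in the risk set for
    events at t (events-before-censorings tie convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1 or len(times) < 1:
        raise ValueError("times and events must be equal-length non-empty vectors")
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=int)
    surv = kmf.survival_function_["KM_estimate"]
    survival = np.array([float(surv.loc[t]) for t in event_times])
    return KMCurve(event_times=event_times, survival=survival, at_risk=at_risk)


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> LogRankResult:
    """Two-group log-rank test; chi-square statistic with 1 df."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise DegenerateInputError("no events in either group: log-rank undefined")
    res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):
        raise DegenerateInputError("zero log-rank variance: degenerate comparison")
    return LogRankResult(chi2=chi2, df=1, p=min(max(p, 5e-324), 1.0))


def stratified_survival(
    cohort: SurvivalCohort,
    spec: ScoreSpec,
    fraction: float,
) -> StratificationResult:
    """Score, select tails, estimate per-tail KM curves and compare by log-rank.

    The emitted long table (one row per patient: expression of the score
    genes, score, tail membership, time, event) is the plot-ready input for
    downstream 3D-axes and violin figures.
    """
    scores = patient_scores(cohort, spec)
    high_ids, low_ids = select_tails(scores, fraction)
    k = len(high_ids)

    idx = {p: i for i, p in enumerate(cohort.patient_ids)}
    hi = np.array([idx[p] for p in high_ids])
    lo = np.array([idx[p] for p in low_ids])

    km_high = km_estimate(cohort.time[hi], cohort.event[hi])
    km_low = km_estimate(cohort.time[lo], cohort.event[lo])
    lr = logrank(cohort.time[hi], cohort.event[hi], cohort.time[lo], cohort.event[lo])

    group = pd.Series("mid", index=scores.index)
    group.loc[high_ids] = "high"
    group.loc[low_ids] = "low"
    long_table = pd.DataFrame(
        {
            "patient_id": cohort.patient_ids,
            **{g: cohort.expr[g].to_numpy() for g in spec.genes},
            "score": scores.to_numpy(),
            "group": group.to_numpy(),
            "time": cohort.time,
            "event": cohort.event,
        }
    )
    return StratificationResult(
        scores=scores,
        fraction=fraction,
        k=k,
        high_ids=high_ids,
        low_ids=low_ids,
        km_high=km_high,
        km_low=km_low,
        logrank=lr,
        long_table=long_table,
    )
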