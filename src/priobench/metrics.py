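"""Outcome indicators and per-experiment rates with bootstrap intervals.

Three binary outcomes are scored per case x experiment x iteration:

* **completeness** — the response is not a refusal and contains at least
  half of the requested number of valid, deduplicated gene symbols
  (``ceil(k/2)``: 25 of a top-50 list, 5 of a top-10 list);
* **accuracy** — the diagnosed gene (canonical form) is among the first k
  parsed genes;
* **compliance** — the response matches the required output structure.

Per experiment e and iteration t the rate is ``p_e(t) = sum_m I_t(m,e) / M``
over the M cases; the summary rate averages p_e(t) over iterations, with a
95% percentile bootstrap interval (B = 100 by default) that resamples
*cases* with replacement — all iterations of a resampled case move
together, since repeated calls on the same case are correlated.

Accuracy is reported two ways: **completed accuracy** restricts the
denominator to completed tasks; **overall accuracy** uses all cases and
counts an incomplete task as incorrect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .cohort import Case
from .lexicon import GeneLexicon, canonicalize
from .parsing import ParsedPrediction, check_structure_compliance

Metric = Literal["completeness", "accuracy_completed", "accuracy_overall", "compliance"]

METRICS: tuple[Metric, ...] = (
    "completeness",
    "accuracy_completed",
    "accuracy_overall",
    "compliance",
)


class ConfigurationError(ValueError):
    """Raised when scoring inputs are inconsistent (e.g. unresolvable truth)."""


class EmptyExperimentError(ValueError):
    """Raised when an experiment has no records to summarize."""


@dataclass(frozen=True)
class OutcomeRecord:
    """The three binary indicators for one case x experiment x iteration."""

    experiment_id: str
    case_id: str
    iteration: int
    complete: int
    accurate: int
    compliant: int


@dataclass(frozen=True)
class MetricSummary:
    experiment_id: str
    metric: Metric
    per_iteration_rates: tuple[float, ...]
    mean_rate: float  # NaN when undefined (no completed tasks anywhere)
    ci_low: float
    ci_high: float
    n_cases: int
    n_bootstrap: int


def completeness_threshold(k: int) -> int:
    """Minimum count of valid unique symbols for a completed top-k task."""
    return math.ceil(k / 2)


def evaluate_case(
    pred: ParsedPrediction, case: Case, lexicon: GeneLexicon, k: int,
    experiment_id: str = "", iteration: int = 1,
) -> OutcomeRecord:
    """Score one parsed response against its case's diagnosed gene."""
    truth = canonicalize(case.diagnosed_gene, lexicon)
    if truth is None:
        raise ConfigurationError(
            f"diagnosed gene {case.diagnosed_gene!r} for case {case.case_id!r} "
            "does not resolve under the lexicon"
        )
    complete = int(
        not pred.refusal and pred.n_valid_unique >= completeness_threshold(k)
    )
    accurate = int(truth in pred.genes[:k])
    compliant = int(check_structure_compliance(pred.raw_text, k))
    return OutcomeRecord(
        experiment_id=experiment_id,
        case_id=case.case_id,
        iteration=iteration,
        complete=complete,
        accurate=accurate,
        compliant=compliant,
    )


def _numerator_denominator(
    complete: np.ndarray, accurate: np.ndarray, compliant: np.ndarray, metric: Metric
) -> tuple[np.ndarray, np.ndarray]:
    ones = np.ones_like(complete)
    if metric == "completeness":
        return complete, ones
    if metric == "compliance":
        return compliant, ones
    if metric == "accuracy_overall":
        # Incomplete tasks count as incorrect against the full denominator.
        return accurate * complete, ones
    if metric == "accuracy_completed":
        return accurate * complete, complete
    raise ValueError(f"unknown metric {metric!r}")


def rate_per_iteration(
    records: Sequence[OutcomeRecord], metric: Metric
) -> float | None:
    """p = sum of indicators / denominator for one experiment-iteration.

    Returns ``None`` (undefined, not zero) for completed accuracy when no
    record completed the task.
    """
    if not records:
        raise EmptyExperimentError("no records")
    complete = np.array([r.complete for r in records])
    accurate = np.array([r.accurate for r in records])
    compliant = np.array([r.compliant for r in records])
    num, den = _numerator_denominator(complete, accurate, compliant, metric)
    if den.sum() == 0:
        return None
    return float(num.sum() / den.sum())


def _records_to_matrices(
    records: Sequence[OutcomeRecord],
) -> tuple[list[str], list[int], np.ndarray, np.ndarray, np.ndarray]:
    """Pivot records into (case, iteration) indicator matrices."""
    case_ids = sorted({r.case_id for r in records})
    iterations = sorted({r.iteration for r in records})
    case_idx = {c: i for i, c in enumerate(case_ids)}
    iter_idx = {t: i for i, t in enumerate(iterations)}
    shape = (len(case_ids), len(iterations))
    complete = np.zeros(shape, dtype=np.int64)
    accurate = np.zeros(shape, dtype=np.int64)
    compliant = np.zeros(shape, dtype=np.int64)
    filled = np.zeros(shape, dtype=bool)
    for r in records:
        i, j = case_idx[r.case_id], iter_idx[r.iteration]
        if filled[i, j]:
            raise ConfigurationError(
                f"duplicate record for case {r.case_id!r} iteration {r.iteration}"
            )
        filled[i, j] = True
        complete[i, j] = r.complete
        accurate[i, j] = r.accurate
        compliant[i, j] = r.compliant
    if not filled.all():
        raise ConfigurationError(
            "records do not form a complete case x iteration grid"
        )
    return case_ids, iterations, complete, accurate, compliant


def _mean_over_iterations(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Iteration-averaged rate for stacked samples.

    ``num``/``den`` have shape (..., M, T); returns shape (...,). Iterations
    with zero denominator are skipped; all-undefined yields NaN.
    """
    den_t = den.sum(axis=-2).astype(float)
    num_t = num.sum(axis=-2).astype(float)
    defined = den_t > 0
    rates = np.divide(num_t, den_t, out=np.zeros_like(num_t), where=defined)
    n_defined = defined.sum(axis=-1)
    total = np.where(defined, rates, 0.0).sum(axis=-1)
    return np.where(n_defined > 0, total / np.maximum(n_defined, 1), np.nan)


def summarize_experiment(
    records: Sequence[OutcomeRecord],
    metric: Metric,
    B: int = 100,
    conf: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> MetricSummary:
    """Iteration-averaged rate with a case-resampling percentile bootstrap.

    Deterministic given ``seed``. The resampling unit is the case with its
    full iteration triplet. Bootstrap replicates in which the rate is
    undefined (completed accuracy with no completed task) are dropped from
    the percentile computation.
    """
    if not records:
        raise EmptyExperimentError("cannot summarize an empty experiment")
    experiment_id = records[0].experiment_id
    _, _, complete, accurate, compliant = _records_to_matrices(records)
    num, den = _numerator_denominator(complete, accurate, compliant, metric)
    M = num.shape[0]

    per_iter: list[float] = []
    den_t = den.sum(axis=0)
    num_t = num.sum(axis=0)
    for j in range(num.shape[1]):
        per_iter.append(float(num_t[j] / den_t[j]) if den_t[j] > 0 else float("nan"))
    mean_rate = float(_mean_over_iterations(num, den))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, M, size=(B, M))
    boot = _mean_over_iterations(num[idx], den[idx])  # shape (B,)
    boot = boot[~np.isnan(boot)]
    alpha = (1.0 - conf) / 2.0
    if boot.size:
        ci_low = float(np.percentile(boot, 100 * alpha))
        ci_high = float(np.percentile(boot, 100 * (1 - alpha)))
    else:
        ci_low = ci_high = float("nan")
    return MetricSummary(
        experiment_id=experiment_id,
        metric=metric,
        per_iteration_rates=tuple(per_iter),
        mean_rate=mean_rate,
        ci_low=ci_low,
        ci_high=ci_high,
        n_cases=M,
        n_bootstrap=B,
    )


def summarize_all(
    records: Iterable[OutcomeRecord],
    metrics: Sequence[Metric] = METRICS,
    B: int = 100,
    conf: float = 0.95,
    seed: int | None = None,
) -> list[MetricSummary]:
    """Summaries for every experiment_id x metric present in the records."""
    by_experiment: dict[str, list[OutcomeRecord]] = {}
    for r in records:
        by_experiment.setdefault(r.experiment_id, []).append(r)
    rng = np.random.default_rng(seed)
    summaries = []
    for experiment_id in sorted(by_experiment):
        for metric in metrics:
            summaries.append(
                summarize_experiment(by_experiment[experiment_id], metric, B, conf, rng)
            )
    return summaries
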