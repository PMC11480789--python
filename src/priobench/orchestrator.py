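"""Factorial experiment grids, backend execution, and end-to-end scoring.

The factorial grid is the Cartesian product of models x prompt templates x
input types x task sizes (k). Execution order over (config, case) pairs is
permuted — repeated queries to a hosted model drift over calendar time, and
permutation prevents that drift from confounding any single factor level —
while the iteration triplet of each pair stays contiguous.

Responses are persisted as append-only JSON Lines so a run can resume
after interruption and be re-scored later without re-querying::

    {"experiment_id": ..., "case_id": ..., "iteration": ..., "prompt": ...,
     "response": ..., "backend": ..., "timestamp": ..., "error": ...}
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from . import bias as bias_mod
from .cohort import Case, ExperimentConfig, InputType
from .lexicon import GeneLexicon
from .metrics import METRICS, MetricSummary, OutcomeRecord, evaluate_case, summarize_all
from .parsing import ParsedPrediction, parse_response
from .prompts import PromptTemplate, load_template, render_prompt
from .rag import Embedder, RagIndex, augment_prompt, retrieve
from .synthetic import RequestContext

logger = logging.getLogger(__name__)


class Backend(Protocol):
    """Contract a response backend must satisfy.

    ``respond`` must be total: transient failures should be raised and are
    recorded (and retried) by the runner, never allowed to corrupt the log.
    """

    backend_id: str

    def respond(self, prompt: str, context: RequestContext) -> str: ...


class GridError(ValueError):
    """Raised for invalid grid factor lists."""


class ScoringError(ValueError):
    """Raised when a response log cannot be matched to cohort/config."""


@dataclass(frozen=True)
class ExperimentGrid:
    configs: tuple[ExperimentConfig, ...]
    case_ids: tuple[str, ...]
    order: tuple[tuple[int, int], ...]  # (config index, case index) pairs
    seed: int | None = None


def build_grid(
    models: Sequence[str],
    templates: Sequence[str],
    input_types: Sequence[InputType],
    ks: Sequence[int],
    iterations: int = 3,
) -> list[ExperimentConfig]:
    """Full Cartesian product of the factor levels, in canonical order."""
    for name, factor in (
        ("models", models), ("templates", templates),
        ("input_types", input_types), ("ks", ks),
    ):
        if not factor:
            raise GridError(f"factor list {name!r} is empty")
    return [
        ExperimentConfig(
            model_id=m, template_name=t, input_type=i, k=k, iterations=iterations
        )
        for m, t, i, k in product(models, templates, input_types, ks)
    ]


def make_grid(
    configs: Sequence[ExperimentConfig], cases: Sequence[Case]
) -> ExperimentGrid:
    """Attach a cohort to a config list with canonical (unpermuted) order."""
    order = tuple(
        (ci, si) for ci in range(len(configs)) for si in range(len(cases))
    )
    return ExperimentGrid(
        configs=tuple(configs),
        case_ids=tuple(c.case_id for c in cases),
        order=order,
    )


def permute_order(grid: ExperimentGrid, seed: int) -> ExperimentGrid:
    """Uniformly random, seed-reproducible permutation of (config, case) pairs."""
    rng = np.random.default_rng(seed)
    order = list(grid.order)
    perm = rng.permutation(len(order))
    return replace(grid, order=tuple(order[i] for i in perm), seed=seed)


def _read_log_keys(path: Path) -> set[tuple[str, str, int]]:
    keys = set()
    if path.exists():
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                if line.strip():
                    obj = json.loads(line)
                    keys.add((obj["experiment_id"], obj["case_id"], int(obj["iteration"])))
    return keys


def run(
    grid: ExperimentGrid,
    cohort: Sequence[Case],
    backend: Backend,
    out_path: str | Path,
    iterations: int = 3,
    templates: dict[str, PromptTemplate] | None = None,
    rag_index: RagIndex | None = None,
    rag_embedder: Embedder | None = None,
    rag_top_k: int = 10,
    max_retries: int = 3,
    retry_wait: float = 0.0,
) -> int:
    """Execute the grid, appending one JSONL record per (config, case, t).

    Already-recorded triples are skipped, so an interrupted run resumes
    where it stopped. Backend failures are retried ``max_retries`` times
    and then recorded with an ``error`` field; the run continues. Returns
    the number of newly written records.
    """
    out_path = Path(out_path)
    cases = {c.case_id: c for c in cohort}
    done = _read_log_keys(out_path)
    templates = templates or {}
    written = 0
    with open(out_path, "a", encoding="utf-8") as handle:
        for config_idx, case_idx in grid.order:
            config = grid.configs[config_idx]
            case = cases[grid.case_ids[case_idx]]
            template = templates.get(config.template_name) or load_template(
                config.template_name
            )
            base_prompt = render_prompt(template, case, config.input_type, config.k)
            if rag_index is not None:
                docs = retrieve(base_prompt, rag_index, rag_top_k, rag_embedder)
                prompt = augment_prompt(base_prompt, docs)
            else:
                prompt = base_prompt
            for iteration in range(1, iterations + 1):
                key = (config.config_id, case.case_id, iteration)
                if key in done:
                    continue
                context = RequestContext(config=config, case=case, iteration=iteration)
                response, error = None, None
                for attempt in range(max_retries + 1):
                    try:
                        response = backend.respond(prompt, context)
                        break
                    except Exception as exc:  # recorded, run continues
                        error = f"{type(exc).__name__}: {exc}"
                        logger.warning(
                            "backend failure on %s (attempt %d/%d): %s",
                            key, attempt + 1, max_retries + 1, error,
                        )
                        if retry_wait:
                            time.sleep(retry_wait * (2 ** attempt))
                record = {
                    "experiment_id": config.config_id,
                    "case_id": case.case_id,
                    "iteration": iteration,
                    "prompt": prompt,
                    "response": response,
                    "backend": backend.backend_id,
                    "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                }
                if response is None:
                    record["error"] = error
                handle.write(json.dumps(record) + "\n")
                written += 1
    return written


def parse_config_id(config_id: str) -> ExperimentConfig:
    """Recover an ExperimentConfig from its ``model|template|input|kN`` id."""
    try:
        model_id, template_name, input_type, k_part = config_id.split("|")
        return ExperimentConfig(
            model_id=model_id,
            template_name=template_name,
            input_type=input_type,  # type: ignore[arg-type]
            k=int(k_part.lstrip("k")),
        )
    except ValueError as exc:
        raise ScoringError(f"unparseable experiment id {config_id!r}") from exc


@dataclass(frozen=True)
class ScoreResult:
    records: tuple[OutcomeRecord, ...]
    predictions: dict[tuple[str, str, int], ParsedPrediction]
    summaries: tuple[MetricSummary, ...]
    n_orphans: int


def score(
    responses_path: str | Path,
    cohort: Sequence[Case],
    lexicon: GeneLexicon,
    bootstrap_reps: int = 100,
    seed: int | None = None,
) -> ScoreResult:
    """Parse and score a response log end to end.

    Every log record must match a known case; records naming unknown cases
    are counted as orphans and reported (callers should treat a non-zero
    orphan count as failure). Records with a recorded backend ``error``
    (null response) are scored as refusal-free empty predictions:
    incomplete, inaccurate, non-compliant.
    """
    cases = {c.case_id: c for c in cohort}
    records: list[OutcomeRecord] = []
    predictions: dict[tuple[str, str, int], ParsedPrediction] = {}
    orphans: list[str] = []
    with open(responses_path, encoding="utf-8") as handle:
        for line in handle:
            if not line.strip():
                continue
            obj = json.loads(line)
            case = cases.get(obj["case_id"])
            if case is None:
                orphans.append(obj["case_id"])
                continue
            config = parse_config_id(obj["experiment_id"])
            text = obj.get("response") or ""
            pred = parse_response(text, lexicon)
            key = (obj["experiment_id"], obj["case_id"], int(obj["iteration"]))
            predictions[key] = pred
            records.append(
                evaluate_case(
                    pred, case, lexicon, config.k,
                    experiment_id=obj["experiment_id"],
                    iteration=int(obj["iteration"]),
                )
            )
    if orphans:
        logger.error("orphan records for unknown cases: %s", sorted(set(orphans))[:20])
    summaries = summarize_all(records, METRICS, B=bootstrap_reps, seed=seed)
    return ScoreResult(
        records=tuple(records),
        predictions=predictions,
        summaries=tuple(summaries),
        n_orphans=len(orphans),
    )


def metrics_report_frame(summaries: Iterable[MetricSummary]) -> pd.DataFrame:
    """Metrics report table (experiment x metric) for CSV export."""
    rows = []
    for s in summaries:
        config = parse_config_id(s.experiment_id)
        rows.append(
            {
                "experiment_id": s.experiment_id,
                "model_id": config.model_id,
                "template": config.template_name,
                "input_type": config.input_type,
                "k": config.k,
                "metric": s.metric,
                "mean_rate": s.mean_rate,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "n_cases": s.n_cases,
                "n_bootstrap": s.n_bootstrap,
            }
        )
    return pd.DataFrame(rows)


def bias_from_scores(
    result: ScoreResult,
    pool_occurrences: dict[str, int],
    null_model: bias_mod.NullModel = "pool_frequency",
    per_k: Sequence[int] = (10, 50),
) -> pd.DataFrame:
    """Observed/expected/OR bias table pooled over all scored experiments.

    Observed counts truncate each prediction at the experiment's own k; a
    separate column is emitted per requested truncation depth alongside the
    OR computed at the experiment-native k.
    """
    native_observed: dict[str, int] = {}
    per_k_observed: dict[int, dict[str, int]] = {k: {} for k in per_k}
    n_experiments = 0
    total_k = 0
    for (experiment_id, _, _), pred in result.predictions.items():
        k = parse_config_id(experiment_id).k
        n_experiments += 1
        total_k += k
        for gene in set(pred.genes[:k]):
            native_observed[gene] = native_observed.get(gene, 0) + 1
        for depth in per_k:
            for gene in set(pred.genes[:depth]):
                per_k_observed[depth][gene] = per_k_observed[depth].get(gene, 0) + 1
    mean_k = total_k / n_experiments if n_experiments else 0
    expected = bias_mod.expected_counts(
        pool_occurrences, n_experiments, mean_k, null_model=null_model
    )
    rows = bias_mod.odds_ratios(native_observed, expected, pool_occurrences)
    frame = bias_mod.bias_report_frame(rows)
    for depth in per_k:
        frame[f"observed_top{depth}"] = [
            per_k_observed[depth].get(g, 0) for g in frame["gene"]
        ]
    return frame
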