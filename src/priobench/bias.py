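"""Gene-dependent prediction bias and response stability statistics.

Language models do not sample candidate genes at the rate the diagnosed-gene
pool would suggest: heavily studied genes (BRCA1, TP53, PTEN) are
over-predicted and sparsely published genes may never be emitted. This
module quantifies that bias as an observed/expected odds ratio per gene and
relates it to publication counts, and tallies how often repeated identical
queries disagree (across iterations, and across sessions run months apart).

The expected count is defined by a pluggable null model; the default
pictures an unbiased predictor filling each of the k slots by drawing from
the diagnosed-gene pool proportionally to pool frequency, so
``expected_g = N_experiments * k * pool_freq_g``. A gene with observed = 0
has OR = 0 ("never predicted"); a gene with expected = 0 has an undefined
OR, reported as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import OutcomeRecord
from .parsing import ParsedPrediction

NullModel = Literal["pool_frequency", "pool_uniform", "lexicon_uniform"]


class AlignmentError(ValueError):
    """Raised when paired record sets do not cover the same experiments."""


@dataclass(frozen=True)
class BiasRow:
    gene: str
    observed: int
    expected: float
    odds_ratio: float | None  # None when expected == 0
    in_diagnosed_pool: bool
    pool_occurrences: int


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float | None
    p_value: float | None
    n_genes: int
    method: str
    low_n: bool
    undefined_reason: str | None
    bin_summary: pd.DataFrame  # mean OR over equal-width log10-count bins


@dataclass(frozen=True)
class StabilitySummary:
    n_experiments: int
    n_discordant_completion: int
    n_discordant_accuracy: int
    n_discordant_compliance: int
    cross_session: dict[str, dict[str, int]] | None = None


def prediction_counts(
    predictions: Iterable[ParsedPrediction], k: int
) -> dict[str, int]:
    """Observed counts: experiments whose top-k prediction contains the gene.

    One count per experiment even if the gene repeats within a response
    (predictions are already deduplicated at parse time).
    """
    counts: dict[str, int] = {}
    for pred in predictions:
        for gene in set(pred.genes[:k]):
            counts[gene] = counts.get(gene, 0) + 1
    return counts


def expected_counts(
    pool_occurrences: Mapping[str, int],
    n_experiments: int,
    k: int,
    null_model: NullModel = "pool_frequency",
    lexicon_size: int | None = None,
) -> dict[str, float]:
    """Expected prediction counts per pool gene under a null predictor."""
    if not pool_occurrences:
        raise ValueError("diagnosed pool is empty")
    total = sum(pool_occurrences.values())
    n_pool = len(pool_occurrences)
    expected: dict[str, float] = {}
    for gene, occ in pool_occurrences.items():
        if null_model == "pool_frequency":
            expected[gene] = n_experiments * k * occ / total
        elif null_model == "pool_uniform":
            expected[gene] = n_experiments * k / n_pool
        elif null_model == "lexicon_uniform":
            if not lexicon_size:
                raise ValueError("lexicon_uniform null model needs lexicon_size")
            expected[gene] = n_experiments * k / lexicon_size
        else:
            raise ValueError(f"unknown null model {null_model!r}")
    return expected


def odds_ratios(
    observed: Mapping[str, int],
    expected: Mapping[str, float],
    pool_occurrences: Mapping[str, int] | None = None,
) -> list[BiasRow]:
    """One BiasRow per gene in observed ∪ expected, sorted by symbol."""
    pool = dict(pool_occurrences or {})
    rows = []
    for gene in sorted(set(observed) | set(expected)):
        obs = int(observed.get(gene, 0))
        exp = float(expected.get(gene, 0.0))
        if exp > 0:
            ratio: float | None = obs / exp
        else:
            ratio = None  # expected 0: undefined, reported missing
        rows.append(
            BiasRow(
                gene=gene,
                observed=obs,
                expected=exp,
                odds_ratio=ratio,
                in_diagnosed_pool=gene in pool if pool else gene in expected,
                pool_occurrences=pool.get(gene, 0),
            )
        )
    return rows


def never_predicted(
    rows: Sequence[BiasRow], pool: Mapping[str, int] | None = None
) -> tuple[list[str], int]:
    """Pool genes with observed = 0 (OR = 0), and their count."""
    genes = [
        r.gene
        for r in rows
        if r.observed == 0 and (r.gene in pool if pool is not None else r.in_diagnosed_pool)
    ]
    return genes, len(genes)


def citation_correlation(
    rows: Sequence[BiasRow],
    citations: Mapping[str, float],
    method: Literal["pearson", "spearman"] = "pearson",
    n_bins: int = 4,
) -> CorrelationResult:
    """Correlate log10 publication counts with odds ratios.

    Uses genes with a positive citation count and a defined OR. Also returns
    mean ORs over ``n_bins`` equal-width bins of log10 citation count (the
    grouped view of the same trend). With fewer than three usable genes the
    computation still runs but is flagged low-n; a constant input vector
    yields an undefined-correlation signal instead of a coefficient.
    """
    pairs = [
        (math.log10(citations[r.gene]), r.odds_ratio)
        for r in rows
        if r.gene in citations and citations[r.gene] > 0 and r.odds_ratio is not None
    ]
    if len(pairs) < 2:
        raise ValueError("need at least two genes with citations and defined OR")
    logc = np.array([p[0] for p in pairs])
    ors = np.array([p[1] for p in pairs])

    edges = np.linspace(logc.min(), logc.max(), n_bins + 1)
    bin_idx = np.clip(np.digitize(logc, edges[1:-1]), 0, n_bins - 1)
    bin_summary = pd.DataFrame(
        {
            "bin": range(n_bins),
            "log10_count_low": edges[:-1],
            "log10_count_high": edges[1:],
            "n_genes": [int((bin_idx == b).sum()) for b in range(n_bins)],
            "mean_odds_ratio": [
                float(ors[bin_idx == b].mean()) if (bin_idx == b).any() else float("nan")
                for b in range(n_bins)
            ],
        }
    )

    undefined = None
    coefficient = p_value = None
    if np.ptp(logc) == 0 or np.ptp(ors) == 0:
        undefined = "constant input vector"
    else:
        if method == "pearson":
            coefficient, p_value = stats.pearsonr(logc, ors)
        else:
            coefficient, p_value = stats.spearmanr(logc, ors)
        coefficient, p_value = float(coefficient), float(p_value)
    return CorrelationResult(
        coefficient=coefficient,
        p_value=p_value,
        n_genes=len(pairs),
        method=method,
        low_n=len(pairs) < 3,
        undefined_reason=undefined,
        bin_summary=bin_summary,
    )


def _group_by_experiment(
    records: Iterable[OutcomeRecord],
) -> dict[tuple[str, str], list[OutcomeRecord]]:
    grouped: dict[tuple[str, str], list[OutcomeRecord]] = {}
    for r in records:
        grouped.setdefault((r.experiment_id, r.case_id), []).append(r)
    return grouped


def _discordance(grouped: Mapping[tuple[str, str], list[OutcomeRecord]]) -> tuple[int, int, int]:
    d_complete = d_accurate = d_compliant = 0
    for key, recs in grouped.items():
        if len(recs) < 2:
            raise ValueError(
                f"experiment {key} has fewer than 2 iterations; "
                "stability needs repeated calls"
            )
        d_complete += len({r.complete for r in recs}) > 1
        d_accurate += len({r.accurate for r in recs}) > 1
        d_compliant += len({r.compliant for r in recs}) > 1
    return d_complete, d_accurate, d_compliant


def stability_summary(
    records: Iterable[OutcomeRecord],
    other_session: Iterable[OutcomeRecord] | None = None,
) -> StabilitySummary:
    """Discordance tallies across iterations (and optionally across sessions).

    An experiment (one experiment_id x case pair with its T >= 2 iterations)
    is discordant on a metric iff its iteration indicators are not all
    equal. In cross-session mode the two record sets are paired by
    experiment and, per metric, experiments whose *number of successful
    iterations* is unchanged between sessions are tallied as "same".
    """
    grouped = _group_by_experiment(records)
    d_complete, d_accurate, d_compliant = _discordance(grouped)
    cross = None
    if other_session is not None:
        other = _group_by_experiment(other_session)
        missing = sorted(set(grouped) ^ set(other))
        if missing:
            raise AlignmentError(
                f"experiment sets differ between sessions: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        cross = {}
        for metric, attr in (
            ("completion", "complete"),
            ("accuracy", "accurate"),
            ("compliance", "compliant"),
        ):
            same = 0
            for key in grouped:
                a = sum(getattr(r, attr) for r in grouped[key])
                b = sum(getattr(r, attr) for r in other[key])
                same += a == b
            cross[metric] = {"same": same, "changed": len(grouped) - same}
    return StabilitySummary(
        n_experiments=len(grouped),
        n_discordant_completion=d_complete,
        n_discordant_accuracy=d_accurate,
        n_discordant_compliance=d_compliant,
        cross_session=cross,
    )


def bias_report_frame(rows: Sequence[BiasRow]) -> pd.DataFrame:
    """Tabular bias report (one row per gene) for CSV export."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "observed": [r.observed for r in rows],
            "expected": [r.expected for r in rows],
            "odds_ratio": [
                r.odds_ratio if r.odds_ratio is not None else float("nan") for r in rows
            ],
            "in_pool": [r.in_diagnosed_pool for r in rows],
            "pool_occurrences": [r.pool_occurrences for r in rows],
        }
    )
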