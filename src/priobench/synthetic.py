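"""Synthetic study inputs and a parameterized simulated responder.

Every pipeline stage is exercised end to end without network access by
generating the four input artifacts (gene-symbol lexicon, gene-phenotype
annotation table, cohort, citation counts) and by a simulated responder
whose behaviour catalogue mirrors what real chat models do on this task:
refusals and ethical declinations, truncated lists, duplicated symbols,
fabricated family-extension symbols (a real root with an invented numeric
suffix, OPA50-style), citation-weighted gene choice, and format drift
between clean comma lists and numbered prose lists.

Because every behaviour is governed by an explicit probability, the
evaluation metrics can be validated by parameter recovery: the measured
completeness rate estimates ``p_complete``, completed accuracy estimates
``p_hit`` (for hit ranks within k), and the compliance rate estimates
``p_complete * p_comply`` (a truncated list can never contain the k-symbol
comma run, and refusals are compliant by definition).

Cohort defaults emulate the study conditions this harness is built for:
276 cases, a diagnosed pool of 165 distinct genes with a skewed occurrence
distribution (a few recurrent genes, most singletons), and per-case HPO
term counts drawn from a rounded normal with mean 12 and s.d. 6 (the
9-35 term range seen across real case collections), clipped to >= 1.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import Case, ExperimentConfig, write_cohort
from .lexicon import GeneLexicon, canonicalize

GenePhenotypeMap = dict[str, list[tuple[str, str]]]


class GenerationError(ValueError):
    """Raised when a response cannot be generated under the given params."""


# ---------------------------------------------------------------------------
# input artifact generators


def synthetic_gene_symbols(n_genes: int) -> list[str]:
    """Deterministic synthetic approved symbols GENE001..GENEnnn."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    width = max(3, len(str(n_genes)))
    return [f"GENE{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_lexicon_table(
    n_genes: int,
    seed: int = 0,
    alias_fraction: float = 0.25,
    prev_fraction: float = 0.2,
    path: str | Path | None = None,
) -> list[tuple[str, str, str]]:
    """Rows (symbol, alias_symbol, prev_symbol) of a synthetic lexicon TSV.

    A random subset of genes receives an alias (``G<i>AL``) and/or a
    previous symbol (``G<i>PR``), exercising the resolution paths.
    """
    rng = np.random.default_rng(seed)
    genes = synthetic_gene_symbols(n_genes)
    rows = []
    for i, gene in enumerate(genes, start=1):
        alias = f"G{i}AL" if rng.random() < alias_fraction else ""
        prev = f"G{i}PR" if rng.random() < prev_fraction else ""
        rows.append((gene, alias, prev))
    if path is not None:
        lines = ["symbol\talias_symbol\tprev_symbol\tstatus"]
        lines += [f"{s}\t{a}\t{p}\tApproved" for s, a, p in rows]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return rows


def generate_gene_phenotype_map(
    n_genes: int,
    phenotypes_per_gene: int,
    seed: int = 0,
    genes: Sequence[str] | None = None,
    phenotype_pool_factor: float = 3.0,
    path: str | Path | None = None,
) -> GenePhenotypeMap:
    """Assign each gene a set of phenotype terms from a shared label pool.

    The phenotype universe holds roughly ``n_genes * phenotypes_per_gene /
    phenotype_pool_factor`` labels so gene phenotype sets overlap, as real
    disease-gene annotations do. Writes the annotation TSV dialect consumed
    by :func:`priobench.rag.load_annotations` when ``path`` is given.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if phenotypes_per_gene < 1:
        raise ValueError("phenotypes_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = synthetic_gene_symbols(n_genes)
    else:
        genes = list(genes)[:n_genes]
    n_phenotypes = max(
        phenotypes_per_gene, int(round(n_genes * phenotypes_per_gene / phenotype_pool_factor))
    )
    labels = [f"phenotype feature {i:04d}" for i in range(1, n_phenotypes + 1)]
    ids = [f"HP:{9000000 + i:07d}"[:10] for i in range(1, n_phenotypes + 1)]
    terms = list(zip(ids, labels))
    g2p: GenePhenotypeMap = {}
    for gene in genes:
        picked = rng.choice(n_phenotypes, size=phenotypes_per_gene, replace=False)
        g2p[gene] = [terms[j] for j in sorted(picked)]
    if path is not None:
        write_annotations(g2p, path)
    return g2p


def write_annotations(g2p: GenePhenotypeMap, path: str | Path) -> None:
    """Write the gene-phenotype map in genes_to_phenotype.txt dialect."""
    lines = ["gene_symbol\thpo_id\thpo_name"]
    for gene, terms in g2p.items():
        for hpo_id, label in terms:
            lines.append(f"{gene}\t{hpo_id}\t{label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def skewed_pool_weights(n: int, skew: float = 0.8) -> np.ndarray:
    """Zipf-like pool weights: a few recurrent genes, a long singleton tail."""
    ranks = np.arange(1, n + 1, dtype=np.float64)
    weights = ranks ** (-skew)
    return weights / weights.sum()


def generate_cohort(
    g2p: GenePhenotypeMap,
    n_cases: int = 276,
    terms_mean: float = 12.0,
    terms_sd: float = 6.0,
    noise_rate: float = 0.1,
    seed: int = 0,
    pool_size: int = 165,
    pool_skew: float = 0.8,
    with_free_text: bool = True,
    source: str = "synthetic",
    path: str | Path | None = None,
) -> list[Case]:
    """Draw a synthetic cohort from a gene-phenotype map.

    Each case draws its diagnosed gene from a skewed pool, then samples the
    gene's phenotype terms plus a ``noise_rate`` fraction of terms from
    other genes; term count is a rounded normal clipped to >= 1. With
    ``noise_rate=0`` every case's terms are a subset of its gene's set.
    """
    if not g2p:
        raise ValueError("gene-phenotype map is empty")
    rng = np.random.default_rng(seed)
    genes = list(g2p)
    pool = genes[: min(pool_size, len(genes))]
    weights = skewed_pool_weights(len(pool), pool_skew)
    all_terms = sorted({t for terms in g2p.values() for t in terms})
    cases = []
    for i in range(1, n_cases + 1):
        gene = pool[int(rng.choice(len(pool), p=weights))]
        own = g2p[gene]
        n_terms = max(1, int(round(rng.normal(terms_mean, terms_sd))))
        n_noise = int(round(n_terms * noise_rate))
        n_signal = min(max(1, n_terms - n_noise), len(own))
        picked = [own[j] for j in sorted(rng.choice(len(own), size=n_signal, replace=False))]
        others = [t for t in all_terms if t not in set(own)]
        if n_noise and others:
            noise_idx = rng.choice(len(others), size=min(n_noise, len(others)), replace=False)
            picked += [others[j] for j in sorted(noise_idx)]
        free_text = _narrative(picked) if with_free_text else ""
        cases.append(
            Case(
                case_id=f"case{i:04d}",
                source=source,
                hpo_terms=tuple(picked),
                free_text=free_text,
                diagnosed_gene=gene,
            )
        )
    if path is not None:
        write_cohort(cases, path)
    return cases


def _narrative(terms: Sequence[tuple[str, str]]) -> str:
    labels = [label for _, label in terms]
    if len(labels) == 1:
        body = labels[0]
    else:
        body = ", ".join(labels[:-1]) + ", and " + labels[-1]
    return f"The patient presents with {body}. No genomic analysis is available."


def generate_citations(
    genes: Sequence[str],
    seed: int = 0,
    mean_log10: float = 4.0,
    sd_log10: float = 1.0,
    path: str | Path | None = None,
) -> dict[str, int]:
    """Log-normal publication counts per gene (``gene<TAB>count`` on disk)."""
    rng = np.random.default_rng(seed)
    counts = {
        gene: max(1, int(round(10 ** rng.normal(mean_log10, sd_log10))))
        for gene in genes
    }
    if path is not None:
        lines = [f"{gene}\t{count}" for gene, count in counts.items()]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return counts


def load_citations(path: str | Path) -> dict[str, int]:
    """Read a two-column ``gene<TAB>count`` table ("#" comments allowed)."""
    counts: dict[str, int] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        gene, _, count = line.partition("\t")
        counts[gene.strip()] = int(float(count))
    return counts


# ---------------------------------------------------------------------------
# simulated responder


@dataclass(frozen=True)
class ResponderParams:
    """Behaviour probabilities of the simulated responder.

    p_refuse:
        Probability of an outright refusal ("not applicable" or an ethical
        declination).
    p_complete:
        Given no refusal, probability of emitting a full k-slot list; the
        complement emits a truncated list with fewer than k/2 valid symbols.
    p_hit:
        Given a full list, probability the diagnosed gene appears at all.
    hit_rank_q:
        Geometric parameter of the diagnosed gene's rank given a hit,
        truncated at k (larger q concentrates hits at the top).
    citation_weights:
        Gene -> positive weight for filler sampling; ``None`` means uniform
        over the lexicon's approved symbols.
    gamma:
        Exponent skewing filler choice proportional to weight**gamma;
        gamma=0 is unbiased over the weight support.
    p_fabricate:
        Per-slot probability of replacing the sampled symbol with a
        fabricated family extension (root symbol + shifted numeric suffix).
    p_duplicate:
        Per-slot probability of repeating an earlier symbol instead of a
        new one.
    p_comply:
        Probability of clean comma-list formatting; otherwise a numbered
        prose list is emitted.
    """

    p_complete: float = 0.8
    p_refuse: float = 0.05
    p_hit: float = 0.17
    hit_rank_q: float = 0.3
    citation_weights: Mapping[str, float] | None = None
    gamma: float = 1.0
    p_fabricate: float = 0.02
    p_comply: float = 0.8
    p_duplicate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("p_complete", "p_refuse", "p_hit",
                     "p_fabricate", "p_comply", "p_duplicate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if not 0.0 < self.hit_rank_q <= 1.0:
            raise ValueError("hit_rank_q must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.citation_weights is not None and any(
            w <= 0 for w in self.citation_weights.values()
        ):
            raise ValueError("citation_weights must be strictly positive")


_REFUSALS = (
    "not applicable",
    "[not applicable]",
    "I'm sorry, but as an AI language model I cannot provide a genetic diagnosis.",
)


def _fabricate(symbol: str, rng: np.random.Generator, lexicon: GeneLexicon) -> str:
    """Family-extension hallucination: root symbol with a shifted suffix."""
    root = symbol.rstrip("0123456789")
    suffix = symbol[len(root):]
    number = int(suffix) if suffix else 0
    candidate = f"{root[:6]}{number + 50 + int(rng.integers(0, 50))}"
    while canonicalize(candidate, lexicon) is not None and len(candidate) < 10:
        candidate += "9"
    return candidate


def simulate_response(
    case: Case,
    params: ResponderParams,
    k: int,
    lexicon: GeneLexicon,
    rng: np.random.Generator | int | None = None,
    filler_genes: Sequence[str] | None = None,
) -> str:
    """Emit one raw response text for a case under the behaviour params.

    The diagnosed gene is excluded from filler sampling so its appearance
    probability is exactly ``p_hit``; the hit slot is never fabricated or
    duplicated. Fillers are drawn without replacement proportionally to
    ``weight**gamma``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if params.citation_weights is not None:
        universe = list(params.citation_weights)
        raw_weights = np.array(
            [params.citation_weights[g] for g in universe], dtype=np.float64
        )
    else:
        universe = sorted(lexicon.approved)
        raw_weights = np.ones(len(universe), dtype=np.float64)
    diagnosed = canonicalize(case.diagnosed_gene, lexicon) or case.diagnosed_gene.upper()
    keep = [i for i, g in enumerate(universe) if g != diagnosed]
    fillers = [universe[i] for i in keep]
    weights = raw_weights[keep] ** params.gamma
    weights = weights / weights.sum() if weights.size else weights

    if rng.random() < params.p_refuse:
        return _REFUSALS[int(rng.choice(len(_REFUSALS), p=[0.6, 0.2, 0.2]))]

    complete = rng.random() < params.p_complete
    if complete:
        n_slots = k
        hit = rng.random() < params.p_hit
    else:
        half = math.ceil(k / 2)
        n_slots = int(rng.integers(1, max(half, 2)))  # < k/2 valid symbols
        hit = False
    n_fill = n_slots - int(hit)
    if n_fill > len(fillers) and params.p_fabricate == 0:
        raise GenerationError(
            f"need {n_fill} filler genes but only {len(fillers)} are available "
            "and fabrication is disabled"
        )
    n_draw = min(n_fill, len(fillers))
    drawn = (
        [fillers[i] for i in rng.choice(len(fillers), size=n_draw, replace=False, p=weights)]
        if n_draw
        else []
    )
    while len(drawn) < n_fill:  # pad with fabrications when fillers run out
        drawn.append(_fabricate(str(rng.choice(fillers or [diagnosed])), rng, lexicon))

    protected: set[int] = set()
    symbols = drawn
    if hit:
        rank = min(int(rng.geometric(params.hit_rank_q)), n_slots)
        symbols = drawn[: rank - 1] + [diagnosed] + drawn[rank - 1:]
        protected.add(rank - 1)

    for i in range(len(symbols)):
        if i in protected:
            continue
        if params.p_fabricate and rng.random() < params.p_fabricate:
            symbols[i] = _fabricate(symbols[i], rng, lexicon)
        elif params.p_duplicate and i > 0 and rng.random() < params.p_duplicate:
            symbols[i] = symbols[int(rng.integers(0, i))]

    if rng.random() < params.p_comply:
        return ", ".join(symbols)
    lines = [f"{i}. {s}" for i, s in enumerate(symbols, start=1)]
    return "Here are candidate genes worth testing:\n" + "\n".join(lines)


class SimulatedBackend:
    """Deterministic drop-in backend running the simulated responder.

    The per-response random stream is derived from the backend seed and a
    CRC of (experiment id, case id, iteration), so responses are stable
    under resumption and independent of execution order.
    """

    def __init__(
        self,
        params: ResponderParams,
        lexicon: GeneLexicon,
        seed: int = 0,
        backend_id: str = "simulated",
    ):
        self.params = params
        self.lexicon = lexicon
        self.seed = int(seed)
        self.backend_id = backend_id
        self.declared_params = {"temperature": 0.0, "model": backend_id}

    def _rng(self, config: ExperimentConfig, case: Case, iteration: int) -> np.random.Generator:
        key = zlib.crc32(f"{config.config_id}|{case.case_id}|{iteration}".encode())
        return np.random.default_rng((self.seed, key))

    def respond(self, prompt: str, context: "RequestContext") -> str:
        if context.case is None or context.config is None:
            raise GenerationError("simulated backend requires case/config context")
        rng = self._rng(context.config, context.case, context.iteration)
        return simulate_response(
            context.case, self.params, context.config.k, self.lexicon, rng
        )


@dataclass(frozen=True)
class RequestContext:
    """Per-call metadata handed to a backend alongside the prompt."""

    config: ExperimentConfig | None = None
    case: Case | None = None
    iteration: int = 1
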