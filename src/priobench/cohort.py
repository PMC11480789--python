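"""Case and experiment-configuration containers, plus cohort JSONL I/O.

A case is one individual's phenotype presentation — an ordered list of HPO
terms (``HP:NNNNNNN`` id + concept label) and/or a free-text narrative —
together with the diagnosed gene that serves as ground truth.

Cohorts are stored as JSON Lines, one case per line::

    {"case_id": "...", "source": "...",
     "hpo_terms": [{"id": "HP:0001250", "label": "Seizure"}],
     "free_text": "...", "diagnosed_gene": "SCN1A"}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .lexicon import GeneLexicon, canonicalize

InputType = Literal["hpo", "free_text"]

DEFAULT_KS = (10, 50)


class CohortError(ValueError):
    """Raised for malformed or invalid cohort lines."""


@dataclass(frozen=True)
class Case:
    """One individual: phenotype input plus the diagnosed gene."""

    case_id: str
    source: str
    hpo_terms: tuple[tuple[str, str], ...]  # (hpo_id, label) pairs
    free_text: str
    diagnosed_gene: str

    def __post_init__(self) -> None:
        if not self.hpo_terms and not self.free_text:
            raise CohortError(
                f"case {self.case_id!r}: at least one of hpo_terms/free_text "
                "must be non-empty"
            )
        if not self.diagnosed_gene:
            raise CohortError(f"case {self.case_id!r}: diagnosed_gene is empty")

    def has_modality(self, input_type: InputType) -> bool:
        if input_type == "hpo":
            return bool(self.hpo_terms)
        return bool(self.free_text)


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the factorial experiment grid."""

    model_id: str
    template_name: str
    input_type: InputType
    k: int
    iterations: int = 3

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def config_id(self) -> str:
        return f"{self.model_id}|{self.template_name}|{self.input_type}|k{self.k}"


def case_to_json(case: Case) -> dict:
    return {
        "case_id": case.case_id,
        "source": case.source,
        "hpo_terms": [{"id": i, "label": l} for i, l in case.hpo_terms],
        "free_text": case.free_text,
        "diagnosed_gene": case.diagnosed_gene,
    }


def case_from_json(obj: dict) -> Case:
    terms = tuple(
        (str(t["id"]), str(t["label"])) for t in obj.get("hpo_terms") or []
    )
    return Case(
        case_id=str(obj["case_id"]),
        source=str(obj.get("source", "")),
        hpo_terms=terms,
        free_text=str(obj.get("free_text") or ""),
        diagnosed_gene=str(obj["diagnosed_gene"]),
    )


def load_cohort(path: str | Path, lexicon: GeneLexicon | None = None) -> list[Case]:
    """Load and validate a cohort JSONL file.

    Invalid lines are rejected with their line number. When a lexicon is
    supplied, every diagnosed gene must canonicalize (to itself or via a
    previous/alias form); an unresolvable diagnosed gene is a configuration
    error because no prediction could ever be scored correct for it.
    """
    cases: list[Case] = []
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortError(f"{path}:{line_no}: malformed JSON ({exc})") from exc
            try:
                case = case_from_json(obj)
            except (KeyError, TypeError, CohortError) as exc:
                raise CohortError(f"{path}:{line_no}: invalid case ({exc})") from exc
            if lexicon is not None and canonicalize(case.diagnosed_gene, lexicon) is None:
                raise CohortError(
                    f"{path}:{line_no}: diagnosed gene {case.diagnosed_gene!r} "
                    "does not resolve under the active lexicon"
                )
            cases.append(case)
    return cases


def write_cohort(cases: Iterable[Case], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for case in cases:
            handle.write(json.dumps(case_to_json(case)) + "\n")


def diagnosed_pool(cases: Iterable[Case], lexicon: GeneLexicon | None = None) -> dict[str, int]:
    """Occurrence counts of diagnosed genes (canonicalized when possible)."""
    pool: dict[str, int] = {}
    for case in cases:
        gene = case.diagnosed_gene
        if lexicon is not None:
            gene = canonicalize(gene, lexicon) or gene
        pool[gene] = pool.get(gene, 0) + 1
    return pool
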