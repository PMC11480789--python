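"""Prompt templates and rendering.

Five templates ship with the package: four zero-shot variants that layer a
role assignment ("Consider you are a genetic counselor.") and/or an extra
instruction block onto the base query, and one few-shot variant with three
worked examples (a neoplasm example, a seizure/developmental-delay example,
and a nonsense-token example answered "not applicable").

Templates carry exactly two placeholders: ``[phenotype list]`` (the rendered
phenotype input) and ``[top k]`` (becomes "top 10"/"top 50"). Rendering is a
pure function of (template, case, input type, k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .cohort import Case, DEFAULT_KS, InputType

logger = logging.getLogger(__name__)

PHENOTYPE_PLACEHOLDER = "[phenotype list]"
TOPK_PLACEHOLDER = "[top k]"

#: Shipped template names, in canonical grid order.
ZERO_SHOT_TEMPLATES = (
    "original",
    "original_role",
    "original_instruction",
    "original_role_instruction",
)
TEMPLATE_NAMES = ZERO_SHOT_TEMPLATES + ("few_shot",)

#: Separator between HPO concept labels in the rendered phenotype list.
HPO_LABEL_SEPARATOR = "; "


class TemplateError(ValueError):
    """Raised when a template violates the placeholder contract."""


class ModalityError(ValueError):
    """Raised when a case lacks the requested input modality."""


@dataclass(frozen=True)
class PromptTemplate:
    name: str
    body: str

    def __post_init__(self) -> None:
        for placeholder in (PHENOTYPE_PLACEHOLDER, TOPK_PLACEHOLDER):
            count = self.body.count(placeholder)
            if count != 1:
                raise TemplateError(
                    f"template {self.name!r} must contain {placeholder!r} "
                    f"exactly once (found {count})"
                )


def load_template(name: str) -> PromptTemplate:
    """Load a shipped template by name."""
    if name not in TEMPLATE_NAMES:
        raise TemplateError(
            f"unknown template {name!r}; shipped templates: {', '.join(TEMPLATE_NAMES)}"
        )
    body = (
        resources.files("priobench.resources.templates")
        .joinpath(f"{name}.txt")
        .read_text(encoding="utf-8")
        .rstrip("\n")
    )
    return PromptTemplate(name=name, body=body)


def load_templates_dir(directory: str | Path) -> dict[str, PromptTemplate]:
    """Load user templates from a directory of ``.txt`` files."""
    templates = {}
    for path in sorted(Path(directory).glob("*.txt")):
        templates[path.stem] = PromptTemplate(
            name=path.stem, body=path.read_text(encoding="utf-8").rstrip("\n")
        )
    return templates


def render_phenotype_list(case: Case, input_type: InputType) -> str:
    """Render a case's phenotype input for prompt substitution.

    HPO input joins concept labels with ``"; "``; free-text input is the
    narrative verbatim.
    """
    if not case.has_modality(input_type):
        raise ModalityError(
            f"case {case.case_id!r} has no {input_type!r} input"
        )
    if input_type == "hpo":
        return HPO_LABEL_SEPARATOR.join(label for _, label in case.hpo_terms)
    return case.free_text


def render_prompt(
    template: PromptTemplate, case: Case, input_type: InputType, k: int
) -> str:
    """Substitute both placeholders; the result contains no residual brackets."""
    if k not in DEFAULT_KS:
        logger.warning("non-standard k=%d (standard task sizes: %s)", k, DEFAULT_KS)
    rendered = template.body.replace(
        PHENOTYPE_PLACEHOLDER, render_phenotype_list(case, input_type)
    ).replace(TOPK_PLACEHOLDER, f"top {k}")
    return rendered


def render_few_shot_prompt(case: Case, input_type: InputType, k: int) -> str:
    """Render the few-shot template (three worked examples + query block)."""
    return render_prompt(load_template("few_shot"), case, input_type, k)
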