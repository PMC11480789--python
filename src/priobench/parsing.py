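"""Structured extraction from raw model responses.

A response is reduced to: the ordered list of canonical (approved) gene
symbols it names, the symbol-shaped tokens it fabricated (family extensions
like ``OPA50`` that resolve to nothing), whether it is a refusal, and
whether it complies with the requested output structure (a comma-separated
list of at least k symbols, or the literal "not applicable").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .lexicon import GeneLexicon, canonicalize

#: Symbol pattern: a letter followed by 1-9 letters/digits/hyphens, maximal.
_SYMBOL = r"[A-Za-z][A-Za-z0-9-]{1,9}"
_TOKEN_RE = re.compile(rf"(?<![A-Za-z0-9-])({_SYMBOL})(?![A-Za-z0-9-])")
#: Markup stripped before tokenization.
_MARKUP_RE = re.compile(r"[*`•]")
#: List numbering / bullets at line starts.
_NUMBERING_RE = re.compile(r"^\s*(?:\d+[.)]\s*|-\s+)", flags=re.MULTILINE)

#: Declination phrases (beyond the literal "not applicable") that mark a
#: refusal; matched case-insensitively as substrings. Configurable because
#: real model refusals are paraphrased in many ways.
DEFAULT_REFUSAL_PATTERNS = (
    "cannot provide",
    "can't provide",
    "i'm unable",
    "i am unable",
    "as an ai",
)


@dataclass(frozen=True)
class ParsedPrediction:
    """Structured view of one raw model response."""

    genes: tuple[str, ...]
    fabricated: tuple[str, ...]
    refusal: bool
    raw_text: str

    @property
    def n_valid_unique(self) -> int:
        return len(self.genes)


def _clean(text: str) -> str:
    return _NUMBERING_RE.sub(" ", _MARKUP_RE.sub("", text))


def extract_candidate_tokens(text: str) -> list[str]:
    """Symbol-shaped tokens in order of appearance, markup/numbering stripped.

    Stop-words and prompt echoes are not filtered here; resolution against
    the lexicon is what separates gene symbols from English words.
    """
    return _TOKEN_RE.findall(_clean(text))


def detect_refusal(
    text: str, patterns: Sequence[str] = DEFAULT_REFUSAL_PATTERNS
) -> bool:
    """True iff the text contains "not applicable" or a declination phrase."""
    lowered = text.lower()
    if "not applicable" in lowered:
        return True
    return any(pattern.lower() in lowered for pattern in patterns)


def _symbol_shaped(token: str) -> bool:
    # Fabricated-token shape: long enough to be a symbol, and either carrying
    # a digit or fully upper-case in the source; filters prose words.
    return len(token) >= 3 and (any(c.isdigit() for c in token) or token.isupper())


def parse_response(
    text: str,
    lexicon: GeneLexicon,
    k: int | None = None,
    refusal_patterns: Sequence[str] = DEFAULT_REFUSAL_PATTERNS,
) -> ParsedPrediction:
    """Parse a raw response into an ordered canonical prediction.

    Tokens are canonicalized in order of appearance; duplicates keep their
    first occurrence. Unresolvable symbol-shaped tokens are recorded as
    fabricated. The gene list is *not* truncated at k here — ranking cutoffs
    belong to the metric layer. A refusal yields an empty prediction.
    """
    if detect_refusal(text, refusal_patterns):
        return ParsedPrediction(genes=(), fabricated=(), refusal=True, raw_text=text)
    genes: list[str] = []
    seen: set[str] = set()
    fabricated: list[str] = []
    fabricated_seen: set[str] = set()
    for token in extract_candidate_tokens(text):
        resolved = canonicalize(token, lexicon)
        if resolved is not None:
            if resolved not in seen:
                seen.add(resolved)
                genes.append(resolved)
        elif _symbol_shaped(token):
            upper = token.upper()
            if upper not in fabricated_seen:
                fabricated_seen.add(upper)
                fabricated.append(upper)
    return ParsedPrediction(
        genes=tuple(genes), fabricated=tuple(fabricated), refusal=False, raw_text=text
    )


def _comma_run_pattern(k: int) -> re.Pattern[str]:
    token = rf"[\"'(\[]?{_SYMBOL}[\"')\]]?"
    return re.compile(rf"(?:{token}[ \t]*,[ \t\n]*){{{max(k - 1, 0)},}}{token}")


def check_structure_compliance(
    text: str,
    k: int,
    refusal_patterns: Sequence[str] = DEFAULT_REFUSAL_PATTERNS,
) -> bool:
    """True iff the response matches the required output dialect.

    The dialect is either a contiguous comma-separated run of at least k
    symbol-shaped tokens (whitespace and markup tolerated, no interleaving
    prose inside the run; surrounding prose is allowed) or a refusal.
    Evaluated independently of task completeness: the tokens need not
    resolve to real genes.
    """
    if detect_refusal(text, refusal_patterns):
        return True
    return _comma_run_pattern(k).search(_clean(text)) is not None
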