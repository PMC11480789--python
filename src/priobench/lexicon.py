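"""Gene-symbol lexicon: canonicalization of free-text tokens to approved symbols.

Model responses name genes in whatever form the model learned: the current
approved symbol, a previous (retired) symbol, an alias, or an invention.
Scoring a prediction therefore requires a resolver from any known symbol form
to one canonical approved symbol, plus a blocklist of known gene-name errors
(date-like symbols such as ``SEPT1`` that spreadsheets and language models
both produce) which must never be credited.

The lexicon file format is the HGNC complete-set TSV dialect: tab-separated
with a header containing at least ``symbol``, ``alias_symbol`` and
``prev_symbol`` columns; multi-valued cells are pipe-delimited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

#: Sentinel target for alias/previous tokens claimed by more than one
#: approved symbol; such tokens never resolve.
AMBIGUOUS = "__AMBIGUOUS__"

_REQUIRED_COLUMNS = ("symbol", "alias_symbol", "prev_symbol")


class LexiconFormatError(ValueError):
    """Raised when a lexicon TSV violates the expected dialect."""


@dataclass(frozen=True)
class GeneLexicon:
    """Resolver from any known symbol form to a canonical approved symbol.

    Attributes
    ----------
    approved:
        Approved symbols (upper-case).
    previous_map:
        Previous symbol -> approved symbol; value is :data:`AMBIGUOUS` when
        multiple approved symbols claim the same previous symbol.
    alias_map:
        Alias symbol -> approved symbol, with the same ambiguity convention.
    error_symbols:
        Tokens blocked before any resolution is attempted.
    version_tag:
        Free-text provenance string for reports.
    """

    approved: frozenset[str]
    previous_map: dict[str, str] = field(default_factory=dict)
    alias_map: dict[str, str] = field(default_factory=dict)
    error_symbols: frozenset[str] = frozenset()
    version_tag: str = ""

    def __len__(self) -> int:
        return len(self.approved)

    def __contains__(self, token: str) -> bool:
        return canonicalize(token, self) is not None


def _split_multi(cell: str) -> list[str]:
    return [part.strip().upper() for part in cell.split("|") if part.strip()]


def load_error_symbols(path: str | Path | None = None) -> frozenset[str]:
    """Read an error-symbol list (one token per line, ``#`` comments).

    With ``path=None`` the packaged default list is used, covering the
    SEPT/MARCH/MARC/MAR/DEC families of spreadsheet-style errors.
    """
    if path is None:
        text = (
            resources.files("priobench.resources")
            .joinpath("gene_name_errors.txt")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    symbols = set()
    for line in text.splitlines():
        token = line.split("#", 1)[0].strip().upper()
        if token:
            symbols.add(token)
    return frozenset(symbols)


def load_lexicon(
    path: str | Path,
    error_list_path: str | Path | None = None,
    version_tag: str = "",
) -> GeneLexicon:
    """Load a gene-symbol lexicon from an HGNC complete-set style TSV.

    Parameters
    ----------
    path:
        Tab-separated file with header columns ``symbol``, ``alias_symbol``,
        ``prev_symbol`` (pipe-delimited multi-values; optional ``status``).
    error_list_path:
        Optional override for the packaged gene-name-error blocklist.

    Raises
    ------
    LexiconFormatError
        If a required column is missing or an approved symbol is duplicated.
    OSError
        If the file cannot be read.
    """
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in _REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise LexiconFormatError(
                f"lexicon file {path!s} is missing required column {column!r}"
            )

    approved: set[str] = set()
    rows: list[tuple[str, str, str]] = []
    for line_no, row in enumerate(frame.itertuples(index=False), start=2):
        symbol = str(getattr(row, "symbol")).strip().upper()
        if not symbol:
            logger.warning("lexicon %s line %d: empty symbol, row skipped", path, line_no)
            continue
        if symbol in approved:
            raise LexiconFormatError(
                f"duplicate approved symbol {symbol!r} at line {line_no}"
            )
        approved.add(symbol)
        rows.append((symbol, getattr(row, "prev_symbol"), getattr(row, "alias_symbol")))

    previous_map: dict[str, str] = {}
    alias_map: dict[str, str] = {}
    for symbol, prev_cell, alias_cell in rows:
        for token in _split_multi(str(prev_cell)):
            _insert(previous_map, token, symbol)
        for token in _split_multi(str(alias_cell)):
            _insert(alias_map, token, symbol)

    return GeneLexicon(
        approved=frozenset(approved),
        previous_map=previous_map,
        alias_map=alias_map,
        error_symbols=load_error_symbols(error_list_path),
        version_tag=version_tag or str(path),
    )


def _insert(mapping: dict[str, str], token: str, symbol: str) -> None:
    current = mapping.get(token)
    if current is None:
        mapping[token] = symbol
    elif current != symbol:
        # One token claimed by several approved symbols: never resolve it.
        mapping[token] = AMBIGUOUS


def canonicalize(token: str, lexicon: GeneLexicon) -> str | None:
    """Resolve a token to its approved symbol, or ``None``.

    Matching is case-insensitive (upper-cased). The blocklist dominates:
    a token on the error list never resolves, regardless of lexicon content.
    Otherwise resolution precedence is approved > previous > alias, and a
    previous/alias token claimed by more than one approved symbol resolves
    to ``None`` (an ambiguous match is never credited).
    """
    if not token:
        return None
    upper = token.strip().upper()
    if not upper or upper in lexicon.error_symbols:
        return None
    if upper in lexicon.approved:
        return upper
    for mapping in (lexicon.previous_map, lexicon.alias_map):
        target = mapping.get(upper)
        if target is not None:
            return None if target == AMBIGUOUS else target
    return None
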