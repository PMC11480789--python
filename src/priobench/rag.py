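"""Retrieval-augmented generation support built on HPO annotations.

Two document corpora can be built from a gene-phenotype annotation table:

* **G2P** (gene-to-phenotype): one document per gene, reading
  "The phenotypes associated with gene <g> include <p1, p2, ...>.";
* **P2G** (phenotype-to-gene): one document per phenotype, listing the
  genes annotated to it.

Documents are embedded by a pluggable embedder (any callable object with
``embedder_id``/``dim`` attributes mapping a string to a fixed-dimension
vector, deterministically). The shipped default is a hashed bag-of-words
embedder, which is deterministic and offline; adapters for service
embeddings implement the same contract. Retrieval ranks documents by cosine
similarity with a lexicographic doc_id tie-break, and the retrieved context
is prefixed to the base prompt.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Protocol, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Direction = Literal["G2P", "P2G"]

G2P_TEMPLATE = "The phenotypes associated with gene {gene} include {phenotypes}."
P2G_TEMPLATE = "The genes associated with phenotype {phenotype} include {genes}."

_GENE_COLUMNS = ("gene_symbol", "gene-symbol", "entrez-gene-symbol")
_HPO_ID_COLUMNS = ("hpo_id", "hpo-term-id")
_HPO_NAME_COLUMNS = ("hpo_name", "hpo-term-name")


class AnnotationFormatError(ValueError):
    """Raised when the annotation TSV lacks the expected columns."""


class EmbedderContractError(ValueError):
    """Raised when an embedder violates its declared contract."""


class Embedder(Protocol):
    embedder_id: str
    dim: int

    def __call__(self, text: str) -> np.ndarray: ...


class HashedBowEmbedder:
    """Deterministic hashed bag-of-words embedding.

    Lower-cased word tokens are hashed (md5, stable across processes) into
    ``dim`` buckets and counted. Not a semantic embedding — it supports
    reproducible lexical retrieval for testing and offline pipelines.
    """

    def __init__(self, dim: int = 256):
        self.dim = dim
        self.embedder_id = f"hashed-bow-{dim}"

    def __call__(self, text: str) -> np.ndarray:
        vector = np.zeros(self.dim, dtype=np.float64)
        for word in re.findall(r"[a-z0-9]+", text.lower()):
            digest = hashlib.md5(word.encode("utf-8")).digest()
            vector[int.from_bytes(digest[:8], "big") % self.dim] += 1.0
        return vector


@dataclass(frozen=True)
class RagDocument:
    doc_id: str
    direction: Direction
    subject: str  # gene symbol (G2P) or phenotype label (P2G)
    text: str


@dataclass(frozen=True)
class RagIndex:
    documents: tuple[RagDocument, ...]
    vectors: np.ndarray  # shape (n_documents, dim)
    embedder_id: str
    dim: int


def load_annotations(path: str | Path) -> list[tuple[str, str]]:
    """Read (gene symbol, phenotype name) pairs from an annotation TSV.

    Accepts the ``genes_to_phenotype.txt`` dialect: tab-separated, header
    row naming at least a gene-symbol column, an HPO id column and an HPO
    name column; leading "#" comment lines are skipped (a "#"-prefixed
    header row is also accepted). Pairs are deduplicated, keeping first-
    occurrence order.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header_row = None
    data_start = 0
    for i, line in enumerate(lines):
        stripped = line.lstrip("#").strip()
        if not stripped:
            continue
        columns = [c.strip().lower() for c in stripped.split("\t")]
        if any(c in _GENE_COLUMNS for c in columns):
            header_row, data_start = columns, i + 1
            break
        if not line.startswith("#"):
            break
    if header_row is None:
        raise AnnotationFormatError(
            f"annotation file {path!s} has no header naming a gene-symbol column"
        )

    def _find(candidates: tuple[str, ...], kind: str) -> int:
        for name in candidates:
            if name in header_row:
                return header_row.index(name)
        raise AnnotationFormatError(
            f"annotation file {path!s} is missing a {kind} column "
            f"(expected one of {candidates})"
        )

    gene_col = _find(_GENE_COLUMNS, "gene symbol")
    _find(_HPO_ID_COLUMNS, "HPO id")
    name_col = _find(_HPO_NAME_COLUMNS, "HPO name")

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for line_no, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) <= max(gene_col, name_col):
            raise AnnotationFormatError(f"{path}:{line_no}: too few columns")
        pair = (fields[gene_col].strip(), fields[name_col].strip())
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return pairs


def build_index(
    pairs: Sequence[tuple[str, str]], direction: Direction, embedder: Embedder
) -> RagIndex:
    """One document per gene (G2P) or per phenotype (P2G), all embedded.

    Phenotype/gene lists are comma-joined in annotation-file order (a
    literal template fill, not sorted).
    """
    if not pairs:
        raise ValueError("no annotation pairs to index")
    grouped: dict[str, list[str]] = {}
    for gene, phenotype in pairs:
        if direction == "G2P":
            grouped.setdefault(gene, []).append(phenotype)
        else:
            grouped.setdefault(phenotype, []).append(gene)
    documents = []
    for subject, items in grouped.items():
        joined = ", ".join(items)
        if direction == "G2P":
            text = G2P_TEMPLATE.format(gene=subject, phenotypes=joined)
        else:
            text = P2G_TEMPLATE.format(phenotype=subject, genes=joined)
        documents.append(
            RagDocument(
                doc_id=f"{direction}:{subject}", direction=direction,
                subject=subject, text=text,
            )
        )
    vectors = np.empty((len(documents), embedder.dim), dtype=np.float64)
    for i, doc in enumerate(documents):
        vector = np.asarray(embedder(doc.text), dtype=np.float64)
        if vector.shape != (embedder.dim,):
            raise EmbedderContractError(
                f"embedder {embedder.embedder_id!r} returned shape {vector.shape}, "
                f"declared dim {embedder.dim}"
            )
        if not np.all(np.isfinite(vector)):
            raise EmbedderContractError("embedder returned non-finite values")
        vectors[i] = vector
    return RagIndex(
        documents=tuple(documents), vectors=vectors,
        embedder_id=embedder.embedder_id, dim=embedder.dim,
    )


def retrieve(
    query: str, index: RagIndex, top_k: int = 10, embedder: Embedder | None = None
) -> list[RagDocument]:
    """Top-k documents by cosine similarity, ties broken by doc_id."""
    if embedder is None:
        raise EmbedderContractError("an embedder is required for retrieval")
    if embedder.embedder_id != index.embedder_id:
        raise EmbedderContractError(
            f"embedder {embedder.embedder_id!r} does not match index "
            f"{index.embedder_id!r}"
        )
    q = np.asarray(embedder(query), dtype=np.float64)
    if q.shape != (index.dim,):
        raise EmbedderContractError("query embedding has wrong dimension")
    norms = np.linalg.norm(index.vectors, axis=1) * (np.linalg.norm(q) or 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(norms > 0, index.vectors @ q / np.where(norms > 0, norms, 1.0), 0.0)
    order = sorted(
        range(len(index.documents)),
        key=lambda i: (-sims[i], index.documents[i].doc_id),
    )
    return [index.documents[i] for i in order[: min(top_k, len(order))]]


def augment_prompt(base_prompt: str, docs: Sequence[RagDocument]) -> str:
    """Prefix the base prompt with a delimited context block, in rank order."""
    if not docs:
        logger.warning("augment_prompt called with no documents; prompt unchanged")
        return base_prompt
    context = "\n".join(f"- {doc.text}" for doc in docs)
    return f"Context:\n{context}\n\n{base_prompt}"


def save_index(index: RagIndex, path: str | Path) -> None:
    """Persist an index as JSON (documents + vectors + embedder stamp)."""
    payload = {
        "embedder_id": index.embedder_id,
        "dim": index.dim,
        "documents": [
            {"doc_id": d.doc_id, "direction": d.direction,
             "subject": d.subject, "text": d.text}
            for d in index.documents
        ],
        "vectors": index.vectors.tolist(),
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_index(path: str | Path) -> RagIndex:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    documents = tuple(
        RagDocument(
            doc_id=d["doc_id"], direction=d["direction"],
            subject=d["subject"], text=d["text"],
        )
        for d in payload["documents"]
    )
    return RagIndex(
        documents=documents,
        vectors=np.asarray(payload["vectors"], dtype=np.float64),
        embedder_id=payload["embedder_id"],
        dim=int(payload["dim"]),
    )
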