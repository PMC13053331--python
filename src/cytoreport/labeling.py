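"""Sentence segmentation and embedding nearest-neighbor section labeling.

Report sentences are assigned to the QLP, PBMC, BSP, or interpretation
section by comparing their embeddings against a manually (here:
renderer-) labeled reference set under cosine similarity.  The default
embedding backend is a deterministic lexical hashing vectorizer — token
counts hashed into a fixed-dimension vector and L2-normalized — so the
whole pipeline runs offline; an API-based semantic embedder can be
plugged in behind the same interface.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ConfigError, UsageError
from .reporting import SectionLabel

#: Tie-break precedence for k-NN voting.
LABEL_ORDER = [SectionLabel.QLP, SectionLabel.PBMC, SectionLabel.BSP, SectionLabel.INTERP]

_ABBREVIATIONS = {
    "e.g", "i.e", "vs", "dr", "mr", "ms", "mrs", "fig", "figs", "no", "approx",
    "al", "etc", "cf", "resp",
}

_TERMINATOR = re.compile(r"([.!?])(\s+)(?=[A-Z0-9\"'(])")


def split_sentences(text: str) -> list[str]:
    """Abbreviation-safe sentence splitting on terminal punctuation.

    Splits after ``.!?`` followed by whitespace and an upper-case or
    numeric continuation, unless the token before the period is a known
    abbreviation.  The concatenation of the returned sentences preserves
    every non-whitespace character of the input.
    """
    text = text.strip()
    if not text:
        return []
    cut_points = []
    for m in _TERMINATOR.finditer(text):
        head = text[: m.start()]
        last_token = re.split(r"[\s(]+", head)[-1].rstrip(".").casefold()
        if last_token in _ABBREVIATIONS:
            continue
        cut_points.append(m.end(1))
    sentences = []
    prev = 0
    for cp in cut_points:
        chunk = text[prev:cp].strip()
        if chunk:
            sentences.append(chunk)
        prev = cp
    tail = text[prev:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# -- embedding backends -----------------------------------------------------


class HashingEmbedder:
    """Deterministic lexical embedding: token frequencies hashed into a
    fixed-dimension vector (CRC32, stable across platforms and runs),
    L2-normalized."""

    def __init__(self, dim: int = 256):
        if dim <= 0:
            raise ConfigError("embedding dimension must be positive")
        self.dim = dim

    def embed(self, sentences: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(sentences), self.dim), dtype=float)
        for i, sentence in enumerate(sentences):
            for token in re.findall(r"\w+", sentence.casefold()):
                out[i, zlib.crc32(token.encode()) % self.dim] += 1.0
            norm = np.linalg.norm(out[i])
            if norm > 0:
                out[i] /= norm
        return out


#: Any object with ``embed(list[str]) -> (n, d) array`` satisfies the contract.
EmbeddingBackend = HashingEmbedder


def embed(sentences: Sequence[str], backend: Optional[EmbeddingBackend] = None) -> np.ndarray:
    """Embed sentences with the given backend (default: lexical hashing).

    Backend failures are re-raised with the index of the offending
    sentence, since API-based adapters may fail per item.
    """
    backend = backend or HashingEmbedder()
    try:
        return np.asarray(backend.embed(list(sentences)), dtype=float)
    except Exception as exc:  # noqa: BLE001 -- annotate and propagate
        for i, s in enumerate(sentences):
            try:
                backend.embed([s])
            except Exception:
                raise type(exc)(f"embedding failed at sentence {i}: {exc}") from exc
        raise


@dataclass
class LabeledSentence:
    text: str
    label: SectionLabel
    vector: np.ndarray


@dataclass
class ReferenceSet:
    sentences: list[LabeledSentence]

    @property
    def matrix(self) -> np.ndarray:
        return np.vstack([s.vector for s in self.sentences])

    def __len__(self) -> int:
        return len(self.sentences)


def build_reference(
    labeled: Sequence[tuple[str, SectionLabel]],
    backend: Optional[EmbeddingBackend] = None,
) -> ReferenceSet:
    if not labeled:
        raise ConfigError("reference set must be non-empty")
    vectors = embed([t for t, _ in labeled], backend)
    return ReferenceSet(
        [LabeledSentence(t, SectionLabel(l), v) for (t, l), v in zip(labeled, vectors)]
    )


def _cosine(matrix: np.ndarray, vector: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1) * (np.linalg.norm(vector) or 1.0)
    norms[norms == 0] = 1.0
    return matrix @ vector / norms


def label_sentence(
    sentence: str,
    reference: ReferenceSet,
    k: int = 5,
    backend: Optional[EmbeddingBackend] = None,
) -> tuple[SectionLabel, float]:
    """Label one sentence by majority vote of its k nearest reference
    sentences under cosine similarity.

    Returns (label, margin) where margin is the winning class's mean
    similarity minus the runner-up class's (the winner's mean similarity
    itself when only one class appears among the neighbors).  Ties break
    by larger summed similarity, then by section order QLP < PBMC < BSP
    < INTERP.  Neighbor selection is deterministic: equal similarities
    resolve by reference index.
    """
    if len(reference) == 0:
        raise ConfigError("reference set is empty")
    if not 1 <= k <= len(reference):
        raise UsageError(f"k={k} outside [1, {len(reference)}]")
    vector = embed([sentence], backend)[0]
    sims = _cosine(reference.matrix, vector)
    order = sorted(range(len(sims)), key=lambda i: (-sims[i], i))[:k]
    by_label: dict[SectionLabel, list[float]] = {}
    for i in order:
        by_label.setdefault(reference.sentences[i].label, []).append(float(sims[i]))
    ranked = sorted(
        by_label.items(),
        key=lambda kv: (-len(kv[1]), -sum(kv[1]), LABEL_ORDER.index(kv[0])),
    )
    winner, winner_sims = ranked[0]
    if len(ranked) > 1:
        margin = float(np.mean(winner_sims) - np.mean(ranked[1][1]))
    else:
        margin = float(np.mean(winner_sims))
    return winner, margin


def label_report_sentences(
    text: str,
    reference: ReferenceSet,
    k: int = 5,
    backend: Optional[EmbeddingBackend] = None,
) -> list[tuple[str, SectionLabel, float]]:
    """Split a report text into sentences and label each one."""
    return [
        (s, *label_sentence(s, reference, k=k, backend=backend))
        for s in split_sentences(text)
    ]
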