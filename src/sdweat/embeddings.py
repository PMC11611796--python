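"""Embedding stores: term→vector resolution and vector-file I/O.

An :class:`EmbeddingStore` is the package's canonical container for word
vectors: a mapping from term to a fixed-dimension real vector, with
vocabulary enumeration.  Anything that can produce such a mapping (a static
vector file, a contextual encoder queried without context) can be wrapped
into a store; the WEAT statistics only ever see the store interface.

Two standard text formats are supported:

* ``glove-text`` — one ``term v1 ... vd`` line per entry, no header;
* ``word2vec-text`` — the same body preceded by a ``count dim`` header line.

Gzip-compressed variants (``.gz``) are accepted transparently.
"""

from __future__ import annotations

import gzip
import io
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np

from .errors import DuplicateTermWarning, TermLookupError, VectorFormatError

__all__ = [
    "EmbeddingStore",
    "ResolutionReport",
    "read_word_vectors",
    "write_word_vectors",
    "resolve_terms",
    "sample_vocabulary",
]

OovPolicy = Literal["error", "skip", "lowercase_fallback"]

_TOKEN_SPLIT = re.compile(r"[\s\-]+")


class EmbeddingStore:
    """A term → fixed-dimension vector mapping with vocabulary enumeration.

    Vectors are validated on insertion: every component must be finite and
    the all-zeros vector is rejected (it has no direction, so cosine
    similarity to it is undefined).
    """

    def __init__(
        self,
        entries: Mapping[str, Sequence[float]] | Iterable[tuple[str, Sequence[float]]] = (),
        source_label: str = "",
    ) -> None:
        self._entries: dict[str, np.ndarray] = {}
        self._dimension: int | None = None
        self.source_label = source_label
        items = entries.items() if isinstance(entries, Mapping) else entries
        for term, vec in items:
            self.add(term, vec)

    @property
    def dimension(self) -> int:
        if self._dimension is None:
            raise ValueError("empty store has no dimension")
        return self._dimension

    def add(self, term: str, vector: Sequence[float]) -> None:
        vec = np.asarray(vector, dtype=np.float64)
        if vec.ndim != 1:
            raise ValueError(f"vector for {term!r} is not one-dimensional")
        if self._dimension is None:
            if vec.size == 0:
                raise ValueError(f"vector for {term!r} is empty")
            self._dimension = int(vec.size)
        elif vec.size != self._dimension:
            raise ValueError(
                f"vector for {term!r} has length {vec.size}, expected {self._dimension}"
            )
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"vector for {term!r} has non-finite components")
        if not np.any(vec):
            raise ValueError(f"vector for {term!r} is the all-zeros vector")
        self._entries[term] = vec

    def __contains__(self, term: str) -> bool:
        return term in self._entries

    def __getitem__(self, term: str) -> np.ndarray:
        return self._entries[term]

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def vocabulary(self) -> list[str]:
        """Terms in insertion order (file order for loaded stores)."""
        return list(self._entries)

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self._entries.items())

    def matrix(self, terms: Sequence[str]) -> np.ndarray:
        """Stack the vectors of ``terms`` into an ``(n, dimension)`` array."""
        missing = [t for t in terms if t not in self._entries]
        if missing:
            raise TermLookupError(f"terms not in store: {missing}")
        return np.stack([self._entries[t] for t in terms])

    def __repr__(self) -> str:
        dim = self._dimension if self._dimension is not None else "?"
        label = f", source={self.source_label!r}" if self.source_label else ""
        return f"EmbeddingStore({len(self)} terms, dim={dim}{label})"


@dataclass(frozen=True)
class ResolutionReport:
    """Bookkeeping for one term-resolution pass.

    ``resolved`` holds ``(term, kind)`` pairs where kind is one of
    ``exact``, ``lowercased`` or ``multi-token-mean``; ``missing`` lists the
    terms that could not be resolved.  Together they partition the request.
    """

    resolved: tuple[tuple[str, str], ...]
    missing: tuple[str, ...]

    @property
    def n_resolved(self) -> int:
        return len(self.resolved)

    @property
    def n_missing(self) -> int:
        return len(self.missing)

    @property
    def resolved_terms(self) -> list[str]:
        return [t for t, _ in self.resolved]


def _open_text(path: Path) -> io.TextIOBase:
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def _sniff_format(first_line: str) -> str:
    parts = first_line.split()
    if len(parts) == 2:
        try:
            int(parts[0]), int(parts[1])
            return "word2vec-text"
        except ValueError:
            pass
    return "glove-text"


def read_word_vectors(
    path: str | Path,
    format: Literal["auto", "glove-text", "word2vec-text"] = "auto",
    source_label: str | None = None,
) -> EmbeddingStore:
    """Read a whitespace-delimited word-vector text file into a store.

    Duplicate terms keep their first occurrence (later ones raise a
    :class:`DuplicateTermWarning`); inconsistent dimensions and zero
    vectors are format errors that name the offending line.
    """
    path = Path(path)
    store = EmbeddingStore(source_label=source_label or path.name)
    dim: int | None = None
    duplicates: list[str] = []
    with _open_text(path) as fh:
        first = fh.readline()
        if not first:
            raise VectorFormatError(f"{path}: empty file")
        fmt = _sniff_format(first) if format == "auto" else format
        lines: Iterable[tuple[int, str]]
        if fmt == "word2vec-text":
            header = first.split()
            if len(header) != 2:
                raise VectorFormatError(
                    f"{path}:1: word2vec-text header must be 'count dim'"
                )
            try:
                dim = int(header[1])
            except ValueError as exc:
                raise VectorFormatError(f"{path}:1: malformed header {first!r}") from exc
            lines = enumerate(fh, start=2)
        else:
            lines = enumerate([first] + list(fh), start=1)
        for lineno, line in lines:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            term, fields = parts[0], [p for p in parts[1:] if p]
            try:
                vec = np.array(fields, dtype=np.float64)
            except ValueError as exc:
                raise VectorFormatError(
                    f"{path}:{lineno}: non-numeric vector component"
                ) from exc
            if dim is None:
                dim = vec.size
            if vec.size != dim:
                raise VectorFormatError(
                    f"{path}:{lineno}: vector for {term!r} has {vec.size} "
                    f"components, expected {dim}"
                )
            if term in store:
                duplicates.append(term)
                continue
            try:
                store.add(term, vec)
            except ValueError as exc:
                raise VectorFormatError(f"{path}:{lineno}: {exc}") from exc
    if duplicates:
        warnings.warn(
            f"{path}: {len(duplicates)} duplicate terms kept first occurrence "
            f"(e.g. {duplicates[:5]})",
            DuplicateTermWarning,
            stacklevel=2,
        )
    if len(store) == 0:
        raise VectorFormatError(f"{path}: no vector entries")
    return store


def write_word_vectors(
    store: EmbeddingStore,
    path: str | Path,
    format: Literal["glove-text", "word2vec-text"] = "glove-text",
    precision: int = 8,
) -> None:
    """Write a store back out in a standard text format (round-trips to
    the printed precision, preserving term order)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", encoding="utf-8") as fh:
        if format == "word2vec-text":
            fh.write(f"{len(store)} {store.dimension}\n")
        for term, vec in store.items():
            comps = " ".join(f"{v:.{precision}g}" for v in vec)
            fh.write(f"{term} {comps}\n")


def _resolve_token(store: EmbeddingStore, token: str, policy: OovPolicy):
    """Resolve one whitespace-free token; returns (vector, kind) or None."""
    if token in store:
        return store[token], "exact"
    if policy == "lowercase_fallback" and token.lower() in store:
        return store[token.lower()], "lowercased"
    return None


def resolve_terms(
    store: EmbeddingStore,
    terms: Sequence[str],
    oov_policy: OovPolicy = "error",
) -> tuple[np.ndarray, ResolutionReport]:
    """Resolve benchmark terms against a store under an out-of-vocabulary policy.

    Multi-word terms (containing spaces or hyphens) resolve to the
    arithmetic mean of their constituent token vectors.  Policies:
    ``error`` aborts on any miss, ``skip`` drops and reports misses,
    ``lowercase_fallback`` tries the lowercased token before dropping.
    """
    if not terms:
        raise TermLookupError("no terms requested")
    vectors: list[np.ndarray] = []
    resolved: list[tuple[str, str]] = []
    missing: list[str] = []
    for term in terms:
        tokens = [t for t in _TOKEN_SPLIT.split(term) if t]
        hits = [_resolve_token(store, tok, oov_policy) for tok in tokens]
        if not hits or any(h is None for h in hits):
            missing.append(term)
            continue
        if len(hits) == 1:
            vec, kind = hits[0]
        else:
            vec = np.mean([h[0] for h in hits], axis=0)
            kind = "multi-token-mean"
            if not np.any(vec):
                missing.append(term)  # token vectors cancelled exactly
                continue
        vectors.append(np.asarray(vec, dtype=np.float64))
        resolved.append((term, kind))
    report = ResolutionReport(resolved=tuple(resolved), missing=tuple(missing))
    if missing and oov_policy == "error":
        raise TermLookupError(f"terms missing from store: {missing}")
    if not resolved:
        raise TermLookupError(f"no requested terms could be resolved: {list(terms)}")
    return np.stack(vectors), report


def default_vocabulary_filter(term: str) -> bool:
    """Keep purely alphabetic terms of length ≥ 2 (drops punctuation,
    numbers and single letters from negative-control pools)."""
    return len(term) >= 2 and term.isalpha()


def sample_vocabulary(
    store: EmbeddingStore,
    n: int,
    seed: int | np.random.Generator | None = None,
    term_filter: Callable[[str], bool] | None = default_vocabulary_filter,
    max_pool: int | None = 50_000,
) -> list[str]:
    """Draw ``n`` distinct terms uniformly without replacement from the
    filtered vocabulary.

    The candidate pool is the first ``max_pool`` vocabulary entries passing
    ``term_filter`` — file order proxies frequency rank in standard vector
    releases, so this approximates "the most frequent general words".
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pool: list[str] = []
    for term in store:
        if term_filter is None or term_filter(term):
            pool.append(term)
            if max_pool is not None and len(pool) >= max_pool:
                break
    if n > len(pool):
        raise ValueError(
            f"cannot sample {n} terms: filtered vocabulary pool has only "
            f"{len(pool)} entries"
        )
    idx = rng.permutation(len(pool))[:n]
    return [pool[i] for i in idx]
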