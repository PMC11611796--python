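"""Bias benchmarks: two target term sets and two attribute term sets.

A :class:`BiasBenchmark` is the unit of one word-embedding association test
(WEAT): target sets ``X`` and ``Y`` (the concepts being tested for bias,
e.g. flowers vs. insects) and attribute sets ``A`` and ``B`` (the poles they
may associate with, e.g. pleasant vs. unpleasant terms).  The ten classic
WEAT benchmarks are bundled as fixture data and available through
:func:`load_bundled_benchmarks`.

File format
-----------
One JSON document per file: either a bare array of benchmark records, or an
object with a ``benchmarks`` array plus free-form header metadata (used to
document fixture provenance).  Each record has keys ``id``, ``description``,
``targets`` (``{"X": {"label", "terms"}, "Y": ...}``) and ``attributes``
(``{"A": ..., "B": ...}``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import BenchmarkParseError, BenchmarkValidationError

__all__ = [
    "TermSet",
    "BiasBenchmark",
    "load_benchmarks",
    "dump_benchmarks",
    "load_bundled_benchmarks",
    "describe_benchmark",
]

_BUNDLED_RESOURCE = "weat_benchmarks.json"


@dataclass(frozen=True)
class TermSet:
    """An ordered, duplicate-free list of terms under a short label."""

    label: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if not self.terms:
            raise BenchmarkValidationError(f"term set {self.label!r} is empty")
        if any(not t or not t.strip() for t in self.terms):
            raise BenchmarkValidationError(
                f"term set {self.label!r} contains a blank or whitespace-only term"
            )
        if len(set(self.terms)) != len(self.terms):
            dupes = sorted({t for t in self.terms if self.terms.count(t) > 1})
            raise BenchmarkValidationError(
                f"term set {self.label!r} contains duplicate terms: {dupes}"
            )

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


@dataclass(frozen=True)
class BiasBenchmark:
    """Two target term sets and two attribute term sets with an identifier.

    Invariants enforced at construction: the two target sets are disjoint
    and the two attribute sets are disjoint (term comparison is exact and
    case-sensitive; case handling at vector-lookup time belongs to the
    embeddings layer).  Unequal target-set sizes are legal but flagged via
    :attr:`balanced`, since the exact partition p-value presumes
    ``|X| = |Y|``.
    """

    id: str
    description: str
    target_x: TermSet
    target_y: TermSet
    attribute_a: TermSet
    attribute_b: TermSet

    def __post_init__(self) -> None:
        overlap = set(self.target_x.terms) & set(self.target_y.terms)
        if overlap:
            raise BenchmarkValidationError(
                f"benchmark {self.id!r}: target sets share terms {sorted(overlap)}"
            )
        overlap = set(self.attribute_a.terms) & set(self.attribute_b.terms)
        if overlap:
            raise BenchmarkValidationError(
                f"benchmark {self.id!r}: attribute sets share terms {sorted(overlap)}"
            )

    @property
    def balanced(self) -> bool:
        """Whether ``|X| = |Y|`` (required for the exact partition p-value)."""
        return len(self.target_x) == len(self.target_y)

    def to_record(self) -> dict:
        def _ts(ts: TermSet) -> dict:
            return {"label": ts.label, "terms": list(ts.terms)}

        return {
            "id": self.id,
            "description": self.description,
            "targets": {"X": _ts(self.target_x), "Y": _ts(self.target_y)},
            "attributes": {"A": _ts(self.attribute_a), "B": _ts(self.attribute_b)},
        }


def _term_set_from_record(record: Mapping, bench_id: str, path: str) -> TermSet:
    try:
        label = record["label"]
        terms = record["terms"]
    except (KeyError, TypeError) as exc:
        raise BenchmarkParseError(
            f"benchmark {bench_id!r}: term set missing field {exc} (at {path})"
        ) from exc
    if not isinstance(terms, list) or not all(isinstance(t, str) for t in terms):
        raise BenchmarkParseError(
            f"benchmark {bench_id!r}: field {path}.terms must be a list of strings"
        )
    return TermSet(label=str(label), terms=tuple(terms))


def _benchmark_from_record(record: Mapping, index: int) -> BiasBenchmark:
    if not isinstance(record, Mapping):
        raise BenchmarkParseError(f"record {index}: expected a JSON object")
    bench_id = record.get("id")
    if not bench_id:
        raise BenchmarkParseError(f"record {index}: missing field 'id'")
    for key in ("targets", "attributes"):
        if key not in record or not isinstance(record[key], Mapping):
            raise BenchmarkParseError(
                f"benchmark {bench_id!r}: missing or malformed field {key!r}"
            )
    targets, attributes = record["targets"], record["attributes"]
    for side, grp in (("X", targets), ("Y", targets), ("A", attributes), ("B", attributes)):
        if side not in grp:
            raise BenchmarkParseError(f"benchmark {bench_id!r}: missing term set {side!r}")
    return BiasBenchmark(
        id=str(bench_id),
        description=str(record.get("description", "")),
        target_x=_term_set_from_record(targets["X"], bench_id, "targets.X"),
        target_y=_term_set_from_record(targets["Y"], bench_id, "targets.Y"),
        attribute_a=_term_set_from_record(attributes["A"], bench_id, "attributes.A"),
        attribute_b=_term_set_from_record(attributes["B"], bench_id, "attributes.B"),
    )


def _parse_document(doc) -> list[BiasBenchmark]:
    if isinstance(doc, Mapping):
        records = doc.get("benchmarks")
        if not isinstance(records, list):
            raise BenchmarkParseError(
                "top-level object has no 'benchmarks' array"
            )
    elif isinstance(doc, list):
        records = doc
    else:
        raise BenchmarkParseError("document must be an array or an object")
    return [_benchmark_from_record(rec, i) for i, rec in enumerate(records)]


def load_benchmarks(path: str | Path) -> list[BiasBenchmark]:
    """Load and validate benchmarks from a JSON file, preserving order."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise BenchmarkParseError(f"{path}: not valid JSON: {exc}") from exc
    return _parse_document(doc)


def dump_benchmarks(
    benchmarks: Iterable[BiasBenchmark],
    path: str | Path,
    header: Mapping | None = None,
) -> None:
    """Serialize benchmarks to the JSON file format (load/dump round-trips)."""
    records = [b.to_record() for b in benchmarks]
    doc: dict | list
    if header:
        doc = dict(header)
        doc["benchmarks"] = records
    else:
        doc = records
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_bundled_benchmarks() -> list[BiasBenchmark]:
    """The ten classic WEAT benchmarks (ids ``WEAT-1`` ... ``WEAT-10``)."""
    ref = resources.files("sdweat") / "data" / _BUNDLED_RESOURCE
    doc = json.loads(ref.read_text(encoding="utf-8"))
    return _parse_document(doc)


@dataclass(frozen=True)
class BenchmarkSummary:
    id: str
    n_target_x: int
    n_target_y: int
    n_attribute_a: int
    n_attribute_b: int
    n_attributes_pooled: int


def describe_benchmark(b: BiasBenchmark) -> BenchmarkSummary:
    """Set sizes and pooled attribute count for one benchmark."""
    pooled = dict.fromkeys(list(b.attribute_a) + list(b.attribute_b))
    return BenchmarkSummary(
        id=b.id,
        n_target_x=len(b.target_x),
        n_target_y=len(b.target_y),
        n_attribute_a=len(b.attribute_a),
        n_attribute_b=len(b.attribute_b),
        n_attributes_pooled=len(pooled),
    )
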