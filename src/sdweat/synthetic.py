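"""Synthetic embeddings with a planted bias direction.

The generator emulates the geometry that makes a WEAT fire on real vectors:
all terms of a benchmark are placed on the unit sphere, and the four term
sets load on a shared latent "bias axis" ``u`` with signed strength
``±β`` plus isotropic Gaussian noise.  With the default pole assignment
(X and A on the ``+1`` pole, Y and B on ``−1``), the effect size grows
monotonically from 0 (at ``β = 0``, where all groups are exchangeable)
towards its maximum of 2 as ``β / noise_scale → ∞``.

Filler terms — pure-noise vectors with purely alphabetic names — pad the
vocabulary so that negative-control sampling has a general word pool to
draw from, just as a real vector file does.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .benchmarks import BiasBenchmark
from .embeddings import EmbeddingStore

__all__ = [
    "SyntheticConfig",
    "generate_synthetic_embeddings",
    "generate_replicate_stores",
    "filler_terms",
]

DEFAULT_POLES: Mapping[str, float] = {"X": 1.0, "Y": -1.0, "A": 1.0, "B": -1.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-bias generator.

    dimension
        Embedding dimension (default 50: large enough that random cosines
        concentrate near 0, small enough to be fast).
    bias_strength
        β ≥ 0, the loading of each poled group on the shared bias axis.
        β = 0 is the exchangeable null model.
    noise_scale
        Per-component scale of the isotropic Gaussian noise.  Only the
        ratio β/noise_scale matters for cosine statistics, since every
        vector is normalized to unit length.
    seed
        RNG seed; identical (config, benchmark) → byte-identical store.
    poles
        Pole per benchmark role, keyed "X", "Y", "A", "B"; +1/−1 place a
        group at opposite ends of the bias axis, 0 makes it pure noise.
    """

    dimension: int = 50
    bias_strength: float = 1.0
    noise_scale: float = 1.0
    seed: int = 0
    poles: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_POLES))

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be positive")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be non-negative")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        unknown = set(self.poles) - {"X", "Y", "A", "B"}
        if unknown:
            raise ValueError(f"unknown pole roles: {sorted(unknown)}")


def filler_terms(n: int, prefix: str = "fill") -> list[str]:
    """``n`` distinct, purely alphabetic filler names (pass the default
    negative-control vocabulary filter)."""
    letters = string.ascii_lowercase
    names = []
    for i in range(n):
        suffix, j = "", i
        for _ in range(4):
            suffix = letters[j % 26] + suffix
            j //= 26
        names.append(prefix + suffix)
    return names


def generate_synthetic_embeddings(
    cfg: SyntheticConfig,
    benchmark: BiasBenchmark | Sequence[BiasBenchmark],
    n_filler: int = 0,
    seed: int | None = None,
) -> EmbeddingStore:
    """Generate a unit-norm embedding store for a benchmark's terms (or the
    union of terms of several benchmarks).

    Each term's raw vector is ``pole(term)·β·u + ε`` with ``u`` a fixed
    unit bias axis and ε isotropic Gaussian noise, then normalized to unit
    length.  Terms appearing in several roles keep the pole of their first
    role in X, Y, A, B order (benchmarks processed in the given order).
    ``seed`` overrides ``cfg.seed`` (used for replicate families).
    """
    actual_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(actual_seed)
    raw = rng.normal(size=cfg.dimension)
    u = raw / np.linalg.norm(raw)

    benchmarks = [benchmark] if isinstance(benchmark, BiasBenchmark) else list(benchmark)
    poles = dict(DEFAULT_POLES)
    poles.update(cfg.poles)
    term_pole: dict[str, float] = {}
    for bench in benchmarks:
        for role, term_set in (
            ("X", bench.target_x),
            ("Y", bench.target_y),
            ("A", bench.attribute_a),
            ("B", bench.attribute_b),
        ):
            for term in term_set:
                term_pole.setdefault(term, poles.get(role, 0.0))
    for term in filler_terms(n_filler):
        term_pole.setdefault(term, 0.0)

    store = EmbeddingStore(
        source_label=f"synthetic(beta={cfg.bias_strength}, seed={actual_seed})"
    )
    beta = cfg.bias_strength
    for term, pole in term_pole.items():
        vec = pole * beta * u + rng.normal(scale=cfg.noise_scale, size=cfg.dimension)
        norm = np.linalg.norm(vec)
        while norm == 0.0:  # astronomically unlikely; keeps the store valid
            vec = rng.normal(scale=cfg.noise_scale, size=cfg.dimension)
            norm = np.linalg.norm(vec)
        store.add(term, vec / norm)
    return store


def generate_replicate_stores(
    cfg: SyntheticConfig,
    n_replicates: int,
    base_seed: int,
    benchmark: BiasBenchmark | Sequence[BiasBenchmark],
    n_filler: int = 0,
) -> list[EmbeddingStore]:
    """A family of stores sharing the planted-bias structure but with
    independent noise — the synthetic analogue of retraining an embedding
    model under different seeds.  Replicate ``i`` uses seed
    ``base_seed + 1 + i``."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    return [
        generate_synthetic_embeddings(cfg, benchmark, n_filler, seed=base_seed + 1 + i)
        for i in range(n_replicates)
    ]
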