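"""The word embedding association test (WEAT).

Given target term sets X, Y and attribute term sets A, B embedded as
vectors, the per-word association is

    s(w, A, B) = mean_{a in A} cos(w, a) - mean_{b in B} cos(w, b),

the effect size is the Cohen's-d-like quantity

    d = [mean_{x in X} s(x,A,B) - mean_{y in Y} s(y,A,B)]
        / std_{w in X∪Y} s(w,A,B),

and significance comes from the permutation distribution of the test
statistic  s(X,Y,A,B) = Σ_x s(x,A,B) − Σ_y s(y,A,B)  over all partitions
of X∪Y into two equal halves: the one-sided p-value is the fraction of
partitions whose statistic strictly exceeds the observed one.

The standard-deviation denominator uses the population convention
(divide by n) by default, which gives the canonical bound |d| ≤ 2 for
equal-size target sets and reproduces the effect sizes published for the
classic benchmarks; the sample convention is available for sensitivity
checks.

:class:`Weat` is the model object (benchmark × embedding store);
:meth:`Weat.fit` returns a :class:`WeatResults` carrying the estimates,
the p-value bookkeeping and term-resolution reports.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from typing import Literal

import numpy as np

from .benchmarks import BiasBenchmark
from .embeddings import EmbeddingStore, OovPolicy, ResolutionReport, resolve_terms
from .errors import DegenerateTiesWarning, UnbalancedTargetsWarning

__all__ = [
    "association",
    "association_profile",
    "effect_size",
    "test_statistic",
    "p_value",
    "Weat",
    "WeatResults",
    "run_weat",
]

SdConvention = Literal["population", "sample"]

_TIE_TOL = 1e-12


def _as_matrix(vecs) -> np.ndarray:
    mat = np.atleast_2d(np.asarray(vecs, dtype=np.float64))
    if mat.size == 0:
        raise ValueError("empty vector set")
    return mat


def _unit_rows(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero vector has no direction; cosine undefined")
    return mat / norms


def association_profile(W, A_vecs, B_vecs) -> np.ndarray:
    """Vector of associations s(w, A, B) for each row of ``W``."""
    W, A, B = _as_matrix(W), _as_matrix(A_vecs), _as_matrix(B_vecs)
    if not (W.shape[1] == A.shape[1] == B.shape[1]):
        raise ValueError("vector dimensions differ between W, A and B")
    Wn, An, Bn = _unit_rows(W), _unit_rows(A), _unit_rows(B)
    return (Wn @ An.T).mean(axis=1) - (Wn @ Bn.T).mean(axis=1)


def association(w_vec, A_vecs, B_vecs) -> float:
    """s(w, A, B): mean cosine of ``w`` to A minus mean cosine to B."""
    w = np.asarray(w_vec, dtype=np.float64)
    if w.ndim != 1:
        raise ValueError("w_vec must be a single vector")
    return float(association_profile(w[None, :], A_vecs, B_vecs)[0])


def _sd(values: np.ndarray, convention: SdConvention) -> float:
    ddof = 0 if convention == "population" else 1
    if values.size - ddof <= 0:
        return 0.0
    return float(np.std(values, ddof=ddof))


def effect_size(
    X_vecs,
    Y_vecs,
    A_vecs,
    B_vecs,
    sd_convention: SdConvention = "population",
) -> float:
    """WEAT effect size d; returns 0 for the degenerate all-identical case."""
    sX = association_profile(X_vecs, A_vecs, B_vecs)
    sY = association_profile(Y_vecs, A_vecs, B_vecs)
    sd = _sd(np.concatenate([sX, sY]), sd_convention)
    if sd == 0.0:
        return 0.0  # all associations identical, so the means tie too
    return float((sX.mean() - sY.mean()) / sd)


def test_statistic(X_vecs, Y_vecs, A_vecs, B_vecs) -> float:
    """s(X, Y, A, B): sum of associations over X minus sum over Y."""
    sX = association_profile(X_vecs, A_vecs, B_vecs)
    sY = association_profile(Y_vecs, A_vecs, B_vecs)
    return float(sX.sum() - sY.sum())


def _exact_p(s_all: np.ndarray, n_half: int, observed: float) -> tuple[float, int]:
    total = float(s_all.sum())
    n = s_all.size
    greater = 0
    ties = 0
    count = comb(n, n_half)
    for idx in itertools.combinations(range(n), n_half):
        stat = 2.0 * float(s_all[list(idx)].sum()) - total
        if stat > observed + _TIE_TOL:
            greater += 1
        elif abs(stat - observed) <= _TIE_TOL:
            ties += 1
    if ties > 0.01 * count:
        warnings.warn(
            f"{ties}/{count} partition statistics tie the observed statistic; "
            "the strict-inequality p-value may be degenerate",
            DegenerateTiesWarning,
            stacklevel=3,
        )
    return greater / count, count


def _monte_carlo_p(
    s_all: np.ndarray, n_half: int, observed: float, n_draws: int, rng: np.random.Generator
) -> tuple[float, int]:
    total = float(s_all.sum())
    # vectorized random equal-size partitions: argsort of uniforms = random perm
    keys = rng.random((n_draws, s_all.size))
    chosen = np.argsort(keys, axis=1)[:, :n_half]
    stats = 2.0 * np.take(s_all, chosen).sum(axis=1) - total
    greater = int(np.sum(stats > observed + _TIE_TOL))
    ties = int(np.sum(np.abs(stats - observed) <= _TIE_TOL))
    if ties > 0.01 * n_draws:
        warnings.warn(
            f"{ties}/{n_draws} sampled partition statistics tie the observed "
            "statistic; the strict-inequality p-value may be degenerate",
            DegenerateTiesWarning,
            stacklevel=3,
        )
    return greater / n_draws, n_draws


def p_value(
    X_vecs,
    Y_vecs,
    A_vecs,
    B_vecs,
    mode: Literal["auto", "exact", "monte_carlo"] = "auto",
    max_exact: int = 200_000,
    n_draws: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, str, int]:
    """One-sided permutation p-value over equal-size partitions of X∪Y.

    Returns ``(p, method, count)`` where method is ``"exact"`` (all
    C(n, n/2) partitions enumerated) or ``"monte_carlo"`` (``n_draws``
    uniform random partitions); ``auto`` picks exact when the partition
    count is at most ``max_exact``.  Ties with the observed statistic are
    counted as non-exceedances (strict ``>``), with a warning when more
    than 1% of partitions tie.
    """
    sX = association_profile(X_vecs, A_vecs, B_vecs)
    sY = association_profile(Y_vecs, A_vecs, B_vecs)
    if sX.size != sY.size:
        warnings.warn(
            f"|X| = {sX.size} != |Y| = {sY.size}; permuted partitions still "
            "split the union into equal halves",
            UnbalancedTargetsWarning,
            stacklevel=2,
        )
    s_all = np.concatenate([sX, sY])
    n = s_all.size
    if n % 2:
        raise ValueError(
            f"|X ∪ Y| = {n} is odd: it admits no partition into equal halves"
        )
    observed = float(sX.sum() - sY.sum())
    n_half = n // 2
    if mode == "auto":
        mode = "exact" if comb(n, n_half) <= max_exact else "monte_carlo"
    if mode == "exact":
        p, count = _exact_p(s_all, n_half, observed)
        return p, "exact", count
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p, count = _monte_carlo_p(s_all, n_half, observed, n_draws, rng)
    return p, "monte_carlo", count


@dataclass(frozen=True)
class WeatResults:
    """Results of one WEAT: estimates plus resolution bookkeeping."""

    benchmark_id: str
    effect_size: float
    test_statistic: float
    p_value: float
    p_method: str
    n_partitions_or_draws: int
    sd_convention: SdConvention
    resolution: dict[str, ResolutionReport]
    balanced: bool

    @property
    def n_used(self) -> dict[str, int]:
        return {role: rep.n_resolved for role, rep in self.resolution.items()}

    def to_dict(self) -> dict:
        d = {
            "benchmark_id": self.benchmark_id,
            "effect_size": self.effect_size,
            "test_statistic": self.test_statistic,
            "p_value": self.p_value,
            "p_method": self.p_method,
            "n_partitions_or_draws": self.n_partitions_or_draws,
            "sd_convention": self.sd_convention,
            "balanced": self.balanced,
        }
        d.update({f"n_used_{role}": n for role, n in self.n_used.items()})
        return d

    def summary(self) -> str:
        n = self.n_used
        lines = [
            f"WEAT results: {self.benchmark_id}",
            "-" * 46,
            f"{'effect size (d)':<28}{self.effect_size:>14.4f}",
            f"{'test statistic':<28}{self.test_statistic:>14.4f}",
            f"{'p-value (one-sided)':<28}{self.p_value:>14.4g}",
            f"{'p method':<28}{self.p_method:>14}",
            f"{'partitions / draws':<28}{self.n_partitions_or_draws:>14d}",
            f"{'SD convention':<28}{self.sd_convention:>14}",
            f"{'terms used X/Y/A/B':<28}"
            f"{'%d/%d/%d/%d' % (n['X'], n['Y'], n['A'], n['B']):>14}",
        ]
        missing = {r: rep.missing for r, rep in self.resolution.items() if rep.missing}
        if missing:
            lines.append(f"unresolved terms: {missing}")
        if not self.balanced:
            lines.append("note: unequal target sets after resolution")
        return "\n".join(lines)


class Weat:
    """WEAT model for one benchmark against one embedding store.

    Terms are resolved at construction under ``oov_policy`` (default
    ``error``: a single benchmark score should not silently change meaning
    when terms are missing).  :meth:`fit` computes the effect size, test
    statistic and permutation p-value.
    """

    def __init__(
        self,
        benchmark: BiasBenchmark,
        store: EmbeddingStore,
        oov_policy: OovPolicy = "error",
        sd_convention: SdConvention = "population",
    ) -> None:
        self.benchmark = benchmark
        self.store = store
        self.oov_policy = oov_policy
        self.sd_convention: SdConvention = sd_convention
        self.resolution: dict[str, ResolutionReport] = {}
        mats = {}
        for role, term_set in (
            ("X", benchmark.target_x),
            ("Y", benchmark.target_y),
            ("A", benchmark.attribute_a),
            ("B", benchmark.attribute_b),
        ):
            mats[role], self.resolution[role] = resolve_terms(
                store, list(term_set), oov_policy
            )
        self.X, self.Y, self.A, self.B = mats["X"], mats["Y"], mats["A"], mats["B"]

    def fit(
        self,
        p_mode: Literal["auto", "exact", "monte_carlo"] = "auto",
        max_exact: int = 200_000,
        n_draws: int = 10_000,
        seed: int | np.random.Generator | None = None,
    ) -> WeatResults:
        d = effect_size(self.X, self.Y, self.A, self.B, self.sd_convention)
        stat = test_statistic(self.X, self.Y, self.A, self.B)
        p, method, count = p_value(
            self.X, self.Y, self.A, self.B,
            mode=p_mode, max_exact=max_exact, n_draws=n_draws, seed=seed,
        )
        return WeatResults(
            benchmark_id=self.benchmark.id,
            effect_size=d,
            test_statistic=stat,
            p_value=p,
            p_method=method,
            n_partitions_or_draws=count,
            sd_convention=self.sd_convention,
            resolution=dict(self.resolution),
            balanced=self.X.shape[0] == self.Y.shape[0],
        )


def run_weat(
    benchmark: BiasBenchmark,
    store: EmbeddingStore,
    oov_policy: OovPolicy = "error",
    sd_convention: SdConvention = "population",
    **fit_kwargs,
) -> WeatResults:
    """One-call convenience wrapper: ``Weat(benchmark, store).fit()``."""
    return Weat(benchmark, store, oov_policy, sd_convention).fit(**fit_kwargs)
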