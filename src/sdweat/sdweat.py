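"""SD-WEAT: dispersion of WEAT effect sizes under attribute resampling.

Instead of scoring one fixed attribute split, the SD-WEAT pools the two
attribute sets of a benchmark into a single list, draws K (default 100)
fresh attribute pairs (A′, B′) of m words each (default 2) from that pool,
computes the WEAT effect size d_i for every draw with the original targets
X, Y, and reports

    SD_WEAT = SD(d_1, ..., d_K).

Under a symmetric resampling of attribute words the effect sizes average
out near zero, so their spread — not their mean — carries the bias signal.

Significance is calibrated against a negative control: the same targets
scored against attribute pairs drawn from general vocabulary (default
10,000 tests in 100 groups of 100).  The SD of each group yields a null
distribution of scores with mean μ and spread σ, and

    z = (SD_WEAT − μ) / σ,     p = P(Z > z)  (right-tailed normal).

:class:`SDWeat` is the model object; :meth:`SDWeat.fit` returns an
:class:`SDWeatResults`.  :func:`negative_control` builds the
:class:`NullCalibration`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .benchmarks import BiasBenchmark
from .embeddings import (
    EmbeddingStore,
    OovPolicy,
    ResolutionReport,
    resolve_terms,
)
from .errors import TermLookupError
from .weat import SdConvention, WeatResults, _unit_rows, run_weat

__all__ = [
    "pool_attributes",
    "resample_attribute_sets",
    "SDWeat",
    "SDWeatResults",
    "NullCalibration",
    "sd_weat",
    "negative_control",
    "significance",
    "run_sdweat_suite",
    "SDWeatSuiteResult",
]

# fraction of a pool that may fail term resolution before the run aborts
MAX_UNRESOLVED_FRAC = 0.2


def pool_attributes(benchmark: BiasBenchmark) -> list[str]:
    """A ∪ B as one list, duplicates removed, original order kept (A then B)."""
    return list(
        dict.fromkeys(list(benchmark.attribute_a) + list(benchmark.attribute_b))
    )


def _draw_indices(
    pool_size: int, n_pick: int, n_tests: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_tests, n_pick) index array; each row a uniform draw without
    replacement from range(pool_size), rows i.i.d.

    Drawn by rejection on within-row duplicates, which is fast because
    n_pick (2m, typically 4-10) is tiny relative to realistic pools.
    """
    if n_pick > pool_size:
        raise ValueError(
            f"cannot draw {n_pick} distinct terms from a pool of {pool_size}"
        )
    idx = rng.integers(0, pool_size, size=(n_tests, n_pick))
    while True:
        sorted_rows = np.sort(idx, axis=1)
        bad = (np.diff(sorted_rows, axis=1) == 0).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, pool_size, size=(int(bad.sum()), n_pick))


def resample_attribute_sets(
    pool: Sequence[str],
    m: int,
    K: int,
    seed: int | np.random.Generator | None = None,
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """K independent draws of 2m distinct pool terms, split into (A′, B′).

    Draws are i.i.d. across tests (the same 2m-subset may recur), matching
    the estimator's sampling model; within a test the 2m terms are
    distinct, the first m forming A′ and the last m forming B′.
    """
    pool = list(pool)
    if m < 1:
        raise ValueError("m must be at least 1")
    if K < 2:
        raise ValueError("K must be at least 2 to estimate a spread")
    if len(pool) < 2 * m:
        raise ValueError(
            f"attribute pool of {len(pool)} terms cannot supply 2*m = {2 * m} "
            "distinct terms per test"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = _draw_indices(len(pool), 2 * m, K, rng)
    return [
        (tuple(pool[i] for i in row[:m]), tuple(pool[i] for i in row[m:]))
        for row in idx
    ]


def _batch_effect_sizes(
    cos: np.ndarray,
    n_x: int,
    idx: np.ndarray,
    m: int,
    sd_convention: SdConvention,
) -> np.ndarray:
    """Effect sizes for many resampled tests at once.

    ``cos`` is the (n_targets, pool) cosine matrix with the X rows first;
    ``idx`` is (K, 2m) with A′ columns first.  Returns the K effect sizes.
    """
    sA = cos[:, idx[:, :m]].mean(axis=2)  # (n_targets, K)
    sB = cos[:, idx[:, m:]].mean(axis=2)
    s = sA - sB
    num = s[:n_x].mean(axis=0) - s[n_x:].mean(axis=0)
    ddof = 0 if sd_convention == "population" else 1
    denom = s.std(axis=0, ddof=ddof)
    return np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)


def _resolve_pool(
    store: EmbeddingStore,
    terms: Sequence[str],
    oov_policy: OovPolicy,
    what: str,
) -> tuple[np.ndarray, ResolutionReport]:
    vecs, report = resolve_terms(store, terms, oov_policy)
    if report.n_missing > MAX_UNRESOLVED_FRAC * len(terms):
        raise TermLookupError(
            f"{report.n_missing}/{len(terms)} {what} terms failed resolution "
            f"(budget {MAX_UNRESOLVED_FRAC:.0%}): {list(report.missing)[:10]}"
        )
    return vecs, report


@dataclass(frozen=True)
class NullCalibration:
    """Negative-control distribution of SD-WEAT scores.

    ``group_sds`` holds the SD of each group of null effect sizes (attribute
    pairs drawn from general vocabulary, targets unchanged); ``mu`` and
    ``sigma`` are their mean and SD and define the z-score reference.
    """

    group_sds: tuple[float, ...]
    mu: float
    sigma: float
    n_tests: int
    group_size: int
    m: int
    vocab_source: str
    target_spec: str
    seed: int | None = None

    @property
    def n_groups(self) -> int:
        return len(self.group_sds)

    def __post_init__(self) -> None:
        if self.n_groups * self.group_size != self.n_tests:
            raise ValueError("group count × group size must equal n_tests")
        if self.sigma == 0:
            raise ValueError("degenerate control: group SDs have zero spread")
        if self.sigma < 0:
            raise ValueError("sigma must be positive")

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "n_tests": self.n_tests,
            "group_size": self.group_size,
            "n_groups": self.n_groups,
            "m": self.m,
            "vocab_source": self.vocab_source,
            "target_spec": self.target_spec,
            "seed": self.seed,
        }


def significance(sd_score: float, calibration: NullCalibration) -> tuple[float, float]:
    """z-score of an SD-WEAT score against its negative control, and the
    right-tailed normal p-value."""
    if calibration.sigma <= 0:
        raise ValueError("degenerate control: sigma must be positive")
    z = (sd_score - calibration.mu) / calibration.sigma
    return float(z), float(sps.norm.sf(z))


@dataclass(frozen=True)
class SDWeatResults:
    """Results of one SD-WEAT run.

    ``effect_sizes`` are the K resampled effect sizes d_i; ``sd_score`` is
    their SD under ``score_sd_convention``; ``draws`` records each test's
    (A′, B′) terms for individual-level inspection.  ``z``/``p_right`` are
    present when a calibration was supplied.
    """

    benchmark_id: str
    sd_score: float
    effect_sizes: tuple[float, ...]
    mean_effect: float
    m: int
    K: int
    seed: int | None
    score_sd_convention: SdConvention
    effect_sd_convention: SdConvention
    draws: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    resolution: dict[str, ResolutionReport]
    z: float | None = None
    p_right: float | None = None
    calibration: NullCalibration | None = None

    def to_dict(self) -> dict:
        return {
            "benchmark_id": self.benchmark_id,
            "sd_score": self.sd_score,
            "mean_effect": self.mean_effect,
            "m": self.m,
            "K": self.K,
            "seed": self.seed,
            "z": self.z,
            "p_right": self.p_right,
            "score_sd_convention": self.score_sd_convention,
            "effect_sd_convention": self.effect_sd_convention,
        }

    def summary(self) -> str:
        lines = [
            f"SD-WEAT results: {self.benchmark_id}",
            "-" * 46,
            f"{'SD-WEAT score':<28}{self.sd_score:>14.4f}",
            f"{'mean resampled effect':<28}{self.mean_effect:>14.4f}",
            f"{'attribute size m':<28}{self.m:>14d}",
            f"{'tests K':<28}{self.K:>14d}",
            f"{'seed':<28}{str(self.seed):>14}",
        ]
        if self.z is not None:
            lines += [
                f"{'z vs negative control':<28}{self.z:>14.4f}",
                f"{'p (right-tailed)':<28}{self.p_right:>14.4g}",
                f"{'control mu, sigma':<28}"
                f"{'%.4f, %.4f' % (self.calibration.mu, self.calibration.sigma):>14}",
            ]
        return "\n".join(lines)


class SDWeat:
    """SD-WEAT model for one benchmark against one embedding store.

    Targets and the pooled attribute list are resolved at construction
    under ``oov_policy`` (default ``lowercase_fallback``, falling through
    to skip-with-report: resampling tolerates missing pool words).  More
    than 20% unresolved terms in either targets or pool aborts.
    """

    def __init__(
        self,
        benchmark: BiasBenchmark,
        store: EmbeddingStore,
        m: int = 2,
        K: int = 100,
        oov_policy: OovPolicy = "lowercase_fallback",
        score_sd_convention: SdConvention = "sample",
        effect_sd_convention: SdConvention = "population",
    ) -> None:
        if m < 1:
            raise ValueError("m must be at least 1")
        if K < 2:
            raise ValueError("K must be at least 2")
        self.benchmark = benchmark
        self.store = store
        self.m = m
        self.K = K
        self.score_sd_convention: SdConvention = score_sd_convention
        self.effect_sd_convention: SdConvention = effect_sd_convention
        self.resolution: dict[str, ResolutionReport] = {}

        X, self.resolution["X"] = _resolve_pool(
            store, list(benchmark.target_x), oov_policy, "target X"
        )
        Y, self.resolution["Y"] = _resolve_pool(
            store, list(benchmark.target_y), oov_policy, "target Y"
        )
        pool_terms = pool_attributes(benchmark)
        pool_vecs, self.resolution["pool"] = _resolve_pool(
            store, pool_terms, oov_policy, "pooled attribute"
        )
        self.pool = self.resolution["pool"].resolved_terms
        if len(self.pool) < 2 * m:
            raise TermLookupError(
                f"resolved attribute pool has {len(self.pool)} terms; "
                f"need at least 2*m = {2 * m}"
            )
        self.n_x = X.shape[0]
        targets = np.vstack([X, Y])
        self._cos = _unit_rows(targets) @ _unit_rows(pool_vecs).T

    def fit(
        self,
        seed: int | None = 0,
        calibration: NullCalibration | None = None,
    ) -> SDWeatResults:
        rng = np.random.default_rng(seed)
        idx = _draw_indices(len(self.pool), 2 * self.m, self.K, rng)
        d = _batch_effect_sizes(
            self._cos, self.n_x, idx, self.m, self.effect_sd_convention
        )
        ddof = 1 if self.score_sd_convention == "sample" else 0
        sd_score = float(np.std(d, ddof=ddof))
        draws = tuple(
            (
                tuple(self.pool[i] for i in row[: self.m]),
                tuple(self.pool[i] for i in row[self.m:]),
            )
            for row in idx
        )
        z = p_right = None
        if calibration is not None:
            z, p_right = significance(sd_score, calibration)
        return SDWeatResults(
            benchmark_id=self.benchmark.id,
            sd_score=sd_score,
            effect_sizes=tuple(float(v) for v in d),
            mean_effect=float(d.mean()),
            m=self.m,
            K=self.K,
            seed=seed,
            score_sd_convention=self.score_sd_convention,
            effect_sd_convention=self.effect_sd_convention,
            draws=draws,
            resolution=dict(self.resolution),
            z=z,
            p_right=p_right,
            calibration=calibration,
        )


def sd_weat(
    benchmark: BiasBenchmark,
    store: EmbeddingStore,
    m: int = 2,
    K: int = 100,
    seed: int | None = 0,
    calibration: NullCalibration | None = None,
    **model_kwargs,
) -> SDWeatResults:
    """One-call convenience wrapper: ``SDWeat(benchmark, store).fit()``."""
    return SDWeat(benchmark, store, m=m, K=K, **model_kwargs).fit(
        seed=seed, calibration=calibration
    )


def negative_control(
    benchmark: BiasBenchmark,
    store: EmbeddingStore,
    vocab: Sequence[str],
    m: int = 2,
    n_tests: int = 10_000,
    group_size: int = 100,
    seed: int | None = 0,
    oov_policy: OovPolicy = "lowercase_fallback",
    effect_sd_convention: SdConvention = "population",
    group_sd_convention: SdConvention = "sample",
) -> NullCalibration:
    """Calibrate the null distribution of SD-WEAT scores for a benchmark's
    targets using random-vocabulary attribute sets.

    Builds ``n_tests`` resampled tests whose attribute pairs come from
    ``vocab`` (targets unchanged), computes their effect sizes, splits them
    in draw order into groups of ``group_size``, and records the SD of each
    group.  The mean μ and SD σ of those group SDs calibrate the z-score.
    """
    if n_tests % group_size:
        raise ValueError(
            f"n_tests = {n_tests} is not divisible by group_size = {group_size}"
        )
    n_groups = n_tests // group_size
    if n_groups < 2:
        raise ValueError(
            "need at least 2 groups to estimate sigma; lower group_size or "
            "raise n_tests"
        )
    X, _ = _resolve_pool(store, list(benchmark.target_x), oov_policy, "target X")
    Y, _ = _resolve_pool(store, list(benchmark.target_y), oov_policy, "target Y")
    vocab = list(vocab)
    vocab_vecs, vocab_report = _resolve_pool(store, vocab, oov_policy, "vocabulary")
    resolved_vocab = vocab_report.resolved_terms
    if len(resolved_vocab) < 2 * m:
        raise TermLookupError(
            f"resolved control vocabulary has {len(resolved_vocab)} terms; "
            f"need at least 2*m = {2 * m}"
        )
    cos = _unit_rows(np.vstack([X, Y])) @ _unit_rows(vocab_vecs).T
    rng = np.random.default_rng(seed)
    idx = _draw_indices(len(resolved_vocab), 2 * m, n_tests, rng)
    d = _batch_effect_sizes(cos, X.shape[0], idx, m, effect_sd_convention)
    ddof = 1 if group_sd_convention == "sample" else 0
    group_sds = d.reshape(n_groups, group_size).std(axis=1, ddof=ddof)
    mu = float(group_sds.mean())
    sigma = float(group_sds.std(ddof=ddof))
    if sigma <= 0:
        raise ValueError("degenerate control: group SDs have zero spread")
    return NullCalibration(
        group_sds=tuple(float(v) for v in group_sds),
        mu=mu,
        sigma=sigma,
        n_tests=n_tests,
        group_size=group_size,
        m=m,
        vocab_source=store.source_label or "vocabulary",
        target_spec=benchmark.id,
        seed=seed,
    )


@dataclass(frozen=True)
class SDWeatSuiteResult:
    """Per-benchmark WEAT + SD-WEAT results and cross-method correlations."""

    weat_results: tuple[WeatResults, ...]
    sdweat_results: tuple[SDWeatResults, ...]
    calibrations: tuple[NullCalibration | None, ...]
    effect_correlation: float | None
    p_correlation: float | None

    def to_frame(self):
        import pandas as pd

        rows = []
        for w, s in zip(self.weat_results, self.sdweat_results):
            rows.append(
                {
                    "benchmark_id": w.benchmark_id,
                    "weat_effect_size": w.effect_size,
                    "weat_p_value": w.p_value,
                    "sd_score": s.sd_score,
                    "mean_effect": s.mean_effect,
                    "z": s.z,
                    "p_right": s.p_right,
                    "m": s.m,
                    "K": s.K,
                }
            )
        return pd.DataFrame(rows)


def _store_for(store, benchmark_id: str) -> EmbeddingStore:
    if isinstance(store, Mapping):
        return store[benchmark_id]
    return store


def run_sdweat_suite(
    benchmarks: Sequence[BiasBenchmark],
    store: EmbeddingStore | Mapping[str, EmbeddingStore],
    m: int = 2,
    K: int = 100,
    seed: int = 0,
    control_vocab: Sequence[str] | Mapping[str, Sequence[str]] | None = None,
    n_control_tests: int = 10_000,
    group_size: int = 100,
    oov_policy: OovPolicy = "lowercase_fallback",
    p_mode: Literal["auto", "exact", "monte_carlo"] = "auto",
    share_controls: bool = False,
) -> SDWeatSuiteResult:
    """Run WEAT and SD-WEAT over a list of benchmarks and correlate them.

    ``store`` may be one shared store or a mapping benchmark id → store
    (synthetic families).  If ``control_vocab`` is given, each benchmark
    gets its own negative control by default (the control depends on the
    targets); ``share_controls`` reuses one calibration across benchmarks
    with identical target sets.  Pearson correlations between the two
    methods' effect sizes and p-values are reported when at least two
    benchmarks are scored (``None`` otherwise).
    """
    weat_results: list[WeatResults] = []
    sdweat_results: list[SDWeatResults] = []
    calibrations: list[NullCalibration | None] = []
    control_cache: dict = {}
    for i, bench in enumerate(benchmarks):
        bstore = _store_for(store, bench.id)
        bench_seed = seed + i
        calib = None
        if control_vocab is not None:
            vocab = (
                control_vocab[bench.id]
                if isinstance(control_vocab, Mapping)
                else control_vocab
            )
            cache_key = (
                (bench.target_x.terms, bench.target_y.terms, id(bstore))
                if share_controls
                else i
            )
            if cache_key not in control_cache:
                control_cache[cache_key] = negative_control(
                    bench,
                    bstore,
                    vocab,
                    m=m,
                    n_tests=n_control_tests,
                    group_size=group_size,
                    seed=seed + 10_000 + i,
                    oov_policy=oov_policy,
                )
            calib = control_cache[cache_key]
        weat_results.append(
            run_weat(bench, bstore, oov_policy=oov_policy, p_mode=p_mode,
                     seed=bench_seed)
        )
        sdweat_results.append(
            SDWeat(bench, bstore, m=m, K=K, oov_policy=oov_policy).fit(
                seed=bench_seed, calibration=calib
            )
        )
        calibrations.append(calib)

    effect_corr = p_corr = None
    if len(weat_results) >= 2:
        d_weat = np.array([w.effect_size for w in weat_results])
        d_sd = np.array([s.sd_score for s in sdweat_results])
        if np.std(d_weat) > 0 and np.std(d_sd) > 0:
            effect_corr = float(sps.pearsonr(d_weat, d_sd).statistic)
        if all(s.p_right is not None for s in sdweat_results):
            p_weat = np.array([w.p_value for w in weat_results])
            p_sd = np.array([s.p_right for s in sdweat_results])
            if np.std(p_weat) > 0 and np.std(p_sd) > 0:
                p_corr = float(sps.pearsonr(p_weat, p_sd).statistic)
    return SDWeatSuiteResult(
        weat_results=tuple(weat_results),
        sdweat_results=tuple(sdweat_results),
        calibrations=tuple(calibrations),
        effect_correlation=effect_corr,
        p_correlation=p_corr,
    )
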