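"""Stability of embedding methods: spread of bias scores across replicates.

An embedding method retrained under different random seeds should, if
stable, give similar bias scores.  This module scores each replicate model
of a method on a set of benchmarks with either the WEAT effect size or the
SD-WEAT score (:func:`score_replicates` → :class:`ScorePanel`), then
summarizes the per-benchmark spread (SD across replicates, plus min/max)
and ranks methods by their mean spread, lower being more stable
(:func:`summarize_stability` → :class:`StabilityReport`).

The spread is taken over the signed scores — a sign flip between
replicates is itself instability, not something to be absolved by an
absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .benchmarks import BiasBenchmark
from .embeddings import EmbeddingStore, OovPolicy
from .errors import TermLookupError
from .sdweat import SDWeat
from .weat import Weat, effect_size

__all__ = ["ScorePanel", "StabilityReport", "score_replicates", "summarize_stability"]

Metric = Literal["weat", "sdweat"]


@dataclass(frozen=True)
class ScorePanel:
    """Replicate × benchmark score matrix for one method and one metric.

    ``scores`` is a DataFrame indexed by benchmark id with one column per
    replicate (0..R−1); ``seeds`` records the resampling seed used for
    each replicate (identical when the resampling seed was frozen).
    """

    method_label: str
    metric: Metric
    scores: pd.DataFrame
    seeds: tuple[int | None, ...]

    def __post_init__(self) -> None:
        if self.scores.shape[1] < 2:
            raise ValueError("a score panel needs at least 2 replicates")

    @property
    def n_replicates(self) -> int:
        return self.scores.shape[1]

    @property
    def benchmark_ids(self) -> list[str]:
        return list(self.scores.index)


def score_replicates(
    stores: Sequence[EmbeddingStore],
    benchmarks: Sequence[BiasBenchmark],
    metric: Metric = "weat",
    method_label: str = "",
    m: int = 2,
    K: int = 100,
    base_seed: int = 0,
    freeze_resample_seed: bool = False,
    oov_policy: OovPolicy = "lowercase_fallback",
    max_missing_frac: float = 0.2,
) -> ScorePanel:
    """Score every replicate store on every benchmark with one metric.

    WEAT cells hold the effect size; SD-WEAT cells hold the SD score with
    per-replicate resampling seed ``base_seed + replicate`` (or a frozen
    ``base_seed`` for all replicates, to isolate model variability from
    resampling noise).  A store failing term resolution on a benchmark
    leaves that cell missing; more than ``max_missing_frac`` missing cells
    aborts.
    """
    if len(stores) < 2:
        raise ValueError("need at least 2 replicate stores")
    label = method_label or (stores[0].source_label or "method")
    seeds: list[int | None] = []
    columns = {}
    for r, store in enumerate(stores):
        seed = base_seed if freeze_resample_seed else base_seed + r
        seeds.append(seed)
        col = {}
        for bench in benchmarks:
            try:
                if metric == "weat":
                    model = Weat(bench, store, oov_policy=oov_policy)
                    col[bench.id] = effect_size(
                        model.X, model.Y, model.A, model.B, model.sd_convention
                    )
                else:
                    col[bench.id] = (
                        SDWeat(bench, store, m=m, K=K, oov_policy=oov_policy)
                        .fit(seed=seed)
                        .sd_score
                    )
            except TermLookupError:
                col[bench.id] = np.nan
        columns[r] = col
    scores = pd.DataFrame(columns).reindex([b.id for b in benchmarks])
    n_missing = int(scores.isna().sum().sum())
    if n_missing > max_missing_frac * scores.size:
        raise TermLookupError(
            f"{n_missing}/{scores.size} replicate×benchmark cells failed "
            f"resolution (budget {max_missing_frac:.0%})"
        )
    return ScorePanel(method_label=label, metric=metric, scores=scores,
                      seeds=tuple(seeds))


@dataclass(frozen=True)
class StabilityReport:
    """Stability summary across methods.

    ``per_benchmark``: rows (method, metric, benchmark_id) with min, max
    and SD of the replicate scores.  ``per_method``: mean of the
    per-benchmark SDs.  ``ranking``: per metric, methods ordered from most
    stable (smallest mean SD) to least.  ``paired`` compares, per method
    present under both metrics, the SD-WEAT spread against the WEAT spread
    benchmark by benchmark.
    """

    per_benchmark: pd.DataFrame
    per_method: pd.DataFrame
    ranking: dict[str, list[str]]
    paired: pd.DataFrame | None

    def summary(self) -> str:
        lines = ["Stability report (lower SD = more stable)", "-" * 46]
        for metric, methods in sorted(self.ranking.items()):
            lines.append(f"{metric}: " + " < ".join(methods))
        lines.append("")
        lines.append(self.per_method.to_string(index=False))
        return "\n".join(lines)


def summarize_stability(panels: Sequence[ScorePanel]) -> StabilityReport:
    """Aggregate score panels into a stability report.

    All panels must cover the same benchmark set.  Spreads are sample SDs
    (ddof=1) across replicates; results are sorted by (method, metric,
    benchmark) so the report is invariant to panel, replicate and
    benchmark ordering.
    """
    if not panels:
        raise ValueError("no panels given")
    bench_sets = {frozenset(p.benchmark_ids) for p in panels}
    if len(bench_sets) > 1:
        raise ValueError("panels cover different benchmark sets")

    rows = []
    for panel in panels:
        ordered = panel.scores.sort_index()
        for bench_id, values in ordered.iterrows():
            vals = values.dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "method": panel.method_label,
                    "metric": panel.metric,
                    "benchmark_id": bench_id,
                    "n_replicates": vals.size,
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                }
            )
    per_benchmark = (
        pd.DataFrame(rows)
        .sort_values(["method", "metric", "benchmark_id"])
        .reset_index(drop=True)
    )
    per_method = (
        per_benchmark.groupby(["method", "metric"], as_index=False)["sd"]
        .mean()
        .rename(columns={"sd": "mean_sd"})
        .sort_values(["metric", "mean_sd", "method"])
        .reset_index(drop=True)
    )
    ranking = {
        metric: grp.sort_values(["mean_sd", "method"])["method"].tolist()
        for metric, grp in per_method.groupby("metric")
    }

    paired = None
    metrics_by_method = per_method.groupby("method")["metric"].apply(set)
    both = [mth for mth, ms in metrics_by_method.items() if {"weat", "sdweat"} <= ms]
    if both:
        wide = per_benchmark[per_benchmark["method"].isin(both)].pivot_table(
            index=["method", "benchmark_id"], columns="metric", values="sd"
        )
        paired = (
            wide.rename(columns={"weat": "weat_sd", "sdweat": "sdweat_sd"})
            .assign(sdweat_minus_weat=lambda f: f["sdweat_sd"] - f["weat_sd"])
            .reset_index()
        )
        paired.columns.name = None
    return StabilityReport(
        per_benchmark=per_benchmark,
        per_method=per_method,
        ranking=ranking,
        paired=paired,
    )
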