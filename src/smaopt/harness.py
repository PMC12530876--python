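"""Experimental protocol: split sweeps, IST/OST evaluation, aggregation, selection.

The surrogate comparison trains every (family, hyperparameters) combination
on every dataset at a sweep of train/test split ratios, with many seeded
splits per ratio.  Performance is reported two ways: on the held-out part of
the training dataset (in-sample test, IST) and on the union of all *other*
datasets (out-of-sample test, OST) — the latter probes generalization beyond
the sampling design that produced the training data.  Per-group means and
sample standard deviations are compared with Welch's two-sample t-test, and
the best models by MAPE and by R^2 feed the optimization stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .data import DensityDataset
from .errors import ContractError, ParameterizationError
from .surrogates import DEFAULT_GRIDS, MetricReport, ModelSpec, evaluate, train


@dataclass(frozen=True)
class SplitSpec:
    """A pseudo-random train/test partition: training fraction + seed."""

    ratio: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio < 1.0:
            raise ContractError(f"split ratio must be in (0, 1), got {self.ratio}")


@dataclass(frozen=True)
class ExperimentPlan:
    """Bookkeeping of a full comparison sweep."""

    datasets: tuple[str, ...]
    ratios: tuple[float, ...]
    seeds_per_ratio: int
    family_grids: dict[str, list[dict]] = field(default_factory=lambda: dict(DEFAULT_GRIDS))


def enumerate_ratios(start: float, stop: float, step: float) -> list[float]:
    """Inclusive arithmetic sequence of split ratios, endpoint tolerance 1e-9."""
    if not (0.0 < start <= stop < 1.0) or step <= 0:
        raise ParameterizationError(
            f"need 0 < start <= stop < 1 and step > 0, got ({start}, {stop}, {step})"
        )
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return [round(start + i * step, 12) for i in range(n)]


def split(ds: DensityDataset, s: SplitSpec) -> tuple[DensityDataset, DensityDataset]:
    """Seeded disjoint, exhaustive partition; ``|train| = round(ratio * n)``."""
    n = len(ds)
    n_train = int(np.floor(s.ratio * n + 0.5))
    if not 1 <= n_train <= n - 1:
        raise ContractError(
            f"ratio {s.ratio} on n={n} gives degenerate split sizes ({n_train})"
        )
    perm = np.random.default_rng(s.seed).permutation(n)
    return (
        ds.subset(np.sort(perm[:n_train])),
        ds.subset(np.sort(perm[n_train:])),
    )


def run_ist_ost(
    spec: ModelSpec,
    ds: DensityDataset,
    s: SplitSpec,
    others: list[DensityDataset],
) -> tuple[MetricReport, MetricReport]:
    """Train on a seeded split of ``ds``; score IST on the held-out part and
    OST on the concatenation of every other dataset."""
    for other in others:
        if other.name == ds.name:
            raise ContractError(f"dataset {ds.name!r} appears in its own OST pool")
    if not others:
        raise ContractError("OST needs at least one other dataset")
    train_ds, test_ds = split(ds, s)
    model = train(spec, train_ds, fingerprint=f"{ds.name}/r{s.ratio}/s{s.seed}")
    ist = evaluate(model, test_ds, "IST")
    pool = DensityDataset(
        "OST", pd.concat([o.frame for o in others], ignore_index=True)
    )
    ost = evaluate(model, pool, "OST")
    return ist, ost


def plan_counts(plan: ExperimentPlan) -> dict[str, int]:
    """Planned model-training counts per family.

    count = |ratios| x seeds_per_ratio x |datasets| x |hyperparameter grid|
    (grid size 1 for the plain linear fit and the fixed-architecture network).
    """
    base = len(plan.ratios) * plan.seeds_per_ratio * len(plan.datasets)
    return {fam: base * len(grid) for fam, grid in plan.family_grids.items()}


def aggregate(
    reports: list[tuple[ModelSpec, str, SplitSpec, MetricReport]]
) -> pd.DataFrame:
    """Group per-run metrics to mean +/- sample sd.

    ``reports`` rows are (spec, dataset name, split, metric report); grouping
    key is (family, hyperparameters, dataset, ratio, mode).  The standard
    deviation is the n-1 sample form.
    """
    if not reports:
        raise ContractError("nothing to aggregate")
    rows = [
        {
            "family": spec.family,
            "hyperparams": json.dumps(spec.hp(), sort_keys=True),
            "dataset": dataset,
            "ratio": s.ratio,
            "mode": rep.mode,
            "mape": rep.mape,
            "r2": rep.r2,
        }
        for spec, dataset, s, rep in reports
    ]
    frame = pd.DataFrame(rows)
    agg = (
        frame.groupby(["family", "hyperparams", "dataset", "ratio", "mode"])
        .agg(
            mean_mape=("mape", "mean"),
            sd_mape=("mape", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            mean_r2=("r2", "mean"),
            sd_r2=("r2", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            n=("mape", "size"),
        )
        .reset_index()
    )
    return agg


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def compare_means(a: list[float], b: list[float]) -> StatTestResult:
    """Welch's two-sample two-sided t-test on per-model scores.

    When every value in both groups is identical the test is degenerate and
    ``p = 1`` by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ContractError("compare_means needs at least 2 values per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return StatTestResult(0.0, 1.0, len(a), len(b))
        return StatTestResult(float("inf"), 0.0, len(a), len(b))
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return StatTestResult(float(t), float(p), len(a), len(b))


@dataclass(frozen=True)
class TopSelection:
    """Ranked best-model ids and their deduplicated union."""

    by_mape: tuple[str, ...]
    by_r2: tuple[str, ...]
    union: tuple[str, ...]
    duplicates: dict[str, str]  # dropped id -> retained id with identical metrics


def select_top(models: list[tuple[str, float, float]], k: int) -> TopSelection:
    """Union of the k lowest-MAPE and k highest-R^2 models.

    Entries with identical (MAPE, R^2) pairs are treated as the same
    underlying model (the first id is retained); ties within a ranking break
    on the secondary metric, then on id.  Returns both ranked lists and the
    deduplicated union in first-appearance order.
    """
    if k < 1:
        raise ContractError("k must be >= 1")
    seen: dict[tuple[float, float], str] = {}
    duplicates: dict[str, str] = {}
    unique: list[tuple[str, float, float]] = []
    for mid, m, r in models:
        key = (m, r)
        if key in seen:
            duplicates[mid] = seen[key]
        else:
            seen[key] = mid
            unique.append((mid, m, r))
    if k > len(unique):
        raise ContractError(f"k={k} exceeds the {len(unique)} distinct models")
    by_mape = sorted(unique, key=lambda t: (t[1], -t[2], t[0]))[:k]
    by_r2 = sorted(unique, key=lambda t: (-t[2], t[1], t[0]))[:k]
    union: list[str] = []
    for mid, _, _ in by_mape + by_r2:
        if mid not in union:
            union.append(mid)
    return TopSelection(
        tuple(t[0] for t in by_mape),
        tuple(t[0] for t in by_r2),
        tuple(union),
        duplicates,
    )


def load_candidate_metrics() -> list[tuple[str, float, float]]:
    """Bundled benchmark table of 24 candidate network models.

    (id, MAPE, R^2) rows of the 12 best-by-MAPE and 12 best-by-R^2 candidate
    surrogates from a published density-prediction benchmark; rows naming the
    same underlying model appear once per ranking.  Used to exercise the
    selection rule on realistic metric values.
    """
    with resources.files("smaopt").joinpath("data/candidate_fnn_metrics.csv").open() as fh:
        frame = pd.read_csv(fh)
    return [
        (str(n), float(m), float(r))
        for n, m, r in frame[["name", "mape", "r2"]].itertuples(index=False, name=None)
    ]
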