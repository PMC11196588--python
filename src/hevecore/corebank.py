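"""Cluster-stratified stepwise core-collection construction.

A core collection is a minimal accession subset that preserves the
genetic diversity of the full panel.  Construction here is stratified by
cluster: per group, the target count is ``max(1, round-half-up(ratio *
group size))``, and accessions are chosen by stepwise redundancy
elimination — repeatedly locate the closest remaining pair and discard
the member with the smaller mean distance to everything else (the more
redundant one) until the target count remains.  Diversity retention
(core He/PIC/pi as a percentage of the original) across a sweep of
sampling ratios drives the recommended ratio: the smallest ratio at
which every group retains at least ``min_retention`` of each statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divstats import population_summary, retention_rate
from .genotype_io import GenotypePanel
from .popstruct import DistanceMatrix, ibs_distance

DEFAULT_RATIOS = (0.1, 0.2, 0.3, 0.4, 0.5)


def allocate_counts(group_sizes: dict | list, ratio: float) -> dict:
    """Per-group core sizes: round-half-up with a one-accession floor."""
    if not 0 < ratio <= 1:
        raise ValueError("ratio must lie in (0, 1]")
    if isinstance(group_sizes, dict):
        items = list(group_sizes.items())
    else:
        items = list(enumerate(group_sizes))
    if not items:
        raise ValueError("no groups")
    out = {}
    for name, size in items:
        if size < 0:
            raise ValueError("negative group size")
        if size == 0:
            continue
        out[name] = min(size, max(1, math.floor(ratio * size + 0.5)))
    return out


def stepwise_core_sample(
    dm: DistanceMatrix, n_target: int, seed: int | None = None
) -> list[str]:
    """Stepwise redundancy elimination within one group.

    Repeatedly find the pair at the smallest distance and drop whichever
    member has the smaller mean distance to all remaining samples.  All
    ties break by sample order in ``dm.ids``, so the procedure is fully
    deterministic; ``seed`` is accepted for interface symmetry with the
    stochastic stages but unused.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if n_target > dm.n:
        raise ValueError("n_target exceeds group size")
    remaining = list(range(dm.n))
    D = dm.values
    while len(remaining) > n_target:
        idx = np.array(remaining)
        sub = D[np.ix_(idx, idx)]
        np.fill_diagonal(sub, np.inf)
        a, b = divmod(int(np.argmin(sub)), len(idx))  # row-major => smallest pair
        if a > b:
            a, b = b, a
        np.fill_diagonal(sub, 0.0)
        mean_a = _mean_to_others(sub, a)
        mean_b = _mean_to_others(sub, b)
        # drop the more redundant member; tie -> keep the earlier sample
        drop = idx[b] if mean_b <= mean_a else idx[a]
        remaining.remove(int(drop))
    return [dm.ids[i] for i in remaining]


def _mean_to_others(sub: np.ndarray, i: int) -> float:
    n = sub.shape[0]
    if n < 2:
        return 0.0
    row = np.delete(sub[i], i)
    return float(row.mean())


@dataclass
class CoreSubset:
    """A core collection at one sampling ratio."""

    ratio: float
    selected: dict  # group -> list of sample ids
    counts: dict  # group -> target count
    summary: pd.DataFrame  # per-group + Mean diversity of the core
    sample_ids: list[str] = field(default_factory=list)


def build_core(
    panel: GenotypePanel,
    group_labels: np.ndarray | list,
    ratio: float,
    dm: DistanceMatrix | None = None,
) -> CoreSubset:
    """Allocate per-group counts, sample stepwise, and summarize the core."""
    labels = np.asarray(group_labels)
    if labels.shape[0] != panel.n_samples:
        raise ValueError("one label per sample required")
    if dm is None:
        dm = ibs_distance(panel)
    groups = list(pd.unique(labels))
    sizes = {g: int((labels == g).sum()) for g in groups}
    counts = allocate_counts(sizes, ratio)
    selected: dict = {}
    for g in groups:
        ids = [panel.sample_ids[i] for i in np.flatnonzero(labels == g)]
        if len(ids) == 1:
            selected[g] = ids
            continue
        selected[g] = stepwise_core_sample(dm.subset(ids), counts[g])
    all_ids = [s for g in groups for s in selected[g]]
    core_panel = panel.subset_by_sample_ids(all_ids)
    core_labels = np.concatenate(
        [np.full(len(selected[g]), g, dtype=labels.dtype) for g in groups]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = population_summary(core_panel, core_labels)
    return CoreSubset(ratio, selected, counts, summary, all_ids)


def sweep_ratios(
    panel: GenotypePanel,
    group_labels: np.ndarray | list,
    ratios: tuple[float, ...] = DEFAULT_RATIOS,
) -> pd.DataFrame:
    """Core diversity per group across sampling ratios, plus 100% baselines.

    Output has one row per (group, ratio) with columns ``group,
    ratio_pct, n_selected, he, pic, pi`` — the shape of a published
    core-collection sweep table.
    """
    labels = np.asarray(group_labels)
    dm = ibs_distance(panel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        baseline = population_summary(panel, labels, add_mean_row=False)
    rows = []
    for ratio in sorted(ratios):
        core = build_core(panel, labels, ratio, dm=dm)
        for _, row in core.summary.iterrows():
            if row["population"] == "Mean":
                continue
            g = row["population"]
            rows.append(
                {
                    "group": g,
                    "ratio_pct": round(100 * ratio),
                    "n_selected": int(row["n_samples"]),
                    "he": row["mean_he"],
                    "pic": row["mean_pic"],
                    "pi": row["mean_pi"],
                }
            )
    for _, row in baseline.iterrows():
        rows.append(
            {
                "group": str(row["population"]),
                "ratio_pct": 100,
                "n_selected": int(row["n_samples"]),
                "he": row["mean_he"],
                "pic": row["mean_pic"],
                "pi": row["mean_pi"],
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["group", "ratio_pct"]).reset_index(drop=True)


def recommend_ratio(sweep: pd.DataFrame, min_retention: float = 0.95) -> float:
    """Smallest sampling ratio retaining ``min_retention`` of He, PIC and pi
    in every group; falls back to the best-retaining ratio with a warning.
    """
    if sweep.empty:
        raise ValueError("empty sweep")
    baselines = sweep[sweep["ratio_pct"] == 100].set_index("group")
    if baselines.empty:
        raise ValueError("sweep lacks 100% baseline rows")
    candidate_pcts = sorted(set(sweep["ratio_pct"]) - {100})
    scores = {}
    for pct in candidate_pcts:
        worst = np.inf
        for _, row in sweep[sweep["ratio_pct"] == pct].iterrows():
            base = baselines.loc[row["group"]]
            rates = retention_rate(row, base)
            worst = min(worst, *[v for v in rates.values() if v is not None])
        scores[pct] = worst
        if worst >= 100.0 * min_retention:
            return pct / 100.0
    best = max(scores, key=lambda p: (scores[p], -p))
    warnings.warn(
        f"no ratio retains {min_retention:.0%} of every statistic; "
        f"returning best-retaining ratio {best}%",
        UserWarning,
        stacklevel=2,
    )
    return best / 100.0
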