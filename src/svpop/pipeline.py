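"""End-to-end study runner on simulated data.

Chains the full pipeline — simulate truth and callers, merge per sample,
filter, merge across the population — and measures truth-referenced
quality metrics: the per-call false discovery rate of the filtered
per-sample callsets, recall of carried truth SVs, and population-level
recall of common truth SVs.  Used by the validation suite; real-data runs
go through the library modules (or the CLI) directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .compare import match_reciprocal
from .filters import apply_filters
from .merge import merge_within_sample
from .model import FilterReport, MergedCall, PopulationSV, SVCall
from .population import category_counts, merge_population
from .simulate import (
    DEFAULT_PROFILES,
    CallerProfile,
    SimGenome,
    SimParams,
    SimTruth,
    simulate_callsets,
    simulate_genome,
    simulate_population,
)


@dataclass(slots=True)
class StudyResult:
    truth: SimTruth
    per_sample_merged: dict[str, list[MergedCall]]
    filter_reports: dict[str, FilterReport]
    popset: list[PopulationSV]
    metrics: dict = field(default_factory=dict)


def run_study(
    params: SimParams,
    profiles: Sequence[CallerProfile] = DEFAULT_PROFILES,
    genome: SimGenome | None = None,
    min_callers: int = 2,
    min_reads: int = 3,
    match_frac: float = 0.5,
) -> StudyResult:
    """Simulate a cohort, run the full pipeline, and score it against the
    generated truth."""
    if genome is None:
        genome = simulate_genome(seed=params.seed)
    truth = simulate_population(params, genome)
    callsets = simulate_callsets(truth, profiles, seed=params.seed)

    geno = truth.genotypes.to_numpy()
    per_sample_merged: dict[str, list[MergedCall]] = {}
    reports: dict[str, FilterReport] = {}
    n_calls = n_false = 0
    n_carried = n_recovered = 0
    for s_idx, sample in enumerate(truth.samples):
        merged = merge_within_sample(
            {caller: callsets[caller][sample] for caller in callsets},
            min_callers=min_callers,
        )
        filtered, report = apply_filters(
            merged, masks=genome.masks, min_reads=min_reads
        )
        per_sample_merged[sample] = filtered
        reports[sample] = report

        carried = [truth.svs[i] for i in np.where(geno[s_idx] > 0)[0]]
        flags, counts = match_reciprocal(filtered, carried, frac=match_frac)
        n_calls += len(flags)
        n_false += counts["novel"]
        if carried:
            recovered, _ = match_reciprocal(carried, filtered, frac=match_frac)
            n_carried += len(carried)
            n_recovered += sum(recovered)

    popset = merge_population(per_sample_merged)

    realized_af = truth.realized_af()
    common_idx = np.where(realized_af > 0.05)[0]
    common_truth: list[SVCall] = [truth.svs[i] for i in common_idx]
    if common_truth:
        common_flags, _ = match_reciprocal(common_truth, popset, frac=match_frac)
        common_recall = 100.0 * sum(common_flags) / len(common_flags)
    else:
        common_recall = float("nan")

    metrics = {
        "n_calls": n_calls,
        "n_false": n_false,
        "fdr_pct": 100.0 * n_false / n_calls if n_calls else float("nan"),
        "carried_recall_pct": (
            100.0 * n_recovered / n_carried if n_carried else float("nan")
        ),
        "n_common_truth": len(common_truth),
        "common_recall_pct": common_recall,
        "n_nonredundant": len(popset),
        "category_counts": category_counts(popset),
    }
    return StudyResult(
        truth=truth,
        per_sample_merged=per_sample_merged,
        filter_reports=reports,
        popset=popset,
        metrics=metrics,
    )
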