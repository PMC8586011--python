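"""Population-level genotyping, nonredundant merging and allele-frequency
classification.

Genotypes are assigned from the variant allele balance (VAB = supporting
reads / site depth) with the 0.2 / 0.8 cut points: VAB <= 0.2 is 0/0,
0.2 < VAB <= 0.8 is 0/1, VAB > 0.8 is 1/1; a site with unknown or zero
depth is missing (./.).  Per-sample consensus calls are merged across
samples with the same CAST / reciprocal-overlap machinery used within
samples, the most common coordinates in the population become the
representative, and each site is classed as singleton (AC = 1), rare
(AC > 1 and AF <= 0.01), low (0.01 < AF <= 0.05) or common (AF > 0.05).

Samples contributing no call to a cluster are genotyped 0/0 (not missing):
the whole cohort enters every AF denominator; ./.  is reserved for
representatives whose site depth is unknown.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .merge import DEFAULT_AFFINITY_THRESHOLD, cast_cluster, partition_components
from .model import AF_CATEGORIES, MergedCall, PopulationSV, SVCall

VAB_HOMREF_MAX = 0.2
VAB_HET_MAX = 0.8


def genotype_from_vab(support_reads: int, site_depth: int | None) -> str:
    """Genotype one sample at one SV site from its allele balance."""
    if site_depth is None or site_depth == 0:
        return "./."
    if support_reads > site_depth:
        raise ValueError(
            f"support_reads {support_reads} exceeds site_depth {site_depth}"
        )
    vab = support_reads / site_depth
    if vab <= VAB_HOMREF_MAX:
        return "0/0"
    if vab <= VAB_HET_MAX:
        return "0/1"
    return "1/1"


def classify_af(ac: int, an: int) -> str:
    """Frequency category of a polymorphic site."""
    if ac == 0:
        raise ValueError("AC = 0: monomorphic-reference site has no category")
    if not 0 < ac <= an:
        raise ValueError(f"need 0 < AC <= AN, got AC={ac}, AN={an}")
    if ac == 1:
        return "singleton"
    af = ac / an
    if af <= 0.01:
        return "rare"
    if af <= 0.05:
        return "low"
    return "common"


_GT_ALT = {"0/0": 0, "0/1": 1, "1/1": 2}


def merge_population(
    per_sample: Mapping[str, Sequence[MergedCall]],
    threshold: float = DEFAULT_AFFINITY_THRESHOLD,
) -> list[PopulationSV]:
    """Merge per-sample consensus calls into a nonredundant population set.

    Cross-sample clustering reuses the within-sample CAST affinity and
    threshold.  The representative of a cluster is the member whose
    (start, svlen) pair occurs in the most samples (ties: higher support,
    then smaller start).  If a sample contributes two members to one
    cluster, the higher-support member is kept.
    """
    samples = sorted(per_sample)
    pooled: list[SVCall] = []
    for sample in samples:
        for mc in per_sample[sample]:
            pooled.append(mc.representative)

    by_key: dict[tuple[str, str], list[SVCall]] = defaultdict(list)
    for call in pooled:
        by_key[(call.chrom, call.sv_type)].append(call)

    popset: list[PopulationSV] = []
    for key in sorted(by_key):
        for group in partition_components(by_key[key]):
            for cluster in cast_cluster(group, threshold=threshold):
                popset.append(_summarize_cluster(cluster, samples))
    popset.sort(key=lambda s: (s.chrom, s.start, s.svlen))
    for i, sv in enumerate(popset):
        sv.sv_id = f"{sv.sv_type}_{sv.chrom}_{sv.start}_{i}"
    return popset


def _summarize_cluster(cluster: Sequence[SVCall], samples: list[str]) -> PopulationSV:
    # one member per sample: keep the higher-support one
    member_of: dict[str, SVCall] = {}
    for call in cluster:
        prev = member_of.get(call.sample_id)
        if prev is None or (call.support_reads, -call.start) > (
            prev.support_reads, -prev.start
        ):
            member_of[call.sample_id] = call

    coord_counts = Counter((c.start, c.svlen) for c in member_of.values())
    top = max(coord_counts.values())
    rep = min(
        (c for c in member_of.values() if coord_counts[(c.start, c.svlen)] == top),
        key=lambda c: (-c.support_reads, c.start),
    )

    genotypes: dict[str, str] = {}
    ac = 0
    n_called = 0
    for sample in samples:
        member = member_of.get(sample)
        if member is None:
            gt = "0/0"
        else:
            gt = genotype_from_vab(member.support_reads, member.site_depth)
        genotypes[sample] = gt
        if gt != "./.":
            n_called += 1
            ac += _GT_ALT[gt]
    an = 2 * n_called
    af = ac / an if an else 0.0
    return PopulationSV(
        sv_id="",
        representative=rep,
        genotypes=genotypes,
        AC=ac,
        AN=an,
        AF=af,
        MAF=min(af, 1 - af),
        category=classify_af(ac, an) if ac > 0 else None,
    )


def category_counts(popset: Sequence[PopulationSV]) -> dict[str, int]:
    """Number of population SVs per frequency category (AC = 0 sites are
    reported under ``unclassified``)."""
    counts = {cat: 0 for cat in AF_CATEGORIES}
    counts["unclassified"] = 0
    for sv in popset:
        counts[sv.category if sv.category else "unclassified"] += 1
    return counts


def subsample_curve(
    per_sample: Mapping[str, Sequence[MergedCall]],
    sizes: Sequence[int],
    reps: int = 4,
    seed: int = 0,
    threshold: float = DEFAULT_AFFINITY_THRESHOLD,
) -> pd.DataFrame:
    """SV-discovery curve: re-merge random sample subsets of increasing
    size and average the per-category nonredundant counts over replicates.

    Returns a DataFrame indexed by subset size with one column per
    frequency category (plus ``total``), each the mean over ``reps``
    random draws.
    """
    samples = sorted(per_sample)
    if max(sizes) > len(samples):
        raise ValueError(
            f"subset size {max(sizes)} exceeds {len(samples)} available samples"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        acc: Counter = Counter()
        for _ in range(reps):
            chosen = rng.choice(samples, size=size, replace=False)
            subset = {s: per_sample[s] for s in chosen}
            popset = merge_population(subset, threshold=threshold)
            counts = category_counts(popset)
            counts["total"] = len(popset)
            acc.update(counts)
        rows.append(
            {"size": size, **{k: acc[k] / reps for k in acc}}
        )
    return pd.DataFrame(rows).set_index("size")
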