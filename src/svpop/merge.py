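"""Within-sample multi-caller merging by reciprocal-overlap CAST clustering.

Calls from the three callers are pooled per SV type and chromosome,
segregated into non-overlapping groups (connected components of the
interval-intersection graph), and each group is clustered with the Cluster
Affinity Search Technique (CAST), using the reciprocal overlap of the two
intervals as the pairwise affinity with a 0.5 threshold.  A cluster whose
members span at least two distinct callers becomes one consensus SV; its
representative is chosen by caller priority (Sniffles, then NanoVar, then
NanoSV).

CAST is a greedy heuristic for clustering a "corrupted clique" graph: it
repeatedly opens a cluster seeded with the highest-degree unassigned node,
then alternately ADDs the outside element with maximal average affinity to
the cluster (if that average meets the threshold) and REMOVEs the member
with minimal average affinity (if below threshold), until stable.  The
add/remove order, seed choice and tie-breaking are fixed here for
determinism: ADD is evaluated before REMOVE; ties are broken by smaller
start, then longer svlen, then caller priority.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Callable, Sequence

import numpy as np

from .model import CALLER_PRIORITY, MergedCall, SVCall

log = logging.getLogger(__name__)

#: minimum mutual overlap for two calls to be considered the same SV
DEFAULT_AFFINITY_THRESHOLD = 0.5


def reciprocal_overlap(a: SVCall, b: SVCall) -> float:
    """Mutual overlap fraction of two calls: min(ov/len(a), ov/len(b)).

    0 when the calls are disjoint or differ in chromosome or type.  INS
    calls are compared on their synthetic intervals, so the affinity is
    sensitive to both position and inserted length.
    """
    if a.length <= 0 or b.length <= 0:
        raise ValueError("zero-length interval in reciprocal_overlap")
    if a.chrom != b.chrom or a.sv_type != b.sv_type:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def partition_components(svs: Sequence[SVCall]) -> list[list[SVCall]]:
    """Segregate calls into non-overlapping groups: the connected
    components of the graph whose edges join interval-intersecting pairs.

    Expects calls from a single chromosome and SV type.  Implemented as a
    sorted sweep (for interval graphs the components are exactly the
    maximal runs of intervals whose union is contiguous).
    """
    if not svs:
        return []
    order = sorted(range(len(svs)), key=lambda i: (svs[i].start, svs[i].end))
    groups: list[list[SVCall]] = []
    current = [svs[order[0]]]
    reach = svs[order[0]].end
    for i in order[1:]:
        sv = svs[i]
        if sv.start < reach:  # half-open: touching intervals do not intersect
            current.append(sv)
            reach = max(reach, sv.end)
        else:
            groups.append(current)
            current = [sv]
            reach = sv.end
    groups.append(current)
    return groups


def _tie_key(sv: SVCall) -> tuple:
    return (sv.start, -sv.svlen, CALLER_PRIORITY.get(sv.caller_id, 99))


def cast_cluster(
    group: Sequence[SVCall],
    threshold: float = DEFAULT_AFFINITY_THRESHOLD,
    affinity: Callable[[SVCall, SVCall], float] = reciprocal_overlap,
) -> list[list[SVCall]]:
    """CAST-cluster one non-overlapping group of calls.

    Returns a partition of ``group``; every cluster is internally ordered
    by the deterministic tie key.  An empty group yields an empty result.
    """
    n = len(group)
    if n == 0:
        return []
    if n == 1:
        return [[group[0]]]

    aff = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aff[i, j] = aff[j, i] = affinity(group[i], group[j])

    keys = [_tie_key(sv) for sv in group]
    unassigned = set(range(n))
    clusters: list[list[SVCall]] = []

    while unassigned:
        # seed: unassigned node with most above-threshold neighbours among
        # the unassigned; ties by (start, -svlen, caller priority)
        idx = sorted(unassigned)
        degree = {
            i: sum(1 for j in idx if j != i and aff[i, j] >= threshold)
            for i in idx
        }
        seed = min(idx, key=lambda i: (-degree[i], keys[i]))
        cluster = {seed}
        open_set = unassigned - {seed}

        max_iter = 4 * n * n + 16  # CAST can oscillate; bound the loop
        for _ in range(max_iter):
            changed = False
            # ADD is evaluated before REMOVE
            if open_set:
                means = {
                    u: sum(aff[u, c] for c in cluster) / len(cluster)
                    for u in open_set
                }
                best = min(open_set, key=lambda u: (-means[u], keys[u]))
                if means[best] >= threshold:
                    cluster.add(best)
                    open_set.remove(best)
                    changed = True
                    continue
            if len(cluster) > 1:
                means_in = {
                    m: sum(aff[m, c] for c in cluster if c != m) / (len(cluster) - 1)
                    for m in cluster
                }
                worst = min(cluster, key=lambda m: (means_in[m], keys[m]))
                if means_in[worst] < threshold:
                    cluster.remove(worst)
                    open_set.add(worst)
                    changed = True
                    continue
            if not changed:
                break

        clusters.append(sorted(cluster, key=lambda i: keys[i]))
        unassigned -= set(clusters[-1])

    clusters.sort(key=lambda c: keys[c[0]])
    return [[group[i] for i in c] for c in clusters]


def dedupe_calls(calls: Sequence[SVCall]) -> list[SVCall]:
    """Collapse exact duplicates (same caller, identical record)."""
    seen: set[SVCall] = set()
    out: list[SVCall] = []
    for call in calls:
        if call in seen:
            log.warning("duplicate record collapsed: %s %s:%d %s",
                        call.caller_id, call.chrom, call.start, call.sv_type)
            continue
        seen.add(call)
        out.append(call)
    return out


def select_representative(members: Sequence[SVCall]) -> SVCall:
    """Caller-priority representative: Sniffles first, then NanoVar, then
    NanoSV; within a caller prefer higher support, then smaller start."""
    return min(
        members,
        key=lambda m: (
            CALLER_PRIORITY.get(m.caller_id, 99),
            -m.support_reads,
            m.start,
            -m.svlen,
        ),
    )


def merge_within_sample(
    callsets: dict[str, list[SVCall]],
    min_callers: int = 2,
    threshold: float = DEFAULT_AFFINITY_THRESHOLD,
) -> list[MergedCall]:
    """Merge one sample's per-caller callsets into consensus SVs.

    Pools calls per (chromosome, type), partitions them into
    non-overlapping groups, CAST-clusters each group, and keeps clusters
    whose members come from at least ``min_callers`` distinct callers.
    """
    pooled = dedupe_calls([c for calls in callsets.values() for c in calls])
    by_key: dict[tuple[str, str], list[SVCall]] = defaultdict(list)
    for call in pooled:
        by_key[(call.chrom, call.sv_type)].append(call)

    merged: list[MergedCall] = []
    for key in sorted(by_key):
        for group in partition_components(by_key[key]):
            for cluster in cast_cluster(group, threshold=threshold):
                support = frozenset(m.caller_id for m in cluster)
                if len(support) < min_callers:
                    continue
                merged.append(
                    MergedCall(
                        representative=select_representative(cluster),
                        members=tuple(cluster),
                        caller_support=support,
                    )
                )
    merged.sort(key=lambda m: (m.chrom, m.start, m.svlen))
    return merged
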