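"""Comparison of SV sets: novelty against external reference datasets and
false-discovery-rate evaluation against a truth set.

Two SVs match when they have the same type and a reciprocal overlap
strictly larger than the fraction threshold (default 0.5) — note the
strict inequality here, versus the >= used when *merging* calls; both
conventions are kept and independently configurable.  INS records are
compared on their synthetic intervals (end = start + inserted length), so
reference insertions without a length must be excluded upstream (the TSV
reader does this).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from intervaltree import Interval, IntervalTree

from .model import MergedCall, PopulationSV, SVCall

DEFAULT_MATCH_FRACTION = 0.5


def _as_call(sv) -> SVCall:
    if isinstance(sv, SVCall):
        return sv
    if isinstance(sv, (PopulationSV, MergedCall)):
        return sv.representative
    raise TypeError(f"cannot interpret {type(sv).__name__} as an SV call")


def _build_index(calls: Sequence[SVCall]) -> dict[tuple[str, str], IntervalTree]:
    index: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for call in calls:
        index[(call.chrom, call.sv_type)].add(Interval(call.start, call.end, call))
    return index


def _matches(call: SVCall, index, frac: float) -> bool:
    tree = index.get((call.chrom, call.sv_type))
    if tree is None:
        return False
    for iv in tree.overlap(call.start, call.end):
        ov = min(call.end, iv.end) - max(call.start, iv.begin)
        if ov > 0 and min(ov / call.length, ov / iv.data.length) > frac:
            return True
    return False


def match_reciprocal(
    query: Sequence, ref: Sequence, frac: float = DEFAULT_MATCH_FRACTION
) -> tuple[list[bool], dict[str, int]]:
    """Flag each query SV as matched (same type, reciprocal overlap
    strictly > ``frac`` with some reference record) or novel.

    Returns the per-query flags plus {"matched": n, "novel": n}.
    """
    ref_calls = [_as_call(r) for r in ref]
    index = _build_index(ref_calls)
    flags = [_matches(_as_call(q), index, frac) for q in query]
    n_matched = sum(flags)
    return flags, {"matched": n_matched, "novel": len(flags) - n_matched}


def novelty_against(
    query: Sequence, refs: Sequence[Sequence], frac: float = DEFAULT_MATCH_FRACTION
) -> list[bool]:
    """Novel = unmatched against the *union* of all reference sets."""
    union = [_as_call(r) for ref in refs for r in ref]
    flags, _ = match_reciprocal(query, union, frac=frac)
    return [not f for f in flags]


def recall_rate(ref: Sequence, query: Sequence,
                frac: float = DEFAULT_MATCH_FRACTION) -> float:
    """Fraction of reference records recovered by the query set."""
    if not len(ref):
        raise ValueError("recall is undefined for an empty reference set")
    flags, counts = match_reciprocal(ref, query, frac=frac)
    return counts["matched"] / len(flags)


def fdr_from_counts(n_calls: int, n_false: int) -> float:
    """FDR as a percentage rounded to one decimal (e.g. 608 false of
    18,737 calls -> 3.2)."""
    if n_calls <= 0:
        raise ValueError("FDR is undefined for an empty callset")
    return round(100.0 * n_false / n_calls, 1)


def evaluate_fdr(
    calls: Sequence, truth: Sequence, frac: float = DEFAULT_MATCH_FRACTION
) -> dict:
    """False discovery rate of a callset against a truth set.

    FDR = (# calls unmatched in the truth set) / (# calls), overall and
    per SV type, each reported as a one-decimal percentage alongside the
    raw counts.
    """
    call_list = [_as_call(c) for c in calls]
    if not call_list:
        raise ValueError("FDR is undefined for an empty callset")
    flags, _ = match_reciprocal(call_list, truth, frac=frac)
    per_type_counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for call, matched in zip(call_list, flags):
        per_type_counts[call.sv_type][0] += 1
        if not matched:
            per_type_counts[call.sv_type][1] += 1
    n_false = sum(1 for f in flags if not f)
    return {
        "n_calls": len(call_list),
        "n_false": n_false,
        "fdr_pct": fdr_from_counts(len(call_list), n_false),
        "per_type": {
            t: {
                "n_calls": n,
                "n_false": f,
                "fdr_pct": fdr_from_counts(n, f),
            }
            for t, (n, f) in sorted(per_type_counts.items())
        },
    }
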