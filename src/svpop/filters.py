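"""Three-step quality filtering of merged calls.

The cascade removes, in order: (1) calls supported by too few reads, (2)
implausibly long calls (DEL/INS above 2 Mb, DUP/INV above 5 Mb) and calls
below the 50 bp SV definition, (3) calls intersecting excluded regions
(centromeres, assembly gaps, high-depth regions).  "Intersects" means any
1 bp overlap, the BEDTools default.  The three filters commute; the
cascade order only determines how removals are attributed in the report.
"""

from __future__ import annotations

from typing import Sequence

from intervaltree import IntervalTree

from .model import FilterReport, MergedCall, RegionMask

MAX_DEL_INS_BP = 2_000_000
MAX_DUP_INV_BP = 5_000_000
MIN_SV_BP = 50
DEFAULT_MIN_READS = 3


def filter_support(
    calls: Sequence[MergedCall],
    min_reads: int = DEFAULT_MIN_READS,
    depth_ratio: float | None = None,
    mean_depth: float | None = None,
) -> list[MergedCall]:
    """Keep calls whose representative is supported by enough reads.

    With ``depth_ratio`` set, the threshold scales with sequencing depth
    instead of being fixed: threshold = round(depth_ratio * mean_depth)
    (a ratio of 0.2 equals 3 supporting reads at 15-fold depth).  Used for
    depth-titration experiments; the production setting is the fixed
    ``min_reads = 3``.
    """
    if depth_ratio is not None:
        if mean_depth is None:
            raise ValueError("depth_ratio requires mean_depth")
        min_reads = round(depth_ratio * mean_depth)
    return [c for c in calls if c.support_reads >= min_reads]


def filter_length(
    calls: Sequence[MergedCall],
    max_del_ins: int = MAX_DEL_INS_BP,
    max_dup_inv: int = MAX_DUP_INV_BP,
    min_len: int = MIN_SV_BP,
) -> list[MergedCall]:
    """Drop DEL/INS longer than 2 Mb, DUP/INV longer than 5 Mb, and any
    call shorter than the 50 bp SV definition."""
    out = []
    for c in calls:
        if c.svlen < min_len:
            continue
        cap = max_del_ins if c.sv_type in ("DEL", "INS") else max_dup_inv
        if c.svlen > cap:
            continue
        out.append(c)
    return out


def build_mask_index(masks: Sequence[RegionMask]) -> dict[str, IntervalTree]:
    """Per-chromosome interval index over the union of all masks."""
    index: dict[str, IntervalTree] = {}
    for mask in masks:
        for chrom, start, end in mask.intervals:
            index.setdefault(chrom, IntervalTree()).addi(start, end)
    return index


def filter_regions(
    calls: Sequence[MergedCall],
    masks: Sequence[RegionMask] | dict[str, IntervalTree],
) -> list[MergedCall]:
    """Drop calls whose interval (INS: synthetic interval) overlaps any
    mask interval by at least 1 bp.  Mask chromosomes absent from the
    calls are simply never consulted."""
    index = masks if isinstance(masks, dict) else build_mask_index(masks)
    out = []
    for c in calls:
        tree = index.get(c.chrom)
        if tree is not None and tree.overlaps(c.start, c.end):
            continue
        out.append(c)
    return out


def apply_filters(
    calls: Sequence[MergedCall],
    masks: Sequence[RegionMask] = (),
    min_reads: int = DEFAULT_MIN_READS,
    depth_ratio: float | None = None,
    mean_depth: float | None = None,
) -> tuple[list[MergedCall], FilterReport]:
    """Run the full cascade and account for removals per step."""
    n_input = len(calls)
    after_support = filter_support(
        calls, min_reads=min_reads, depth_ratio=depth_ratio, mean_depth=mean_depth
    )
    after_length = filter_length(after_support)
    after_region = filter_regions(after_length, masks)
    report = FilterReport(
        n_input=n_input,
        n_after_support=len(after_support),
        n_after_length=len(after_length),
        n_after_region=len(after_region),
    )
    return after_region, report
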