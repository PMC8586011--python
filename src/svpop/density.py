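"""Meta-chromosome SV density.

Chromosome arms are rescaled onto a common 0-2 coordinate: 0 is the p-arm
telomere, 1 the centromere, 2 the q-arm telomere.  SV positions (interval
midpoints) are normalized per arm, and counts are taken in overlapping
sliding windows (100 kb window, 50 kb step by default) whose centers are
reported on the normalized scale, so profiles aggregate across
chromosomes of different lengths.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import SVCall

#: per-chromosome arm definition: (p_start, centromere_start,
#: centromere_end, q_end), 0-based half-open
ArmTable = Mapping[str, tuple[int, int, int, int]]

DEFAULT_WINDOW_BP = 100_000
DEFAULT_STEP_BP = 50_000


def _midpoint(sv: SVCall) -> float:
    return (sv.start + sv.end) / 2.0


def meta_position(sv: SVCall, arms: ArmTable) -> float:
    """Normalized 0-2 arm coordinate of an SV's midpoint.

    Raises for midpoints inside the centromere — centromeric SVs are
    removed by the region filter upstream.
    """
    try:
        p_start, cen_start, cen_end, q_end = arms[sv.chrom]
    except KeyError:
        raise KeyError(f"no arm definition for chromosome {sv.chrom!r}") from None
    mid = _midpoint(sv)
    if mid < cen_start:
        return (mid - p_start) / (cen_start - p_start)
    if mid >= cen_end:
        return 1.0 + (mid - cen_end) / (q_end - cen_end)
    raise ValueError(
        f"SV midpoint {mid} of {sv.chrom}:{sv.start}-{sv.end} lies in the "
        "centromere; filter centromeric SVs before computing density"
    )


def density_profile(
    svs: Sequence[SVCall],
    arms: ArmTable,
    window: int = DEFAULT_WINDOW_BP,
    step: int = DEFAULT_STEP_BP,
) -> pd.DataFrame:
    """Sliding-window SV counts per arm, with normalized window centers.

    Returns one row per (chromosome, arm, window) with per-type counts and
    the window center on the 0-2 meta-chromosome scale.  Counting is by
    interval midpoint.  With ``step == window`` the windows tile the arm
    and their counts sum to the number of SVs on it.
    """
    by_chrom: dict[str, list[SVCall]] = {}
    for sv in svs:
        by_chrom.setdefault(sv.chrom, []).append(sv)

    sv_types = sorted({sv.sv_type for sv in svs}) or ["DEL", "INS", "DUP", "INV"]
    rows = []
    for chrom, (p_start, cen_start, cen_end, q_end) in sorted(arms.items()):
        mids = np.array([_midpoint(sv) for sv in by_chrom.get(chrom, [])])
        types = np.array([sv.sv_type for sv in by_chrom.get(chrom, [])])
        for arm, (a_start, a_end) in (
            ("p", (p_start, cen_start)),
            ("q", (cen_end, q_end)),
        ):
            arm_len = a_end - a_start
            if arm_len <= 0:
                continue
            for w_start in range(a_start, a_end, step):
                w_end = min(w_start + window, a_end)
                center = (w_start + w_end) / 2.0
                norm = (center - a_start) / arm_len
                norm_center = norm if arm == "p" else 1.0 + norm
                in_win = (mids >= w_start) & (mids < w_end) if mids.size else \
                    np.zeros(0, bool)
                row = {
                    "chrom": chrom,
                    "arm": arm,
                    "win_start": w_start,
                    "win_end": w_end,
                    "norm_center": norm_center,
                    "total": int(in_win.sum()),
                }
                for t in sv_types:
                    row[t] = int((in_win & (types == t)).sum()) if mids.size else 0
                rows.append(row)
    return pd.DataFrame(rows)


def aggregate_profile(profile: pd.DataFrame, n_bins: int = 40) -> pd.DataFrame:
    """Sum window counts across chromosomes onto a fixed grid of
    ``n_bins`` equal bins per arm unit of the 0-2 scale."""
    if profile.empty:
        edges = np.linspace(0, 2, 2 * n_bins + 1)
        return pd.DataFrame({
            "bin_center": (edges[:-1] + edges[1:]) / 2, "total": 0,
        })
    width = 1.0 / n_bins
    binned = profile.copy()
    binned["bin"] = np.minimum(
        (binned["norm_center"] / width).astype(int), 2 * n_bins - 1
    )
    count_cols = [c for c in profile.columns
                  if c not in ("chrom", "arm", "win_start", "win_end",
                               "norm_center")]
    agg = binned.groupby("bin")[count_cols].sum().reindex(
        range(2 * n_bins), fill_value=0
    )
    agg.insert(0, "bin_center", (agg.index + 0.5) * width)
    return agg.reset_index(drop=True)
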