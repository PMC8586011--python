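"""Population-differentiation statistics on the SV genotype matrix.

Per-site F_ST uses the Hudson (1992) estimator with sample-size
correction (the default of PBS-scanning tools); the population branch
statistic for focal population A against sister B and outgroup C is

    PBS_A = [ -ln(1 - F_ST(A,B)) - ln(1 - F_ST(A,C)) + ln(1 - F_ST(B,C)) ] / 2,

clamped at 0.  A genome scan keeps sites with pooled MAF above a cutoff,
marks sites above the empirical 99.9% rank of the focal-branch scores,
and chains above-threshold sites within 1 Mb of each other into
independent signals.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def hudson_fst(ac1: int, an1: int, ac2: int, an2: int,
               clamp: bool = True) -> float:
    """Hudson's F_ST estimator for one site from allele counts.

    numerator   (p1-p2)^2 - p1(1-p1)/(an1-1) - p2(1-p2)/(an2-1)
    denominator p1(1-p2) + p2(1-p1)

    Negative estimates are clamped to 0 unless ``clamp=False`` (the raw
    value is the unbiased choice when averaging over many sites).  A zero
    denominator (both populations fixed) yields NaN.
    """
    if an1 < 2 or an2 < 2:
        raise ValueError("Hudson F_ST needs at least 2 alleles per population")
    p1, p2 = ac1 / an1, ac2 / an2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (an1 - 1) - p2 * (1 - p2) / (an2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0:
        return float("nan")
    fst = num / den
    if clamp:
        fst = min(max(fst, 0.0), np.nextafter(1.0, 0.0))
    return fst


def hudson_fst_arrays(ac1, an1, ac2, an2, clamp: bool = True) -> np.ndarray:
    """Vectorized :func:`hudson_fst` over arrays of allele counts."""
    ac1, an1 = np.asarray(ac1, float), np.asarray(an1, float)
    ac2, an2 = np.asarray(ac2, float), np.asarray(an2, float)
    if np.any(an1 < 2) or np.any(an2 < 2):
        raise ValueError("Hudson F_ST needs at least 2 alleles per population")
    p1, p2 = ac1 / an1, ac2 / an2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (an1 - 1) - p2 * (1 - p2) / (an2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if clamp:
        fst = np.clip(fst, 0.0, np.nextafter(1.0, 0.0))
    return fst


def hudson_fst_genome(ac1, an1, ac2, an2) -> tuple[float, float]:
    """Multi-site Hudson F_ST as the ratio of summed numerators to summed
    denominators (the recommended way to combine sites — averaging
    per-site ratios is biased), with a leave-one-site-out jackknife
    standard error.

    Returns (estimate, standard error).
    """
    ac1, an1 = np.asarray(ac1, float), np.asarray(an1, float)
    ac2, an2 = np.asarray(ac2, float), np.asarray(an2, float)
    if np.any(an1 < 2) or np.any(an2 < 2):
        raise ValueError("Hudson F_ST needs at least 2 alleles per population")
    p1, p2 = ac1 / an1, ac2 / an2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (an1 - 1) - p2 * (1 - p2) / (an2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    total_num, total_den = num.sum(), den.sum()
    if total_den == 0:
        raise ValueError("all sites fixed in both populations")
    est = total_num / total_den
    loo = (total_num - num) / (total_den - den)
    m = len(num)
    se = float(np.sqrt((m - 1) / m * ((loo - loo.mean()) ** 2).sum()))
    return float(est), se


def pbs(fst_ab: float, fst_ac: float, fst_bc: float) -> float:
    """Population branch statistic for the focal branch A, clamped at 0.

    Symmetric in the two F_ST values involving A, and (pre-clamp)
    increasing in both of them and decreasing in F_ST(B, C).
    """
    for f in (fst_ab, fst_ac, fst_bc):
        if not 0 <= f < 1:
            raise ValueError(f"F_ST values must lie in [0, 1), got {f}")
    val = (-np.log1p(-fst_ab) - np.log1p(-fst_ac) + np.log1p(-fst_bc)) / 2
    return max(0.0, float(val))


def _group_counts(genotypes: pd.DataFrame, members: Sequence[str]):
    sub = genotypes.loc[list(members)]
    ac = sub.sum(axis=0).to_numpy(float)
    an = 2.0 * sub.notna().sum(axis=0).to_numpy(float)
    return ac, an


def pbs_scan(
    genotypes: pd.DataFrame,
    sites: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    focal: str,
    sister: str,
    outgroup: str,
    maf_min: float = 0.01,
    rank: float = 0.999,
    merge_bp: int = 1_000_000,
) -> tuple[pd.DataFrame, float]:
    """PBS genome scan over a samples x sites genotype matrix (0/1/2).

    ``sites`` must carry ``chrom`` and ``pos`` columns aligned with the
    genotype columns.  Sites with pooled MAF <= ``maf_min`` are dropped;
    the threshold is the empirical ``rank`` quantile of the focal-branch
    scores (NaN scores excluded); above-threshold sites on one chromosome
    within ``merge_bp`` of each other share a ``signal_id``.

    Returns (records, threshold).
    """
    for name in (focal, sister, outgroup):
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")

    ac_a, an_a = _group_counts(genotypes, groups[focal])
    ac_b, an_b = _group_counts(genotypes, groups[sister])
    ac_c, an_c = _group_counts(genotypes, groups[outgroup])

    ac_all = ac_a + ac_b + ac_c
    an_all = an_a + an_b + an_c
    with np.errstate(invalid="ignore"):
        af = ac_all / an_all
    maf = np.minimum(af, 1 - af)
    keep = maf > maf_min

    fst_ab = hudson_fst_arrays(ac_a[keep], an_a[keep], ac_b[keep], an_b[keep])
    fst_ac = hudson_fst_arrays(ac_a[keep], an_a[keep], ac_c[keep], an_c[keep])
    fst_bc = hudson_fst_arrays(ac_b[keep], an_b[keep], ac_c[keep], an_c[keep])

    with np.errstate(invalid="ignore"):
        scores = (
            -np.log1p(-fst_ab) - np.log1p(-fst_ac) + np.log1p(-fst_bc)
        ) / 2
    scores = np.where(np.isnan(scores), np.nan, np.maximum(scores, 0.0))

    valid = ~np.isnan(scores)
    if not valid.any():
        raise ValueError("no valid PBS scores (all sites fixed or filtered)")
    threshold = float(np.quantile(scores[valid], rank))

    records = sites.loc[keep, ["chrom", "pos"]].reset_index()
    records = records.rename(columns={"index": "sv_id"})
    records["p_focal"] = ac_a[keep] / an_a[keep]
    records["p_sister"] = ac_b[keep] / an_b[keep]
    records["p_outgroup"] = ac_c[keep] / an_c[keep]
    records["fst_ab"] = fst_ab
    records["fst_ac"] = fst_ac
    records["fst_bc"] = fst_bc
    records["pbs"] = scores
    records["above_threshold"] = valid & (scores > threshold)
    records["signal_id"] = _assign_signals(records, merge_bp)
    return records, threshold


def _assign_signals(records: pd.DataFrame, merge_bp: int) -> pd.Series:
    signal = pd.Series(pd.NA, index=records.index, dtype="Int64")
    above = records[records["above_threshold"]].sort_values(["chrom", "pos"])
    current = -1
    prev_chrom, prev_pos = None, None
    for idx, row in above.iterrows():
        if row["chrom"] != prev_chrom or row["pos"] - prev_pos > merge_bp:
            current += 1
        signal.loc[idx] = current
        prev_chrom, prev_pos = row["chrom"], row["pos"]
    return signal


def ibs_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Identity-by-state similarity between samples.

    ``genotypes`` is samples x sites coded 0/1/2;
    IBS(i, j) = mean over sites of (2 - |g_i - g_j|) / 2; diagonal 1.
    """
    g = np.asarray(genotypes, float)
    if np.isnan(g).any():
        raise ValueError("ibs_matrix expects complete genotypes")
    n = g.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        diff = np.abs(g[i] - g[i + 1:])  # vectorized over the lower block
        if diff.size:
            out[i, i + 1:] = out[i + 1:, i] = ((2.0 - diff) / 2.0).mean(axis=1)
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / n_tests, reported to two
    significant figures (e.g. 0.05 / 29,510 -> 1.7e-6)."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    return float(f"{alpha / n_tests:.1e}")
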