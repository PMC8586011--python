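"""Seedable simulator of truth SV populations and imperfect caller output.

The generator produces, in order: a toy genome (chromosomes with a
centromere, assembly gaps, a high-depth region and non-overlapping
protein-coding genes), a truth population of SV loci with realistic type
mix and length distribution, per-sample genotypes under an (optionally
structured) allele-frequency model, and per-sample callsets from three
emulated long-read callers with breakpoint jitter, per-type sensitivity,
read-support sampling and false positives.

Study conditions baked into the defaults:

* type mix DEL/INS/DUP/INV = 0.444 / 0.538 / 0.014 / 0.004;
* DEL/INS lengths from a four-component mixture (lognormal body with
  median ~120 bp, an Alu-like peak at ~300 bp, a LINE-like peak at ~6 kb,
  and a long lognormal tail) with weights 0.55 / 0.35 / 0.07 / 0.03 —
  weights chosen to reproduce the two characteristic peaks; DUPs and INVs
  from longer lognormals (medians ~1 kb and ~5.5 kb);
* a singleton-heavy site-frequency spectrum from Beta(0.3, 2.0) ancestral
  frequencies, truncated to allele count >= 1;
* subpopulation divergence under the Balding-Nichols model: subpopulation
  frequency p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F), genotypes ~ Binomial(2, p_k);
* mean sequencing depth 15-fold; supporting reads ~ Binomial(depth, 0.5)
  for heterozygotes and Binomial(depth, 1.0) for homozygotes;
* three caller profiles with sensitivities 0.95 / 0.90 / 0.85, breakpoint
  jitter SD 10 / 20 / 30 bp and false-call rates 300 / 500 / 800 per
  genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import SV_TYPES, GeneModel, RegionMask, SVCall

DEFAULT_TYPE_MIX: dict[str, float] = {
    "DEL": 0.444, "INS": 0.538, "DUP": 0.014, "INV": 0.004,
}

#: DEL/INS length mixture: (weight, sampler family, params)
LENGTH_MIXTURE = (
    (0.55, "lognormal", (np.log(120.0), 1.0)),   # short-indel body
    (0.35, "normal", (300.0, 30.0)),             # Alu-like peak
    (0.07, "normal", (6000.0, 600.0)),           # LINE-like peak
    (0.03, "lognormal", (np.log(20000.0), 1.0)),  # long tail
)


@dataclass(slots=True)
class SimGenome:
    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    masks: list[RegionMask]
    arms: dict[str, tuple[int, int, int, int]]


@dataclass(slots=True)
class SimParams:
    n_samples: int = 50
    n_svs: int = 5000
    type_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    sfs_beta: tuple[float, float] = (0.3, 2.0)
    #: (group name, group size, Balding-Nichols F); None = panmictic
    subpops: list[tuple[str, int, float]] | None = None
    depth: float = 15.0
    #: cap on simulated SV length; the length mixture's extreme tail
    #: cannot be placed on megabase-scale toy chromosomes
    max_sv_len: int = 100_000
    #: number of DEL loci planted over a CDS (labelled pLoF in the truth)
    n_plof: int = 0
    #: loci where the first group's divergence is raised to planted_f
    n_planted_high_f: int = 0
    planted_f: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.type_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"type_mix sums to {total}, expected 1")
        if self.subpops is not None:
            for _, n, f in self.subpops:
                if not 0 <= f < 1:
                    raise ValueError(f"Balding-Nichols F must be in [0,1), got {f}")
            if sum(n for _, n, _ in self.subpops) != self.n_samples:
                raise ValueError("subpop sizes must sum to n_samples")


@dataclass(slots=True)
class CallerProfile:
    caller_id: str
    #: detection probability, scalar or per SV type
    sensitivity: float | dict[str, float] = 0.95
    breakpoint_jitter_sd: float = 10.0
    length_jitter_cv: float = 0.03
    #: expected false calls per genome (Poisson)
    fp_rate: float = 300.0
    het_p: float = 0.5
    hom_p: float = 1.0

    def sens(self, sv_type: str) -> float:
        if isinstance(self.sensitivity, dict):
            return self.sensitivity.get(sv_type, 1.0)
        return self.sensitivity


DEFAULT_PROFILES: tuple[CallerProfile, ...] = (
    CallerProfile("sniffles", 0.95, 10.0, 0.03, 300.0),
    CallerProfile("nanovar", 0.90, 20.0, 0.05, 500.0),
    CallerProfile("nanosv", 0.85, 30.0, 0.08, 800.0),
)

NOISE_FREE_PROFILES: tuple[CallerProfile, ...] = (
    CallerProfile("sniffles", 1.0, 0.0, 0.0, 0.0),
    CallerProfile("nanovar", 1.0, 0.0, 0.0, 0.0),
    CallerProfile("nanosv", 1.0, 0.0, 0.0, 0.0),
)


@dataclass(slots=True)
class SimTruth:
    genome: SimGenome
    params: SimParams
    svs: list[SVCall]
    af_global: np.ndarray
    subpop_af: dict[str, np.ndarray]
    #: samples x loci genotype matrix (0/1/2)
    genotypes: pd.DataFrame
    plof_planted: np.ndarray
    high_f_planted: np.ndarray
    sample_groups: dict[str, list[str]]

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes.index)

    def realized_af(self) -> np.ndarray:
        """Allele frequency realized in the sampled genotypes."""
        n = len(self.genotypes)
        return self.genotypes.to_numpy().sum(axis=0) / (2.0 * n)


def simulate_genome(
    n_chroms: int = 3,
    chrom_len: int = 10_000_000,
    n_genes: int = 60,
    centromere_frac: float = 0.1,
    seed: int = 0,
) -> SimGenome:
    """Toy genome: equal-length chromosomes, centered centromeres, a few
    gap and high-depth mask intervals, and non-overlapping genes with
    UTR-CDS-intron-CDS-UTR structure placed clear of all masks."""
    if chrom_len < 1_000_000:
        raise ValueError("chromosomes must be at least 1 Mb")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_lengths = {c: chrom_len for c in chroms}

    cen_len = int(chrom_len * centromere_frac)
    centromeres, gaps, highdepth, arms = [], [], [], {}
    for chrom in chroms:
        cen_start = (chrom_len - cen_len) // 2
        centromeres.append((chrom, cen_start, cen_start + cen_len))
        arms[chrom] = (0, cen_start, cen_start + cen_len, chrom_len)
        for _ in range(2):
            g_len = int(rng.integers(10_000, 30_000))
            side = rng.random() < 0.5
            lo, hi = (50_000, cen_start - g_len - 50_000) if side else \
                (cen_start + cen_len + 50_000, chrom_len - g_len - 50_000)
            g_start = int(rng.integers(lo, hi))
            gaps.append((chrom, g_start, g_start + g_len))
        h_len = int(rng.integers(5_000, 15_000))
        h_start = int(rng.integers(cen_start + cen_len + 50_000,
                                   chrom_len - h_len - 50_000))
        highdepth.append((chrom, h_start, h_start + h_len))

    masks = [
        RegionMask("centromere", centromeres),
        RegionMask("gap", gaps),
        RegionMask("highdepth", highdepth),
    ]
    mask_trees: dict[str, IntervalTree] = {}
    for m in masks:
        for chrom, s, e in m.intervals:
            mask_trees.setdefault(chrom, IntervalTree()).addi(s, e)

    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(n_genes / n_chroms))
    gene_no = 0
    for chrom in chroms:
        anchors = np.linspace(100_000, chrom_len - 150_000,
                              per_chrom, dtype=int)
        for anchor in anchors:
            if gene_no >= n_genes:
                break
            utr5_len = 200
            cds1 = int(rng.integers(300, 900))
            intron = int(rng.integers(500, 3000))
            cds2 = int(rng.integers(300, 900))
            utr3_len = 300
            span = utr5_len + cds1 + intron + cds2 + utr3_len
            start = int(anchor)
            end = start + span
            # genes (and their 1 kb promoters) must stay clear of masks
            if mask_trees[chrom].overlaps(start - 1_100, end + 1_100):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            p0 = start
            utr5 = [(p0, p0 + utr5_len)]
            c1 = (p0 + utr5_len, p0 + utr5_len + cds1)
            c2 = (c1[1] + intron, c1[1] + intron + cds2)
            utr3 = [(c2[1], end)]
            if strand == "-":
                utr5, utr3 = utr3, utr5
            genes.append(
                GeneModel(
                    gene_id=f"GENE{gene_no:04d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    cds=[c1, c2],
                    utr5=utr5,
                    utr3=utr3,
                )
            )
            gene_no += 1
    return SimGenome(chrom_lengths, genes, masks, arms)


def _sample_del_ins_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    weights = np.array([w for w, _, _ in LENGTH_MIXTURE])
    comp = rng.choice(len(LENGTH_MIXTURE), size=n, p=weights / weights.sum())
    out = np.empty(n)
    for k, (_, family, (a, b)) in enumerate(LENGTH_MIXTURE):
        mask = comp == k
        m = int(mask.sum())
        if not m:
            continue
        if family == "lognormal":
            out[mask] = rng.lognormal(a, b, size=m)
        else:
            out[mask] = rng.normal(a, b, size=m)
    return np.clip(np.round(out), 50, 2_000_000).astype(int)


def sample_sv_lengths(rng: np.random.Generator, sv_types: np.ndarray) -> np.ndarray:
    """Lengths for an array of SV types under the default length models."""
    n = len(sv_types)
    out = np.empty(n, dtype=int)
    di = np.isin(sv_types, ("DEL", "INS"))
    out[di] = _sample_del_ins_lengths(rng, int(di.sum()))
    dup = sv_types == "DUP"
    out[dup] = np.clip(
        np.round(rng.lognormal(np.log(1000.0), 0.9, int(dup.sum()))),
        50, 5_000_000).astype(int)
    inv = sv_types == "INV"
    out[inv] = np.clip(
        np.round(rng.lognormal(np.log(5500.0), 0.8, int(inv.sum()))),
        50, 5_000_000).astype(int)
    return out


def _forbidden_trees(
    genome: SimGenome,
) -> tuple[dict[str, IntervalTree], dict[str, IntervalTree]]:
    """(mask-only, mask + padded-gene) per-chromosome exclusion trees."""
    mask_trees: dict[str, IntervalTree] = {c: IntervalTree()
                                           for c in genome.chrom_lengths}
    for m in genome.masks:
        for chrom, s, e in m.intervals:
            mask_trees[chrom].addi(s, e)
    full_trees = {c: IntervalTree(t) for c, t in mask_trees.items()}
    for g in genome.genes:
        ps, pe = g.promoter
        full_trees[g.chrom].addi(min(g.start, ps) - 100, max(g.end, pe) + 100)
    return mask_trees, full_trees


def _subpop_freqs(rng: np.random.Generator, af: np.ndarray,
                  f: float) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies around ancestral ``af``."""
    if f <= 0:
        return af.copy()
    return rng.beta(af * (1 - f) / f, (1 - af) * (1 - f) / f)


def _planted_shift(rng: np.random.Generator, af: np.ndarray,
                   fst_target: float) -> np.ndarray:
    """Deterministically shifted focal frequency whose per-locus Hudson
    F_ST against an undiverged population at frequency ``af`` equals
    ``fst_target``.

    Solving (q-p)^2 = F * [p(1-q) + q(1-p)] for q = p + d gives
    d = [F(1-2p) + sqrt(F^2 (1-2p)^2 + 8 F p(1-p))] / 2; the shift points
    toward the farther allele-frequency boundary (random for p = 0.5) so
    clipping cannot erode the planted divergence.
    """

    def up_shift(p: np.ndarray) -> np.ndarray:
        b = fst_target * (1 - 2 * p)
        return (b + np.sqrt(b * b + 8 * fst_target * p * (1 - p))) / 2

    sign_up = np.where(af == 0.5, rng.random(af.size) < 0.5, af < 0.5)
    shifted = np.where(sign_up, af + up_shift(af), af - up_shift(1 - af))
    return np.clip(shifted, 0.01, 0.99)


def simulate_population(params: SimParams, genome: SimGenome) -> SimTruth:
    """Draw a truth SV population over a simulated genome.

    Loci never overlap each other or the masks.  When ``n_plof`` > 0,
    that many DEL loci are placed over a CDS and flagged as planted pLoF;
    all other loci avoid gene bodies and promoters entirely, so planted
    flags are the complete ground truth for coding impact.
    """
    rng = np.random.default_rng(params.seed)
    types = np.array(sorted(params.type_mix))
    probs = np.array([params.type_mix[t] for t in types])
    sv_types = rng.choice(types, size=params.n_svs, p=probs)
    if params.n_plof:
        if not genome.genes:
            raise ValueError("n_plof > 0 needs a genome with genes")
        sv_types[:params.n_plof] = "DEL"
    lengths = np.minimum(sample_sv_lengths(rng, sv_types), params.max_sv_len)

    mask_trees, forbidden = _forbidden_trees(genome)
    occupied: dict[str, IntervalTree] = {c: IntervalTree()
                                         for c in genome.chrom_lengths}
    chroms = sorted(genome.chrom_lengths)
    chrom_probs = np.array([genome.chrom_lengths[c] for c in chroms], float)
    chrom_probs /= chrom_probs.sum()

    margin = 200  # keeps jittered calls from bridging adjacent loci
    placed_svs: dict[int, SVCall] = {}
    plof_planted = np.zeros(params.n_svs, bool)
    # place planted pLoF loci first, then the rest longest-first (long SVs
    # cannot find room once the genome is densely occupied)
    order = list(range(params.n_plof)) + sorted(
        range(params.n_plof, params.n_svs), key=lambda i: -lengths[i]
    )
    for i in order:
        length = int(lengths[i])
        placed = False
        if i < params.n_plof:
            length = min(length, 2000)  # keep planted DELs intragenic-scale
        for _ in range(200):
            if i < params.n_plof:
                gene = genome.genes[int(rng.integers(len(genome.genes)))]
                cds_s, cds_e = gene.cds[int(rng.integers(len(gene.cds)))]
                lo = max(0, cds_s - length + 1)
                start = int(rng.integers(lo, cds_e))
                chrom = gene.chrom
            else:
                chrom = str(rng.choice(chroms, p=chrom_probs))
                hi = genome.chrom_lengths[chrom] - length - margin
                if hi <= margin:
                    break
                start = int(rng.integers(margin, hi))
            end = start + length
            if occupied[chrom].overlaps(start - margin, end + margin):
                continue
            if i >= params.n_plof and forbidden[chrom].overlaps(start, end):
                continue
            if i < params.n_plof and mask_trees[chrom].overlaps(start, end):
                continue
            occupied[chrom].addi(start - margin, end + margin)
            placed_svs[i] = SVCall(
                sample_id="truth",
                caller_id="truth",
                sv_type=str(sv_types[i]),
                chrom=chrom,
                start=start,
                end=end,
                svlen=length,
            )
            plof_planted[i] = i < params.n_plof
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place SV {i} of {params.n_svs}: genome too crowded"
            )
    svs = [placed_svs[i] for i in range(params.n_svs)]

    n = params.n_svs
    a, b = params.sfs_beta
    # the rarest representable frequency scales with the cohort: a quarter
    # allele in 2N chromosomes keeps conditioning on segregation fast while
    # preserving the singleton-heavy tail of the spectrum
    af_floor = max(1.0 / (4 * params.n_samples), 1e-4)
    af = rng.beta(a, b, size=n)
    af = np.clip(af, af_floor, 0.999)

    high_f = np.zeros(n, bool)
    if params.n_planted_high_f:
        if params.subpops is None:
            raise ValueError("planted high-F loci need subpopulations")
        candidates = np.where((af > 0.2) & (af < 0.8))[0]
        chosen = rng.choice(candidates, size=params.n_planted_high_f,
                            replace=False)
        high_f[chosen] = True

    subpops = params.subpops or [("pop", params.n_samples, 0.0)]
    sample_groups: dict[str, list[str]] = {}
    subpop_af: dict[str, np.ndarray] = {}
    geno_blocks = []
    sample_names = []
    for g_idx, (group, size, f) in enumerate(subpops):
        p_k = _subpop_freqs(rng, af, f)
        if g_idx == 0 and high_f.any():
            p_k[high_f] = _planted_shift(rng, af[high_f], params.planted_f)
        subpop_af[group] = p_k
        names = [f"{group}{j:03d}" for j in range(size)]
        sample_groups[group] = names
        sample_names.extend(names)
        geno_blocks.append(rng.binomial(2, p_k, size=(size, n)))
    genotypes = np.vstack(geno_blocks)

    # truncate the SFS to segregating sites: condition AC = 0 loci on
    # segregation by redrawing their subpopulation frequencies and
    # genotypes (the ancestral frequency stays fixed, so the
    # singleton-heavy tail of the spectrum is preserved)
    for _ in range(5000):
        ac = genotypes.sum(axis=0)
        zero = np.where(ac == 0)[0]
        if not zero.size:
            break
        offset = 0
        for g_idx, (group, size, f) in enumerate(subpops):
            p_sub = _subpop_freqs(rng, af[zero], f)
            planted_here = high_f[zero]
            if g_idx == 0 and planted_here.any():
                p_sub[planted_here] = _planted_shift(
                    rng, af[zero][planted_here], params.planted_f)
            subpop_af[group][zero] = p_sub
            genotypes[offset:offset + size, zero] = rng.binomial(
                2, p_sub, size=(size, zero.size))
            offset += size
    else:
        raise RuntimeError("failed to make all loci segregating")

    sv_ids = [f"sv{i:05d}" for i in range(n)]
    geno_df = pd.DataFrame(genotypes, index=sample_names, columns=sv_ids)
    return SimTruth(
        genome=genome,
        params=params,
        svs=svs,
        af_global=af,
        subpop_af=subpop_af,
        genotypes=geno_df,
        plof_planted=plof_planted,
        high_f_planted=high_f,
        sample_groups=sample_groups,
    )


def simulate_caller_calls(
    truth: SimTruth,
    profile: CallerProfile,
    seed: int,
) -> dict[str, list[SVCall]]:
    """Emulate one caller over every sample of a truth population.

    For each carrier of each truth SV the call is emitted with the
    profile's per-type sensitivity, its breakpoint jittered by a rounded
    normal and its length by a multiplicative normal factor; supporting
    reads are Binomial(site depth, 0.5 | 1.0) for het | hom.  False calls
    are Poisson per genome, placed at least twice the longest truth SV
    away from every truth locus.  Fully deterministic given the seed.
    """
    caller_idx = {"sniffles": 1, "nanovar": 2, "nanosv": 3}.get(
        profile.caller_id, 9)
    genome = truth.genome
    geno = truth.genotypes.to_numpy()
    n_sv = len(truth.svs)
    starts = np.array([sv.start for sv in truth.svs])
    lens = np.array([sv.svlen for sv in truth.svs])
    sv_chroms = np.array([sv.chrom for sv in truth.svs])
    sv_types = np.array([sv.sv_type for sv in truth.svs])
    sens = np.array([profile.sens(t) for t in sv_types])
    depth_mean = truth.params.depth

    # exclusion zones around truth loci for false-positive placement
    radius = 2 * int(lens.max()) if n_sv else 0
    truth_trees: dict[str, IntervalTree] = {c: IntervalTree()
                                            for c in genome.chrom_lengths}
    for sv in truth.svs:
        truth_trees[sv.chrom].addi(sv.start - radius, sv.end + radius)
    chroms = sorted(genome.chrom_lengths)
    chrom_probs = np.array([genome.chrom_lengths[c] for c in chroms], float)
    chrom_probs /= chrom_probs.sum()
    type_names = np.array(sorted(truth.params.type_mix))
    type_probs = np.array([truth.params.type_mix[t] for t in type_names])

    callsets: dict[str, list[SVCall]] = {}
    for s_idx, sample in enumerate(truth.samples):
        rng = np.random.default_rng([seed, caller_idx, s_idx])
        gt = geno[s_idx]
        carriers = np.where(gt > 0)[0]
        detected = carriers[rng.random(carriers.size) < sens[carriers]]

        if profile.breakpoint_jitter_sd > 0:
            shift = np.round(rng.normal(0, profile.breakpoint_jitter_sd,
                                        detected.size)).astype(int)
        else:
            shift = np.zeros(detected.size, int)
        if profile.length_jitter_cv > 0:
            factor = 1 + rng.normal(0, profile.length_jitter_cv, detected.size)
        else:
            factor = np.ones(detected.size)
        new_len = np.maximum(np.round(lens[detected] * factor), 1).astype(int)
        new_start = np.maximum(starts[detected] + shift, 0)

        depth = np.maximum(rng.poisson(depth_mean, detected.size), 1)
        p_support = np.where(gt[detected] == 1, profile.het_p, profile.hom_p)
        support = rng.binomial(depth, p_support)

        calls: list[SVCall] = []
        for j, sv_i in enumerate(detected):
            if support[j] < 1:
                continue
            chrom = sv_chroms[sv_i]
            start = int(min(new_start[j],
                            genome.chrom_lengths[chrom] - new_len[j]))
            calls.append(
                SVCall(
                    sample_id=sample,
                    caller_id=profile.caller_id,
                    sv_type=str(sv_types[sv_i]),
                    chrom=str(chrom),
                    start=start,
                    end=start + int(new_len[j]),
                    svlen=int(new_len[j]),
                    support_reads=int(support[j]),
                    site_depth=int(depth[j]),
                )
            )

        n_fp = rng.poisson(profile.fp_rate)
        if n_fp:
            fp_types = rng.choice(type_names, size=n_fp, p=type_probs)
            fp_lens = sample_sv_lengths(rng, fp_types)
            fp_depth = np.maximum(rng.poisson(depth_mean, n_fp), 1)
            fp_support = np.maximum(rng.binomial(fp_depth, 0.5), 1)
            for j in range(n_fp):
                length = int(min(fp_lens[j], 100_000))
                for _ in range(50):
                    chrom = str(rng.choice(chroms, p=chrom_probs))
                    hi = genome.chrom_lengths[chrom] - length - 1
                    start = int(rng.integers(0, hi))
                    if not truth_trees[chrom].overlaps(start, start + length):
                        calls.append(
                            SVCall(
                                sample_id=sample,
                                caller_id=profile.caller_id,
                                sv_type=str(fp_types[j]),
                                chrom=chrom,
                                start=start,
                                end=start + length,
                                svlen=length,
                                support_reads=int(fp_support[j]),
                                site_depth=int(fp_depth[j]),
                            )
                        )
                        break
        calls.sort(key=lambda c: (c.chrom, c.start, c.svlen))
        callsets[sample] = calls
    return callsets


def simulate_callsets(
    truth: SimTruth,
    profiles: Sequence[CallerProfile] = DEFAULT_PROFILES,
    seed: int = 0,
) -> dict[str, dict[str, list[SVCall]]]:
    """All callers over all samples: caller -> sample -> calls."""
    return {
        p.caller_id: simulate_caller_calls(truth, p, seed) for p in profiles
    }


def write_simulation(
    truth: SimTruth,
    callsets: Mapping[str, Mapping[str, list[SVCall]]],
    outdir: str | Path,
) -> None:
    """Write a simulated study to disk: GTF gene models, mask BEDs, an arm
    table, per-sample per-caller VCFs and a truth TSV."""
    from . import io as svio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    svio.write_gene_models_gtf(truth.genome.genes, outdir / "genes.gtf")
    for mask in truth.genome.masks:
        svio.write_bed([iv for iv in mask.intervals],
                       outdir / f"mask_{mask.label}.bed")
    arms = pd.DataFrame(
        [(c, *v) for c, v in sorted(truth.genome.arms.items())],
        columns=["chrom", "p_start", "cen_start", "cen_end", "q_end"],
    )
    arms.to_csv(outdir / "arms.tsv", sep="\t", index=False)
    truth_rows = [
        {
            "sv_id": sv_id, "chrom": sv.chrom, "start": sv.start,
            "end": sv.end, "type": sv.sv_type, "length": sv.svlen,
            "af": truth.af_global[i], "plof_planted": bool(truth.plof_planted[i]),
        }
        for i, (sv_id, sv) in enumerate(zip(truth.genotypes.columns, truth.svs))
    ]
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    vcf_dir = outdir / "calls"
    vcf_dir.mkdir(exist_ok=True)
    for caller, per_sample in callsets.items():
        for sample, calls in per_sample.items():
            svio.write_caller_vcf(
                calls, vcf_dir / f"{sample}.{caller}.vcf", caller, sample,
                truth.genome.chrom_lengths,
            )
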