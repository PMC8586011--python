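"""Properties of the synthetic-data generator: determinism, type mix,
Hardy-Weinberg structure, caller emulation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chi2

from svpop.merge import reciprocal_overlap
from svpop.simulate import (
    DEFAULT_PROFILES,
    CallerProfile,
    SimParams,
    simulate_caller_calls,
    simulate_callsets,
    simulate_genome,
    simulate_population,
)


class TestSimulateGenome:
    def test_gene_count_and_mask_clearance(self, toy_genome):
        assert len(toy_genome.genes) > 0
        from intervaltree import IntervalTree

        trees = {}
        for mask in toy_genome.masks:
            for chrom, s, e in mask.intervals:
                trees.setdefault(chrom, IntervalTree()).addi(s, e)
        for gene in toy_genome.genes:
            assert not trees[gene.chrom].overlaps(gene.start, gene.end)

    def test_gtf_round_trip_count(self, tmp_path, toy_genome):
        from svpop.io import read_gene_models, write_gene_models_gtf

        path = tmp_path / "genes.gtf"
        write_gene_models_gtf(toy_genome.genes, path)
        assert len(read_gene_models(path)) == len(toy_genome.genes)

    def test_deterministic_under_seed(self):
        g1 = simulate_genome(n_chroms=2, chrom_len=2_000_000, n_genes=6,
                             seed=11)
        g2 = simulate_genome(n_chroms=2, chrom_len=2_000_000, n_genes=6,
                             seed=11)
        assert [g.gene_id for g in g1.genes] == [g.gene_id for g in g2.genes]
        assert [(g.start, g.end) for g in g1.genes] == [
            (g.start, g.end) for g in g2.genes
        ]
        assert g1.masks[0].intervals == g2.masks[0].intervals


class TestSimulatePopulation:
    def test_panmictic_subpop_frequencies_equal_global(self, toy_genome):
        params = SimParams(
            n_samples=12, n_svs=100, seed=1,
            subpops=[("a", 6, 0.0), ("b", 6, 0.0)],
        )
        truth = simulate_population(params, toy_genome)
        # F = 0: no planted loci, both groups share the ancestral AF
        assert np.allclose(truth.subpop_af["a"], truth.subpop_af["b"])
        assert np.allclose(truth.subpop_af["a"], truth.af_global)

    def test_type_mix_proportions(self):
        genome = simulate_genome(n_chroms=4, chrom_len=20_000_000,
                                 n_genes=0, seed=2)
        params = SimParams(n_samples=4, n_svs=10_000, seed=2)
        truth = simulate_population(params, genome)
        types = np.array([sv.sv_type for sv in truth.svs])
        for t, frac in params.type_mix.items():
            assert abs((types == t).mean() - frac) < 0.01

    def test_length_model_has_both_indel_peaks(self):
        genome = simulate_genome(n_chroms=4, chrom_len=20_000_000,
                                 n_genes=0, seed=3)
        params = SimParams(n_samples=4, n_svs=8_000, seed=3)
        truth = simulate_population(params, genome)
        lens = np.array([sv.svlen for sv in truth.svs
                         if sv.sv_type in ("DEL", "INS")])
        assert (np.abs(lens - 300) < 60).mean() > 0.2   # Alu-like peak
        assert ((lens > 4_500) & (lens < 7_500)).mean() > 0.03  # LINE peak
        assert lens.min() >= 50

    def test_all_loci_segregating_and_disjoint(self, toy_genome):
        params = SimParams(n_samples=10, n_svs=300, seed=4)
        truth = simulate_population(params, toy_genome)
        assert (truth.genotypes.sum(axis=0) > 0).all()
        by_chrom: dict[str, list] = {}
        for sv in truth.svs:
            by_chrom.setdefault(sv.chrom, []).append((sv.start, sv.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a_end <= b_start for (_, a_end), (b_start, _)
                       in zip(ivs, ivs[1:]))

    def test_hardy_weinberg_at_common_loci(self):
        """Within a subpopulation, genotype frequencies at common loci are
        consistent with Hardy-Weinberg at that subpopulation's allele
        frequency (chi-square non-significant at alpha = 0.01 for >= 99%
        of loci up to chance)."""
        genome = simulate_genome(n_chroms=3, chrom_len=20_000_000,
                                 n_genes=0, seed=5)
        params = SimParams(
            n_samples=400, n_svs=2_000, seed=5,
            subpops=[("a", 200, 0.05), ("b", 200, 0.05)],
        )
        truth = simulate_population(params, genome)
        g = truth.genotypes.loc[truth.sample_groups["a"]].to_numpy()
        p_k = truth.subpop_af["a"]
        common = (p_k > 0.1) & (p_k < 0.9)
        n = g.shape[0]
        counts = np.stack([(g[:, common] == k).sum(axis=0) for k in range(3)])
        p = p_k[common]
        expected = np.stack([
            n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p ** 2
        ])
        stat = ((counts - expected) ** 2 / expected).sum(axis=0)
        reject = stat > chi2.ppf(0.99, df=2)
        assert reject.mean() < 0.02

    def test_af_recovery_from_generated_genotypes(self):
        """Realized allele frequencies recover the ancestral frequencies
        without bias at 200 samples: mean(AF_realized - AF_ancestral)
        within 3 SE of zero (Balding-Nichols draws and binomial genotype
        sampling are both mean-preserving)."""
        genome = simulate_genome(n_chroms=3, chrom_len=20_000_000,
                                 n_genes=0, seed=6)
        params = SimParams(
            n_samples=200, n_svs=1_500, seed=6,
            sfs_beta=(2.0, 2.0),  # common loci: truncation cannot bias
            subpops=[("a", 100, 0.05), ("b", 100, 0.05)],
        )
        truth = simulate_population(params, genome)
        err = truth.realized_af() - truth.af_global
        se = err.std(ddof=1) / np.sqrt(err.size)
        assert abs(err.mean()) < 3 * se

    def test_vab_genotyped_af_bias_is_small(self):
        """AF re-estimated through allele-balance genotyping at 15-fold
        depth tracks the realized AF closely.  It is not exactly unbiased:
        at depths divisible by 5 the 0.2 band boundary lands on an integer
        read count and het -> 0/0 miscalls slightly exceed het -> 1/1
        ones; the net effect stays below 0.002 in absolute AF."""
        from svpop.population import genotype_from_vab

        genome = simulate_genome(n_chroms=3, chrom_len=20_000_000,
                                 n_genes=0, seed=6)
        params = SimParams(n_samples=200, n_svs=1_000, seed=6)
        truth = simulate_population(params, genome)
        rng = np.random.default_rng(6)
        g = truth.genotypes.to_numpy()
        af_hat = np.empty(g.shape[1])
        for j in range(g.shape[1]):
            ac = 0
            for i in range(g.shape[0]):
                if g[i, j] == 0:
                    continue
                depth = max(int(rng.poisson(15)), 1)
                p = 0.5 if g[i, j] == 1 else 1.0
                support = int(rng.binomial(depth, p))
                ac += {"0/0": 0, "0/1": 1, "1/1": 2, "./.": 0}[
                    genotype_from_vab(support, depth)
                ]
            af_hat[j] = ac / (2 * g.shape[0])
        err = af_hat - truth.realized_af()
        assert abs(err.mean()) < 0.002


class TestSimulateCallerCalls:
    def test_identity_profile_reproduces_carriers(self, toy_genome):
        params = SimParams(n_samples=5, n_svs=150, seed=7)
        truth = simulate_population(params, toy_genome)
        profile = CallerProfile("sniffles", 1.0, 0.0, 0.0, 0.0)
        callsets = simulate_caller_calls(truth, profile, seed=7)
        geno = truth.genotypes.to_numpy()
        for s_idx, sample in enumerate(truth.samples):
            carried = {truth.svs[i].key
                       for i in np.flatnonzero(geno[s_idx] > 0)}
            called = {c.key for c in callsets[sample]}
            assert called == carried

    def test_deterministic_vcf_bytes(self, tmp_path, toy_genome):
        from svpop.io import write_caller_vcf

        params = SimParams(n_samples=3, n_svs=100, seed=8)
        truth = simulate_population(params, toy_genome)
        contents = []
        for run in range(2):
            calls = simulate_caller_calls(truth, DEFAULT_PROFILES[0], seed=8)
            path = tmp_path / f"run{run}.vcf"
            write_caller_vcf(calls[truth.samples[0]], path, "sniffles",
                             truth.samples[0], toy_genome.chrom_lengths)
            text = path.read_text()
            body = "\n".join(l for l in text.splitlines()
                             if not l.startswith("##fileDate"))
            contents.append(body)
        assert contents[0] == contents[1]

    def test_false_call_count_poisson(self, toy_genome):
        """With an empty truth set every emitted call is false, and counts
        across seeds follow Poisson(rate)."""
        params = SimParams(n_samples=1, n_svs=1, seed=9)
        truth = simulate_population(params, toy_genome)
        profile = CallerProfile("nanovar", 0.0, 0.0, 0.0, fp_rate=100.0)
        counts = [
            len(simulate_caller_calls(truth, profile, seed=seed)
                [truth.samples[0]])
            for seed in range(20)
        ]
        mean = np.mean(counts)
        assert abs(mean - 100.0) < 3 * np.sqrt(100.0 / 20)

    def test_jitter_keeps_reciprocal_overlap(self, toy_genome):
        """15 bp breakpoint jitter on ~300 bp SVs keeps at least 99% of
        emitted calls above 50% reciprocal overlap with their truth SV."""
        genome = simulate_genome(n_chroms=1, chrom_len=5_000_000,
                                 n_genes=0, seed=10)
        params = SimParams(n_samples=20, n_svs=200, seed=10)
        truth = simulate_population(params, genome)
        # force every locus to ~300 bp for the tail computation
        from svpop.model import SVCall

        truth.svs = [
            SVCall("truth", "truth", sv.sv_type, sv.chrom, sv.start,
                   sv.start + 300, 300)
            for sv in truth.svs
        ]
        profile = CallerProfile("sniffles", 1.0, 15.0, 0.0, 0.0)
        callsets = simulate_caller_calls(truth, profile, seed=10)
        truth_at = {(sv.chrom, i): sv for i, sv in enumerate(truth.svs)}
        by_start = {}
        for i, sv in enumerate(truth.svs):
            by_start.setdefault(sv.chrom, []).append((sv.start, sv))
        ok = total = 0
        for sample, calls in callsets.items():
            for call in calls:
                candidates = [sv for s, sv in by_start[call.chrom]
                              if abs(s - call.start) < 500
                              and sv.sv_type == call.sv_type]
                best = max(
                    (reciprocal_overlap(call, sv) for sv in candidates),
                    default=0.0,
                )
                ok += best > 0.5
                total += 1
        assert total > 500
        assert ok / total >= 0.99

    def test_callsets_cover_all_samples_and_callers(self, toy_genome):
        params = SimParams(n_samples=4, n_svs=50, seed=11)
        truth = simulate_population(params, toy_genome)
        callsets = simulate_callsets(truth, DEFAULT_PROFILES, seed=11)
        assert set(callsets) == {"sniffles", "nanovar", "nanosv"}
        for per_sample in callsets.values():
            assert set(per_sample) == set(truth.samples)
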