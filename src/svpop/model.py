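"""Core data model for the structural-variant population pipeline.

Coordinates are 0-based, half-open throughout the package; VCF/GTF readers
and writers convert at the boundary.  For insertions the stored interval is
the *synthetic* one ``[start, start + svlen)`` — the reference footprint of
an INS is the single breakpoint at ``start``, but merging and dataset
comparison treat the call as an interval whose length equals the inserted
sequence, so that both position and length enter the overlap criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SV_TYPES: tuple[str, ...] = ("DEL", "INS", "DUP", "INV")

CALLERS: tuple[str, ...] = ("sniffles", "nanovar", "nanosv", "truth", "other")

#: Representative-selection priority when several callers see the same SV.
#: Sniffles first, then NanoVar, then NanoSV (most balanced performance on
#: ONT reads first).
CALLER_PRIORITY: dict[str, int] = {
    "sniffles": 0,
    "nanovar": 1,
    "nanosv": 2,
    "truth": 3,
    "other": 4,
}

AF_CATEGORIES: tuple[str, ...] = ("singleton", "rare", "low", "common")

GENE_FEATURES: tuple[str, ...] = ("promoter", "UTR", "CDS", "intron", "intergenic")

GENOTYPES: tuple[str, ...] = ("0/0", "0/1", "1/1", "./.")


@dataclass(frozen=True, slots=True)
class SVCall:
    """A single SV call made by one caller in one sample.

    ``end - start == svlen`` for every type: DEL/DUP/INV occupy their
    reference footprint, INS uses the synthetic interval (see module
    docstring).
    """

    sample_id: str
    caller_id: str
    sv_type: str
    chrom: str
    start: int
    end: int
    svlen: int
    support_reads: int = 0
    site_depth: int | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.caller_id not in CALLERS:
            raise ValueError(f"unknown caller_id {self.caller_id!r}")
        if self.svlen < 1:
            raise ValueError(f"svlen must be >= 1, got {self.svlen}")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end - self.start != self.svlen:
            raise ValueError(
                f"end - start = {self.end - self.start} != svlen = {self.svlen}"
            )
        if self.support_reads < 0:
            raise ValueError("negative support_reads")
        if self.site_depth is not None:
            if self.site_depth < 0:
                raise ValueError("negative site_depth")
            if self.support_reads > self.site_depth:
                raise ValueError(
                    f"support_reads {self.support_reads} exceeds "
                    f"site_depth {self.site_depth}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Identity of the underlying variant (ignores sample/caller)."""
        return (self.chrom, self.sv_type, self.start, self.svlen)


@dataclass(slots=True)
class MergedCall:
    """Within-sample consensus SV: one CAST cluster that passed the
    minimum-caller requirement, with a priority-chosen representative."""

    representative: SVCall
    members: tuple[SVCall, ...]
    caller_support: frozenset[str]

    @property
    def n_callers(self) -> int:
        return len(self.caller_support)

    # convenience proxies to the representative call
    @property
    def sample_id(self) -> str:
        return self.representative.sample_id

    @property
    def sv_type(self) -> str:
        return self.representative.sv_type

    @property
    def chrom(self) -> str:
        return self.representative.chrom

    @property
    def start(self) -> int:
        return self.representative.start

    @property
    def end(self) -> int:
        return self.representative.end

    @property
    def svlen(self) -> int:
        return self.representative.svlen

    @property
    def support_reads(self) -> int:
        return self.representative.support_reads

    @property
    def site_depth(self) -> int | None:
        return self.representative.site_depth


@dataclass(slots=True)
class PopulationSV:
    """A nonredundant population SV with per-sample genotypes and
    allele-frequency bookkeeping.

    ``category`` is ``None`` when AC == 0 (every carrier's allele balance
    fell in the homozygous-reference band) — such sites are kept but cannot
    be frequency-classified.
    """

    sv_id: str
    representative: SVCall
    genotypes: dict[str, str]
    AC: int
    AN: int
    AF: float
    MAF: float
    category: str | None
    novel: bool | None = None

    @property
    def sv_type(self) -> str:
        return self.representative.sv_type

    @property
    def chrom(self) -> str:
        return self.representative.chrom

    @property
    def start(self) -> int:
        return self.representative.start

    @property
    def end(self) -> int:
        return self.representative.end

    @property
    def svlen(self) -> int:
        return self.representative.svlen


@dataclass(slots=True)
class RegionMask:
    """A labelled set of excluded intervals (centromeres, assembly gaps,
    abnormally high-depth regions)."""

    label: str
    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0 or end <= start:
                raise ValueError(f"bad mask interval {chrom}:{start}-{end}")
        self.intervals = sorted(self.intervals)


#: Promoter length: the 1 kb directly preceding the transcription start
#: site, strand-aware, clipped at the chromosome start.
PROMOTER_BP = 1000


@dataclass(slots=True)
class GeneModel:
    """A protein-coding gene with CDS/UTR structure and a derived promoter."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    promoter: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("empty gene span")
        for s, e in [*self.cds, *self.utr5, *self.utr3]:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"sub-feature [{s}, {e}) outside gene span of {self.gene_id}"
                )
        if self.strand == "+":
            self.promoter = (max(0, self.start - PROMOTER_BP), self.start)
        else:
            self.promoter = (self.end, self.end + PROMOTER_BP)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(slots=True)
class FilterReport:
    """Per-step bookkeeping of the three-stage filtering cascade."""

    n_input: int
    n_after_support: int
    n_after_length: int
    n_after_region: int

    @property
    def removed_per_step(self) -> dict[str, int]:
        return {
            "support": self.n_input - self.n_after_support,
            "length": self.n_after_support - self.n_after_length,
            "region": self.n_after_length - self.n_after_region,
        }

    def __post_init__(self) -> None:
        counts = (
            self.n_input,
            self.n_after_support,
            self.n_after_length,
            self.n_after_region,
        )
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"filter counts must be weakly decreasing: {counts}")
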