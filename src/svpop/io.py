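"""Readers and writers for the pipeline's external formats.

Supported formats: VCF 4.2 (caller dialects in, population set out), BED 3
region masks, Ensembl-dialect GTF gene models and BED-like TSV tables of
external SV datasets.  All parsing of VCF goes through :mod:`pysam`; GTF
goes through :mod:`gffutils`.

Caller dialects
---------------
The three long-read callers emit support/depth in different places; the
mapping used for allele-balance genotyping is a versioned table
(:data:`CALLER_FIELD_MAP`):

========  =======================  =================================
caller    supporting reads         site depth
========  =======================  =================================
sniffles  INFO/RE (or FORMAT/DV)   FORMAT DV + DR
nanovar   INFO/SR                  FORMAT/DP
nanosv    FORMAT/DV                FORMAT DV + DR
other     —                        unknown
========  =======================  =================================
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam

from .model import (
    SV_TYPES,
    GeneModel,
    PopulationSV,
    RegionMask,
    SVCall,
)

log = logging.getLogger(__name__)

#: version tag of the caller field-mapping convention below
CALLER_FIELD_MAP_VERSION = "1"


def _first(value):
    """Unpack pysam's tuple-valued INFO/FORMAT entries."""
    if isinstance(value, tuple):
        return value[0] if value else None
    return value


def _info_get(rec: pysam.VariantRecord, key: str):
    """INFO lookup tolerant of fields absent from the header."""
    try:
        return _first(rec.info.get(key))
    except (KeyError, ValueError):
        return None


def _sniffles_fields(rec: pysam.VariantRecord) -> tuple[int, int | None]:
    support = _info_get(rec, "RE")
    dv = dr = None
    if rec.samples:
        fmt = rec.samples[0]
        dv = _first(fmt.get("DV"))
        dr = _first(fmt.get("DR"))
    if support is None:
        support = dv
    depth = dv + dr if dv is not None and dr is not None else None
    return int(support or 0), depth


def _nanovar_fields(rec: pysam.VariantRecord) -> tuple[int, int | None]:
    support = _info_get(rec, "SR")
    depth = None
    if rec.samples:
        depth = _first(rec.samples[0].get("DP"))
    return int(support or 0), int(depth) if depth is not None else None


def _nanosv_fields(rec: pysam.VariantRecord) -> tuple[int, int | None]:
    dv = dr = None
    if rec.samples:
        fmt = rec.samples[0]
        dv = _first(fmt.get("DV"))
        dr = _first(fmt.get("DR"))
    depth = dv + dr if dv is not None and dr is not None else None
    return int(dv or 0), depth


def _generic_fields(rec: pysam.VariantRecord) -> tuple[int, int | None]:
    support = _info_get(rec, "SUPPORT") or _info_get(rec, "RE") or 0
    depth = _info_get(rec, "DEPTH")
    return int(support), int(depth) if depth is not None else None


CALLER_FIELD_MAP = {
    "sniffles": _sniffles_fields,
    "nanovar": _nanovar_fields,
    "nanosv": _nanosv_fields,
    "truth": _generic_fields,
    "other": _generic_fields,
}


def read_caller_vcf(path: str | Path, caller_id: str, sample_id: str) -> list[SVCall]:
    """Read one caller's single-sample VCF into :class:`SVCall` records.

    1-based POS becomes the 0-based ``start``; negative SVLEN (the deletion
    convention) is taken as its absolute value; BND/TRA and other
    non-canonical types are dropped (a count is logged); records lacking
    SVTYPE are skipped with a warning.
    """
    extract = CALLER_FIELD_MAP.get(caller_id, _generic_fields)
    calls: list[SVCall] = []
    n_noncanonical = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = _info_get(rec, "SVTYPE")
            if svtype is None:
                log.warning("%s: record at %s:%s lacks SVTYPE, skipped",
                            path, rec.chrom, rec.pos)
                continue
            if svtype not in SV_TYPES:
                n_noncanonical += 1
                continue
            svlen = _info_get(rec, "SVLEN")
            if svlen is not None:
                svlen = abs(int(svlen))
            else:
                svlen = rec.stop - rec.start
            if svlen < 1:
                log.warning("%s: zero-length record at %s:%s skipped",
                            path, rec.chrom, rec.pos)
                continue
            support, depth = extract(rec)
            if depth is not None and support > depth:
                depth = support  # defensive: dialects can disagree
            calls.append(
                SVCall(
                    sample_id=sample_id,
                    caller_id=caller_id,
                    sv_type=svtype,
                    chrom=rec.chrom,
                    start=rec.start,
                    end=rec.start + svlen,
                    svlen=svlen,
                    support_reads=support,
                    site_depth=depth,
                )
            )
    if n_noncanonical:
        log.info("%s: dropped %d non-canonical (BND/TRA/...) records",
                 path, n_noncanonical)
    return calls


def _caller_header(caller_id: str, sample_id: str,
                   contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of structural variant")
    header.info.add("END", 1, "Integer", "End position of structural variant")
    header.formats.add("GT", 1, "String", "Genotype")
    if caller_id == "sniffles":
        header.info.add("RE", 1, "Integer", "Number of reads supporting the variant")
        header.formats.add("DR", 1, "Integer", "Number of reference reads")
        header.formats.add("DV", 1, "Integer", "Number of variant reads")
    elif caller_id == "nanovar":
        header.info.add("SR", 1, "Integer", "Number of supporting reads")
        header.formats.add("DP", 1, "Integer", "Read depth at the site")
    elif caller_id == "nanosv":
        header.formats.add("DR", 1, "Integer", "Number of reference reads")
        header.formats.add("DV", 1, "Integer", "Number of variant reads")
    else:
        header.info.add("SUPPORT", 1, "Integer", "Number of supporting reads")
        header.info.add("DEPTH", 1, "Integer", "Read depth at the site")
    header.add_sample(sample_id)
    return header


def write_caller_vcf(calls: list[SVCall], path: str | Path, caller_id: str,
                     sample_id: str, contigs: dict[str, int]) -> None:
    """Write calls in the named caller's dialect (inverse of
    :func:`read_caller_vcf`; used by the simulator and for round-trips).

    DEL records carry negative SVLEN, as the callers emit them.
    """
    header = _caller_header(caller_id, sample_id, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.chrom, c.start, c.svlen)):
            rec = vcf.new_record(
                contig=call.chrom,
                start=call.start,
                stop=call.end,
                alleles=("N", f"<{call.sv_type}>"),
            )
            rec.info["SVTYPE"] = call.sv_type
            rec.info["SVLEN"] = -call.svlen if call.sv_type == "DEL" else call.svlen
            support, depth = call.support_reads, call.site_depth
            fmt = rec.samples[sample_id]
            fmt["GT"] = (None, None)
            if caller_id == "sniffles":
                rec.info["RE"] = support
                fmt["DV"] = support
                fmt["DR"] = (depth - support) if depth is not None else None
            elif caller_id == "nanovar":
                rec.info["SR"] = support
                fmt["DP"] = depth
            elif caller_id == "nanosv":
                fmt["DV"] = support
                fmt["DR"] = (depth - support) if depth is not None else None
            else:
                rec.info["SUPPORT"] = support
                if depth is not None:
                    rec.info["DEPTH"] = depth
            rec.stop = call.end  # SVLEN updates can reset rlen; restore END
            vcf.write(rec)


_GT_TO_TUPLE = {
    "0/0": (0, 0),
    "0/1": (0, 1),
    "1/1": (1, 1),
    "./.": (None, None),
}
_TUPLE_TO_GT = {v: k for k, v in _GT_TO_TUPLE.items()}


def write_population_vcf(popset: list[PopulationSV], samples: list[str],
                         path: str | Path, contigs: dict[str, int]) -> None:
    """Write the nonredundant population set as a multi-sample VCF.

    INS END is written as start+1 (the VCF convention for a point
    insertion); the synthetic end is kept in INFO/SYNEND so the interval
    used for merging survives a round-trip.
    """
    seen_ids: set[str] = set()
    for sv in popset:
        if sv.sv_id in seen_ids:
            raise ValueError(f"duplicate SV id {sv.sv_id!r}")
        seen_ids.add(sv.sv_id)
        for sample in samples:
            if sample not in sv.genotypes:
                raise ValueError(f"{sv.sv_id}: no genotype for sample {sample!r}")

    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of structural variant")
    header.info.add("END", 1, "Integer", "End position of structural variant")
    header.info.add("SYNEND", 1, "Integer",
                    "Synthetic end (start + SVLEN) used for INS merging")
    header.info.add("AC", "A", "Integer", "Alternate allele count")
    header.info.add("AN", 1, "Integer", "Total number of called alleles")
    header.info.add("AF", "A", "Float", "Alternate allele frequency")
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in samples:
        header.add_sample(sample)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for sv in sorted(popset, key=lambda s: (s.chrom, s.start, s.svlen)):
            rep = sv.representative
            rec = vcf.new_record(
                contig=rep.chrom,
                start=rep.start,
                stop=rep.start + 1 if rep.sv_type == "INS" else rep.end,
                alleles=("N", f"<{rep.sv_type}>"),
                id=sv.sv_id,
            )
            rec.info["SVTYPE"] = rep.sv_type
            rec.info["SVLEN"] = rep.svlen
            if rep.sv_type == "INS":
                rec.info["SYNEND"] = rep.end
            rec.info["AC"] = sv.AC
            rec.info["AN"] = sv.AN
            rec.info["AF"] = sv.AF
            for sample in samples:
                rec.samples[sample]["GT"] = _GT_TO_TUPLE[sv.genotypes[sample]]
            rec.stop = rep.start + 1 if rep.sv_type == "INS" else rep.end
            vcf.write(rec)


def read_population_vcf(path: str | Path) -> tuple[list[PopulationSV], list[str]]:
    """Read a population VCF written by :func:`write_population_vcf`."""
    popset: list[PopulationSV] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            svtype = _first(rec.info["SVTYPE"])
            svlen = int(_first(rec.info["SVLEN"]))
            genotypes = {}
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                genotypes[sample] = _TUPLE_TO_GT.get(tuple(gt or (None, None)), "./.")
            ac = int(_first(rec.info["AC"]))
            an = int(_first(rec.info["AN"]))
            af = ac / an if an else 0.0
            rep = SVCall(
                sample_id="population",
                caller_id="other",
                sv_type=svtype,
                chrom=rec.chrom,
                start=rec.start,
                end=rec.start + svlen,
                svlen=svlen,
            )
            popset.append(
                PopulationSV(
                    sv_id=rec.id or f"{svtype}_{rec.chrom}_{rec.start}",
                    representative=rep,
                    genotypes=genotypes,
                    AC=ac,
                    AN=an,
                    AF=af,
                    MAF=min(af, 1 - af),
                    category=_af_category(ac, an),
                )
            )
    return popset, samples


def _af_category(ac: int, an: int) -> str | None:
    # local copy of the classification rule to avoid an import cycle;
    # the canonical implementation lives in svpop.population.classify_af
    if ac == 0:
        return None
    if ac == 1:
        return "singleton"
    af = ac / an
    if af <= 0.01:
        return "rare"
    if af <= 0.05:
        return "low"
    return "common"


def read_bed_mask(path: str | Path, label: str) -> RegionMask:
    """Read a BED3(+) file into a :class:`RegionMask`."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    intervals = [(str(r.chrom), int(r.start), int(r.end))
                 for r in df.itertuples()]
    return RegionMask(label=label, intervals=intervals)


def write_bed(intervals: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in sorted(intervals):
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read protein-coding gene models from an Ensembl-dialect GTF.

    One :class:`GeneModel` per protein-coding gene; CDS and UTR intervals
    are pooled over the gene's transcripts; the promoter is derived
    strand-aware (1 kb preceding the TSS).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        biotype = gene.attributes.get("gene_biotype", ["protein_coding"])[0]
        if biotype != "protein_coding":
            continue
        gene_id = gene.attributes.get("gene_id", [gene.id])[0]
        cds, utr5, utr3 = [], [], []
        for feat in db.children(gene, featuretype=("CDS",)):
            cds.append((feat.start - 1, feat.end))
        for feat in db.children(gene, featuretype=("five_prime_utr",)):
            utr5.append((feat.start - 1, feat.end))
        for feat in db.children(gene, featuretype=("three_prime_utr",)):
            utr3.append((feat.start - 1, feat.end))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                cds=sorted(set(cds)),
                utr5=sorted(set(utr5)),
                utr3=sorted(set(utr3)),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gene_models_gtf(genes: list[GeneModel], path: str | Path,
                          source: str = "svpop") -> None:
    """Write gene models as Ensembl-dialect GTF (inverse of
    :func:`read_gene_models`)."""

    def line(chrom, feature, start, end, strand, attrs):
        attr = " ".join(f'{k} "{v}";' for k, v in attrs)
        return f"{chrom}\t{source}\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr}\n"

    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            base = [("gene_id", g.gene_id), ("gene_biotype", "protein_coding")]
            tx = [*base, ("transcript_id", f"{g.gene_id}.t1")]
            fh.write(line(g.chrom, "gene", g.start, g.end, g.strand, base))
            fh.write(line(g.chrom, "transcript", g.start, g.end, g.strand, tx))
            for s, e in g.cds:
                fh.write(line(g.chrom, "CDS", s, e, g.strand, tx))
            for s, e in g.utr5:
                fh.write(line(g.chrom, "five_prime_utr", s, e, g.strand, tx))
            for s, e in g.utr3:
                fh.write(line(g.chrom, "three_prime_utr", s, e, g.strand, tx))


#: type vocabulary accepted in external SV tables, normalized to canonical
#: types: CNV gains are treated as DUP, losses as DEL, mobile-element
#: insertions as INS.
EXTERNAL_TYPE_MAP = {
    "DEL": "DEL", "INS": "INS", "DUP": "DUP", "INV": "INV",
    "MEI": "INS", "ALU": "INS", "LINE1": "INS", "SVA": "INS",
    "CNV_GAIN": "DUP", "CNV_LOSS": "DEL", "GAIN": "DUP", "LOSS": "DEL",
    "DUP:TANDEM": "DUP",
}


def read_external_tsv(path: str | Path, dataset: str = "external") -> list[SVCall]:
    """Read an external SV reference set from a BED-like TSV with columns
    chrom, start, end, type, length (header required).

    INS records without a usable length are excluded — both position and
    length enter the reciprocal-overlap comparison.  INS end is rebuilt as
    start + length.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "type", "length"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: external SV table needs columns {sorted(required)}"
        )
    calls: list[SVCall] = []
    for row in df.itertuples():
        svtype = EXTERNAL_TYPE_MAP.get(str(row.type).upper())
        if svtype is None:
            continue
        start = int(row.start)
        length = row.length
        if svtype == "INS":
            if pd.isna(length) or int(length) < 1:
                continue
            svlen = int(length)
        else:
            svlen = int(length) if not pd.isna(length) and int(length) >= 1 \
                else int(row.end) - start
        if svlen < 1:
            continue
        calls.append(
            SVCall(
                sample_id=dataset,
                caller_id="other",
                sv_type=svtype,
                chrom=str(row.chrom),
                start=start,
                end=start + svlen,
                svlen=svlen,
            )
        )
    return calls
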