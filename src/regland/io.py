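"""Readers and writers for the formats the pipeline touches.

VCF 4.x is handled through :mod:`pysam` (phased ``GT`` fields; optional INFO
keys ``AA`` ancestral allele, ``CSQ`` consequence class, ``CONS`` conservation
score, ``CE`` conserved-element flag).  Expression/count/annotation tables are
tab-separated with a header row.  Internal coordinates are 1-based inclusive;
BED output is converted to 0-based half-open at this boundary only.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .types import (
    AlleleCountTable,
    ExpressionBundle,
    FormatError,
    GeneModel,
    PhasedHaplotypeSet,
    PhasingError,
)

log = logging.getLogger("regland")

_INFO_KEYS = {
    "AA": ("String", "Ancestral allele"),
    "CSQ": ("String", "Consequence class"),
    "CONS": ("Float", "Base-wise conservation score"),
    "CE": ("Flag", "Conserved-element membership"),
}


def read_genotypes(vcf_source, strict: bool = True) -> list[PhasedHaplotypeSet]:
    """Read phased biallelic genotypes, one :class:`PhasedHaplotypeSet` per
    chromosome (in order of first appearance).

    Parameters
    ----------
    vcf_source : str or Path
        Uncompressed or bgzipped VCF with phased ``GT`` fields.
    strict : bool
        If True, an unphased heterozygote raises :class:`PhasingError` and a
        multiallelic record raises :class:`FormatError`; if False both are
        skipped with a warning.
    """
    per_chrom: dict[str, dict[str, list]] = {}
    with pysam.VariantFile(str(vcf_source)) as vf:
        samples = list(vf.header.samples)
        have = {k for k in _INFO_KEYS if k in vf.header.info}
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                if strict:
                    raise FormatError(
                        f"multiallelic or alt-less record at {rec.chrom}:{rec.pos}"
                    )
                log.warning("skipping multiallelic record at %s:%d", rec.chrom, rec.pos)
                continue
            hap_col = np.empty((len(samples), 2), dtype=np.int8)
            ok = True
            for i, s in enumerate(samples):
                sd = rec.samples[s]
                gt = sd["GT"]
                if gt is None or len(gt) != 2 or None in gt:
                    ok = False
                elif not sd.phased and gt[0] != gt[1]:
                    # unphased homozygotes carry no phase information
                    if strict:
                        raise PhasingError(
                            f"unphased genotype for {s} at {rec.chrom}:{rec.pos}"
                        )
                    ok = False
                else:
                    hap_col[i] = gt
            if not ok:
                if strict:
                    raise PhasingError(
                        f"missing/unphased genotype at {rec.chrom}:{rec.pos}"
                    )
                log.warning("skipping unphased/missing record at %s:%d", rec.chrom, rec.pos)
                continue
            store = per_chrom.setdefault(
                rec.chrom,
                {"pos": [], "alleles": [], "haps": [], "aa": [], "csq": [],
                 "ce": [], "cons": []},
            )
            if store["pos"] and rec.pos == store["pos"][-1]:
                raise FormatError(f"duplicated position {rec.chrom}:{rec.pos}")
            store["pos"].append(rec.pos)
            ref, alt = rec.ref, rec.alts[0]
            store["alleles"].append((ref, alt))
            store["haps"].append(hap_col)
            aa = rec.info.get("AA", None) if "AA" in have else None
            if isinstance(aa, tuple):
                aa = aa[0]
            if aa == ref:
                store["aa"].append("ref")
            elif aa == alt:
                store["aa"].append("alt")
            else:
                store["aa"].append("unknown")
            csq = rec.info.get("CSQ", None) if "CSQ" in have else None
            if isinstance(csq, tuple):
                csq = csq[0]
            store["csq"].append(csq if csq else "other")
            store["ce"].append(bool(rec.info.get("CE", False))
                               if "CE" in have else False)
            cons = rec.info.get("CONS", None) if "CONS" in have else None
            store["cons"].append(float(cons) if cons is not None else np.nan)

    out = []
    for chrom, d in per_chrom.items():
        out.append(
            PhasedHaplotypeSet(
                sample_ids=samples,
                chrom=chrom,
                positions=np.array(d["pos"], dtype=np.int64),
                alleles=d["alleles"],
                haplotypes=np.stack(d["haps"], axis=2) if d["haps"] else
                np.empty((len(samples), 2, 0), dtype=np.int8),
                ancestral=np.array(d["aa"]),
                consequence=np.array(d["csq"]),
                conserved_flag=np.array(d["ce"], dtype=bool),
                conservation_score=np.array(d["cons"], dtype=float),
            )
        )
    return out


def write_genotypes(haps: PhasedHaplotypeSet, path) -> None:
    """Write a :class:`PhasedHaplotypeSet` as an uncompressed VCF."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={haps.chrom}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for key, (typ, desc) in _INFO_KEYS.items():
        num = "0" if typ == "Flag" else "1"
        header.add_line(
            f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">'
        )
    for s in haps.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j in range(haps.n_sites):
            ref, alt = haps.alleles[j]
            rec = vf.new_record(
                contig=haps.chrom,
                start=int(haps.positions[j]) - 1,  # pysam start is 0-based
                stop=int(haps.positions[j]) - 1 + len(ref),
                alleles=(ref, alt),
            )
            if haps.ancestral[j] != "unknown":
                rec.info["AA"] = ref if haps.ancestral[j] == "ref" else alt
            if haps.consequence[j] != "other":
                rec.info["CSQ"] = str(haps.consequence[j])
            if haps.conserved_flag[j]:
                rec.info["CE"] = True
            if np.isfinite(haps.conservation_score[j]):
                rec.info["CONS"] = float(haps.conservation_score[j])
            for i, s in enumerate(haps.sample_ids):
                rec.samples[s]["GT"] = tuple(int(a) for a in haps.haplotypes[i, :, j])
                rec.samples[s].phased = True
            vf.write(rec)


# ---------------------------------------------------------------------------
# tables


def read_annotation(annot_tsv) -> list[GeneModel]:
    """Annotation TSV: columns gene, strand, tss, exon_id, exon_start, exon_end
    (one row per exon)."""
    df = pd.read_csv(annot_tsv, sep="\t")
    genes = []
    for gid, grp in df.groupby("gene", sort=False):
        grp = grp.sort_values("exon_start")
        exons = [(int(s), int(e)) for s, e in zip(grp["exon_start"], grp["exon_end"])]
        genes.append(
            GeneModel(
                gene_id=str(gid),
                strand=str(grp["strand"].iloc[0]),
                tss=int(grp["tss"].iloc[0]),
                exons=exons,
                exon_ids=[str(x) for x in grp["exon_id"]],
            )
        )
    return genes


def read_tables(
    expr_tsv, exon_tsv, annot_tsv, counts_tsv, haps: PhasedHaplotypeSet | None = None
) -> tuple[ExpressionBundle, AlleleCountTable]:
    """Read the expression bundle and the allelic count table.

    Expression and exon matrices are individuals × features with the sample
    id as the first (index) column.  Rows for samples absent from *haps* (if
    given) are dropped with a logged warning.
    """
    gene_expr = pd.read_csv(expr_tsv, sep="\t", index_col=0)
    gene_expr.index.name = None
    exon_counts = pd.read_csv(exon_tsv, sep="\t", index_col=0)
    exon_counts.index.name = None
    if not np.all(np.mod(exon_counts.to_numpy(), 1) == 0):
        raise FormatError("exon count matrix contains non-integer values")
    exon_counts = exon_counts.astype(np.int64)
    annotation = read_annotation(annot_tsv)
    counts = pd.read_csv(counts_tsv, sep="\t")

    if haps is not None:
        keep = [s for s in gene_expr.index if s in haps.sample_ids]
        dropped = sorted(set(gene_expr.index) - set(keep))
        if dropped:
            log.warning("dropping %d samples absent from genotypes: %s",
                        len(dropped), dropped[:5])
        gene_expr = gene_expr.loc[keep]
        exon_counts = exon_counts.loc[[s for s in exon_counts.index if s in keep]]
        counts = counts[counts["sample_id"].isin(keep)].reset_index(drop=True)

    bundle = ExpressionBundle(gene_expr=gene_expr, exon_counts=exon_counts,
                              annotation=annotation)
    act = AlleleCountTable(counts)
    if haps is not None:
        act.validate(haps)
    return bundle, act


def write_bundle(bundle: ExpressionBundle, expr_tsv, exon_tsv, annot_tsv) -> None:
    bundle.gene_expr.to_csv(expr_tsv, sep="\t", index_label="sample_id")
    bundle.exon_counts.to_csv(exon_tsv, sep="\t", index_label="sample_id")
    rows = []
    for g in bundle.annotation:
        for eid, (s, e) in zip(g.exon_ids, g.exons):
            rows.append((g.gene_id, g.strand, g.tss, eid, s, e))
    pd.DataFrame(
        rows, columns=["gene", "strand", "tss", "exon_id", "exon_start", "exon_end"]
    ).to_csv(annot_tsv, sep="\t", index=False)


def write_counts(counts: AlleleCountTable, path) -> None:
    counts.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coordinate conversion and result output


def to_bed_interval(position_1based: int, length: int = 1) -> tuple[int, int]:
    """1-based inclusive site → BED 0-based half-open (start, end)."""
    return position_1based - 1, position_1based - 1 + length

def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """BED 0-based half-open → 1-based inclusive (first, last)."""
    return start + 1, end


def write_results(result, path, format: str = "tsv",
                  haps: PhasedHaplotypeSet | None = None) -> None:
    """Write a result table (any downstream result with ``to_frame`` or a
    DataFrame) as TSV, or as BED when the table carries site positions.

    BED output needs the paired *haps* (for chrom/position lookup of
    ``site_index``-bearing tables) unless the frame already has ``chrom`` and
    ``position`` columns.
    """
    frame = result.to_frame() if hasattr(result, "to_frame") else pd.DataFrame(result)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif format == "bed":
        if "chrom" in frame.columns and "position" in frame.columns:
            chroms = frame["chrom"]
            pos = frame["position"].to_numpy(dtype=int)
            names = frame.iloc[:, 0].astype(str)
        else:
            site_col = next(
                (c for c in frame.columns if c in
                 ("site_index", "best_site", "candidate_site")), None)
            if site_col is None or haps is None:
                raise FormatError("BED output needs positions or haps + site index")
            idx = frame[site_col].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                valid = pd.notna(idx)
            frame = frame.loc[valid]
            idx = frame[site_col].to_numpy(dtype=int)
            chroms = pd.Series([haps.chrom] * len(frame))
            pos = haps.positions[idx]
            names = frame.iloc[:, 0].astype(str)
        starts = pos - 1
        bed = pd.DataFrame(
            {"chrom": np.asarray(chroms), "start": starts, "end": pos,
             "name": np.asarray(names)})
        bed.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown output format: {format!r}")


def read_result_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
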