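"""Readers and writers for every external format the pipeline touches.

Internal coordinates are 0-based, half-open everywhere; conversion to each
format's native convention (1-based inclusive GFF3, 1-based methylation
TSV, 0-based half-open BED, 1-based VCF POS) happens only here. All writers
are deterministic given sorted input, and every filtering reader logs
(input count, surviving count, rule).
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .genome import GeneModel
from .popgen import MISSING, VariantTable

logger = logging.getLogger(__name__)

METHYLATION_COLUMNS = ["chrom", "pos", "strand", "context", "tissue",
                       "meth_reads", "total_reads"]
VALID_CONTEXTS = {"CpG", "nonCpG"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variants(path: str | Path, outgroup_samples: list[str]) -> VariantTable:
    """Read biallelic SNPs from a VCF into a VariantTable.

    ``outgroup_samples`` are separated from the focal panel; their genotype
    calls are collapsed to a single allele (heterozygous or missing calls
    become 'N'). Multiallelic and indel records are skipped with a logged
    count. Positions become 0-based.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_og = [s for s in outgroup_samples if s not in samples]
    if missing_og:
        raise ValueError(f"outgroup samples not in VCF: {missing_og}")
    focal_idx = [i for i, s in enumerate(samples) if s not in outgroup_samples]
    og_idx = [samples.index(s) for s in outgroup_samples]
    if not vcf.seqnames:
        logger.warning("%s: no contig headers present", path)

    chroms, poss, refs, alts, gts, ogs = [], [], [], [], [], []
    skipped = 0
    total = 0
    for rec in vcf:
        total += 1
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        types = rec.gt_types  # cyvcf2: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        code = np.select([types == 0, types == 1, types == 3],
                         [0, 1, 2], default=MISSING)
        oga = rec.INFO.get("OGA")
        if oga is not None:
            og_allele = str(oga).split(",")
            if len(og_allele) != len(og_idx):
                raise ValueError(
                    f"{rec.CHROM}:{rec.POS}: OGA has {len(og_allele)} alleles "
                    f"for {len(og_idx)} outgroups")
        else:
            og_allele = []
            for i in og_idx:
                t = types[i]
                if t == 0:
                    og_allele.append(rec.REF)
                elif t == 3:
                    og_allele.append(rec.ALT[0])
                else:
                    og_allele.append("N")
        chroms.append(rec.CHROM)
        poss.append(rec.POS - 1)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gts.append(code[focal_idx])
        ogs.append(og_allele)
    logger.info("filter=biallelic_snp input=%d surviving=%d",
                total, total - skipped)
    n_focal = len(focal_idx)
    return VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype="<U1"),
        alt=np.array(alts, dtype="<U1"),
        genotypes=(np.array(gts, dtype=np.int8) if gts
                   else np.empty((0, n_focal), dtype=np.int8)),
        outgroup_alleles=(np.array(ogs, dtype="<U1") if ogs
                          else np.empty((0, len(og_idx)), dtype="<U1")),
        samples=[samples[i] for i in focal_idx],
        outgroup_names=list(outgroup_samples))


def write_variants(vt: VariantTable, path: str | Path,
                   chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a VariantTable as a minimal GT-only VCF 4.2 text file.

    Outgroup alleles are carried in the OGA INFO field (one allele per
    outgroup, 'N' for missing) -- a plain GT encoding could not represent an
    outgroup base that matches neither focal allele -- and additionally as
    homozygous calls of extra samples where representable, so the file
    round-trips through :func:`read_variants` exactly.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if chrom_lengths:
            for c, L in chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={L}>\n")
        else:
            for c in vt.chromosomes:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=OGA,Number=1,Type=String,'
                 'Description="Outgroup alleles, one per outgroup sample">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT", *vt.samples, *vt.outgroup_names]
        fh.write("\t".join(header) + "\n")
        for i in range(vt.n_sites):
            info = "OGA=" + ",".join(vt.outgroup_alleles[i]) \
                if vt.outgroup_names else "."
            fields = [str(vt.chrom[i]), str(int(vt.pos[i]) + 1), ".",
                      str(vt.ref[i]), str(vt.alt[i]), ".", "PASS", info, "GT"]
            fields += [gt_str[int(g)] for g in vt.genotypes[i]]
            for a in vt.outgroup_alleles[i]:
                if a == vt.ref[i]:
                    fields.append("0/0")
                elif a == vt.alt[i]:
                    fields.append("1/1")
                else:
                    fields.append("./.")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 file (1-based inclusive -> 0-based).

    Genes on sequences whose name starts with ``scaffold`` are flagged as
    unplaced. An explicit ``placed=0`` attribute also marks a gene unplaced.
    """
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        start = feat.start - 1
        if start < 0:
            raise ValueError(f"coordinate underflow at {feat.id}")
        placed = not feat.seqid.lower().startswith("scaffold")
        if feat.attributes.get("placed", ["1"])[0] == "0":
            placed = False
        genes.append(GeneModel(
            gene_id=feat.attributes.get("ID", [feat.id])[0],
            chrom=feat.seqid, start=start, end=feat.end,
            strand=feat.strand, placed=placed))
    return genes


def write_gff(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            placed = "" if g.placed else ";placed=0"
            fh.write("\t".join([
                g.chrom, "selectscan", "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", f"ID={g.gene_id}{placed}"]) + "\n")


# ---------------------------------------------------------------------------
# methylation calls
# ---------------------------------------------------------------------------

def read_methylation(path: str | Path) -> pd.DataFrame:
    """Read long-format methylation calls (1-based TSV -> 0-based frame).

    Columns: chrom, pos, strand, context in {CpG, nonCpG}, tissue,
    meth_reads, total_reads. Rows with total_reads <= 0, meth > total or an
    unknown context are rejected with an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "tissue": str})
    missing = set(METHYLATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"methylation table missing columns: {sorted(missing)}")
    bad_ctx = set(df["context"].unique()) - VALID_CONTEXTS
    if bad_ctx:
        raise ValueError(f"unknown methylation context(s): {sorted(bad_ctx)}")
    if (df["total_reads"] <= 0).any():
        raise ValueError("methylation rows with total_reads <= 0")
    if (df["meth_reads"] > df["total_reads"]).any():
        raise ValueError("methylation rows with meth_reads > total_reads")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64) - 1
    if (df["pos"] < 0).any():
        raise ValueError("coordinate underflow in methylation table")
    return df.sort_values(["chrom", "pos", "tissue"],
                          kind="stable").reset_index(drop=True)


def write_methylation(long_df: pd.DataFrame, path: str | Path) -> None:
    out = long_df.copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out = out.sort_values(["chrom", "pos", "tissue"], kind="stable")
    out.to_csv(path, sep="\t", index=False, columns=METHYLATION_COLUMNS)


def wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Internal wide site table -> long per-(site, tissue) rows."""
    tissues = sorted(c.removeprefix("total_") for c in wide.columns
                     if c.startswith("total_"))
    frames = []
    for t in tissues:
        frames.append(pd.DataFrame({
            "chrom": wide["chrom"], "pos": wide["pos"],
            "strand": wide["strand"], "context": wide["context"], "tissue": t,
            "meth_reads": wide[f"meth_{t}"], "total_reads": wide[f"total_{t}"]}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# simple tables, BED, FASTA
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "fpkm"} <= set(df.columns):
        raise ValueError("expression table needs gene_id and fpkm columns")
    return df


def read_term_map(path: str | Path):
    """Gene-to-term TSV (columns gene_id, term[, label]) -> TermMap."""
    from .enrichment import TermMap

    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term"} <= set(df.columns):
        raise ValueError("term map needs gene_id and term columns")
    gene_terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for row in df.itertuples(index=False):
        gene_terms.setdefault(row.gene_id, set()).add(row.term)
        if hasattr(row, "label") and isinstance(row.label, str):
            labels[row.term] = row.label
    return TermMap(gene_terms, labels)


def write_term_map(term_map, path: str | Path) -> None:
    rows = [{"gene_id": g, "term": t, "label": term_map.labels.get(t, t)}
            for g in sorted(term_map.gene_terms)
            for t in sorted(term_map.gene_terms[g])]
    pd.DataFrame(rows, columns=["gene_id", "term", "label"]).to_csv(
        path, sep="\t", index=False)


def write_bed(intervals, path: str | Path) -> None:
    """Write intervals (objects with chrom/start/end and optional score
    attribute, or region DataFrame rows) as BED6, 0-based half-open."""
    with open(path, "w") as fh:
        if isinstance(intervals, pd.DataFrame):
            it = intervals.itertuples(index=False)
        else:
            it = intervals
        for iv in it:
            score = getattr(iv, "summed_clr", getattr(iv, "score", 0.0))
            name = getattr(iv, "name", getattr(iv, "gene_id", "."))
            strand = getattr(iv, "strand", ".")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t"
                     f"{score:.6g}\t{strand}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_alignment_fasta(alignment: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=taxon, description="")
               for taxon, seq in alignment.items()]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    aln = {rec.id: str(rec.seq).upper()
           for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ValueError(f"{path}: sequences have unequal lengths")
    return aln
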