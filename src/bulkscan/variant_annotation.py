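"""Variant annotation against gene models: genomic context and coding effect.

Mirrors the annotation vocabulary of gene-based SNP/InDel classification:
genomic contexts {CDS, UTR, intron, upstream, downstream, intergenic} with
upstream/downstream defined as the 1-kb flank beyond the transcription start
and termination sites (strand-aware, inclusive of the 1,000th base), and
coding effects {synonymous, nonsynonymous, stop_gain, stop_loss,
frameshift_insertion, frameshift_deletion, nonframeshift_insertion,
nonframeshift_deletion}.

One canonical transcript per gene (the longest CDS) is used so every variant
gets a single category.  When a position matches features of several genes
the highest-precedence context wins (CDS > UTR > intron > upstream >
downstream > intergenic).  Coordinates are 1-based inclusive (GFF3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gffutils
import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger(__name__)

CONTEXT_PRECEDENCE = ("CDS", "UTR", "intron", "upstream", "downstream")

EFFECTS = (
    "synonymous",
    "nonsynonymous",
    "stop_gain",
    "stop_loss",
    "frameshift_insertion",
    "frameshift_deletion",
    "nonframeshift_insertion",
    "nonframeshift_deletion",
    "not_applicable",
)


@dataclass
class GeneModel:
    """Canonical-transcript gene structure, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]  # genomic order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tts(self) -> int:
        """Transcription termination site (strand-aware)."""
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains_in(self, pos: int, intervals: list[tuple[int, int]]) -> bool:
        return any(s <= pos <= e for s, e in intervals)


@dataclass
class AnnotationResult:
    context: str
    coding_effect: str = "not_applicable"
    gene_id: str | None = None


def load_gene_models(gff_path: str) -> dict[str, list[GeneModel]]:
    """Parse a GFF3 into per-chromosome gene models (one canonical transcript).

    Uses gene/mRNA/exon/CDS features; when a gene carries several mRNAs the
    one with the longest total CDS is kept.
    """
    db = gffutils.create_db(
        gff_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict[str, list[GeneModel]] = {}
    for gene in db.features_of_type("gene"):
        best: GeneModel | None = None
        transcripts = list(db.children(gene, featuretype="mRNA")) or [gene]
        for tx in transcripts:
            exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
            if not exons:
                exons = list(cds)
            gm = GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tx_start=tx.start,
                tx_end=tx.end,
                exons=exons,
                cds=cds,
            )
            if best is None or gm.cds_length > best.cds_length:
                best = gm
        if best is not None:
            models.setdefault(best.chrom, []).append(best)
    for lst in models.values():
        lst.sort(key=lambda g: g.tx_start)
    return models


def _context_for_gene(pos: int, gm: GeneModel, flank: int) -> str | None:
    if gm.contains_in(pos, gm.cds):
        return "CDS"
    if gm.tx_start <= pos <= gm.tx_end:
        return "UTR" if gm.contains_in(pos, gm.exons) else "intron"
    if gm.strand == "+":
        if 0 < gm.tss - pos <= flank:
            return "upstream"
        if 0 < pos - gm.tts <= flank:
            return "downstream"
    else:
        if 0 < pos - gm.tss <= flank:
            return "upstream"
        if 0 < gm.tts - pos <= flank:
            return "downstream"
    return None


def classify_genomic_context(
    chrom: str,
    pos: int,
    models: dict[str, list[GeneModel]],
    flank: int = 1000,
) -> AnnotationResult:
    """Best-precedence genomic context of a position over all nearby genes."""
    gene_list = models.get(chrom)
    if gene_list is None:
        log.warning("chromosome %s absent from gene models; calling intergenic", chrom)
        return AnnotationResult("intergenic")
    best_rank = len(CONTEXT_PRECEDENCE)
    best: AnnotationResult | None = None
    for gm in gene_list:
        if pos < gm.tx_start - flank:
            break  # gene list is sorted by tx_start
        ctx = _context_for_gene(pos, gm, flank)
        if ctx is not None and CONTEXT_PRECEDENCE.index(ctx) < best_rank:
            best_rank = CONTEXT_PRECEDENCE.index(ctx)
            best = AnnotationResult(ctx, gene_id=gm.gene_id)
    return best if best is not None else AnnotationResult("intergenic")


def _fetch(seqs, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice of a chromosome from a dict of strings or pyfaidx."""
    return str(seqs[chrom][start - 1 : end]).upper()


def _spliced_cds_offset(gm: GeneModel, pos: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS (transcript orientation)."""
    offset = 0
    if gm.strand == "+":
        for s, e in gm.cds:
            if s <= pos <= e:
                return offset + (pos - s)
            offset += e - s + 1
    else:
        for s, e in reversed(gm.cds):
            if s <= pos <= e:
                return offset + (e - pos)
            offset += e - s + 1
    return None


def classify_snp_effect(
    chrom: str, pos: int, ref: str, alt: str, gm: GeneModel, seqs
) -> str:
    """Coding effect of a SNP inside a CDS: codon reconstruction + translation.

    The affected codon is rebuilt from the spliced CDS in transcript
    orientation (reverse-complemented for minus-strand genes) and both
    alleles are translated with the standard nuclear codon table.
    """
    if gm.cds_length < 3 or gm.cds_length % 3 != 0:
        log.warning("%s: CDS length %d not divisible by 3", gm.gene_id, gm.cds_length)
        return "not_applicable"
    off = _spliced_cds_offset(gm, pos)
    if off is None:
        return "not_applicable"
    codon_start = (off // 3) * 3
    within = off % 3
    spliced = _spliced_cds_sequence(gm, seqs)
    codon = spliced[codon_start : codon_start + 3]
    ref_t, alt_t = ref.upper(), alt.upper()
    if gm.strand == "-":
        ref_t = str(Seq(ref_t).reverse_complement())
        alt_t = str(Seq(alt_t).reverse_complement())
    if codon[within] != ref_t:
        log.warning(
            "%s:%d reference allele %s disagrees with gene sequence %s",
            chrom,
            pos,
            ref,
            codon[within],
        )
    mutant = codon[:within] + alt_t + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutant).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gain"
    if aa_ref == "*":
        return "stop_loss"
    return "nonsynonymous"


def _spliced_cds_sequence(gm: GeneModel, seqs) -> str:
    parts = [_fetch(seqs, gm.chrom, s, e) for s, e in gm.cds]
    seq = "".join(parts)
    if gm.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def classify_indel_effect(chrom: str, pos: int, ref: str, alt: str, gm: GeneModel) -> str:
    """Frameshift vs in-frame classification for an indel fully inside the CDS.

    Uses VCF anchor-base convention: the first REF/ALT base is shared.  An
    indel touching a CDS boundary gets ``not_applicable`` (no rule for
    splice-spanning events).
    """
    diff = len(alt) - len(ref)
    if diff == 0:
        return "not_applicable"
    if diff > 0:  # insertion between pos and pos+1
        inside = any(s <= pos and pos + 1 <= e for s, e in gm.cds)
        if not inside:
            log.warning("%s:%d insertion touches a CDS boundary", chrom, pos)
            return "not_applicable"
        return "frameshift_insertion" if diff % 3 else "nonframeshift_insertion"
    del_start, del_end = pos + 1, pos + len(ref) - 1  # deleted bases
    inside = any(s <= del_start and del_end <= e for s, e in gm.cds)
    if not inside:
        log.warning("%s:%d deletion spans a CDS boundary", chrom, pos)
        return "not_applicable"
    return "frameshift_deletion" if (-diff) % 3 else "nonframeshift_deletion"


def annotate_variants(
    records,
    models: dict[str, list[GeneModel]],
    seqs=None,
    flank: int = 1000,
) -> pd.DataFrame:
    """Annotate a stream of variant records; returns one row per variant.

    ``seqs`` (dict of chromosome sequences or a pyfaidx.Fasta) is needed for
    SNP coding effects; without it CDS SNPs get effect ``not_applicable``.
    """
    gene_index = {
        (gm.chrom, gm.gene_id): gm for lst in models.values() for gm in lst
    }
    rows = []
    for rec in records:
        res = classify_genomic_context(rec.chrom, rec.pos, models, flank)
        effect = "not_applicable"
        if res.context == "CDS" and res.gene_id is not None:
            gm = gene_index[(rec.chrom, res.gene_id)]
            if rec.variant_class == "SNP":
                if seqs is not None:
                    effect = classify_snp_effect(
                        rec.chrom, rec.pos, rec.ref, rec.alt, gm, seqs
                    )
            else:
                effect = classify_indel_effect(rec.chrom, rec.pos, rec.ref, rec.alt, gm)
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "variant_class": rec.variant_class,
                "context": res.context,
                "coding_effect": effect,
                "gene_id": res.gene_id,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "variant_class",
            "context",
            "coding_effect",
            "gene_id",
        ],
    )


def summarize_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Category-count summary: context tallies (with %) and coding-effect tallies."""
    n = len(annotations)
    rows = []
    for ctx in (*CONTEXT_PRECEDENCE, "intergenic"):
        count = int((annotations["context"] == ctx).sum())
        rows.append(
            {
                "category": ctx,
                "count": count,
                "percent": round(100.0 * count / n, 2) if n else 0.0,
            }
        )
    for eff in EFFECTS[:-1]:
        count = int((annotations["coding_effect"] == eff).sum())
        rows.append({"category": eff, "count": count, "percent": float("nan")})
    return pd.DataFrame(rows, columns=["category", "count", "percent"])
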