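"""Variant effect annotation against GFF3 gene models.

Each SNP is classified into a single region class per transcript (codon
change classes inside CDS, splice classes in introns near junctions, UTR,
intron, upstream/downstream within a configurable window, else intergenic);
when several transcripts overlap the most severe consequence is reported.
Region classes map onto the four-level impact scheme used by variant
annotators:

    HIGH      stop_gained, stop_lost, start_lost, splice_acceptor, splice_donor
    MODERATE  missense
    LOW       synonymous, splice_region
    MODIFIER  5'UTR, 3'UTR, intron, upstream, downstream, intergenic

The "gene body" marker panel used for model retraining is every SNP whose
class is not intergenic (UTR, up/downstream, intron and coding classes
together).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

SEVERITY_ORDER = [
    "stop_gained", "stop_lost", "start_lost", "splice_acceptor", "splice_donor",
    "missense", "splice_region", "synonymous", "5'UTR", "3'UTR", "intron",
    "upstream", "downstream", "intergenic",
]
_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

IMPACT = {
    "stop_gained": "HIGH", "stop_lost": "HIGH", "start_lost": "HIGH",
    "splice_acceptor": "HIGH", "splice_donor": "HIGH",
    "missense": "MODERATE",
    "synonymous": "LOW", "splice_region": "LOW",
    "5'UTR": "MODIFIER", "3'UTR": "MODIFIER", "intron": "MODIFIER",
    "upstream": "MODIFIER", "downstream": "MODIFIER", "intergenic": "MODIFIER",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass
class VariantAnnotation:
    chrom: str
    pos: int
    ref: str
    alt: str
    region_class: str
    impact: str
    gene_id: str = ""


@dataclass
class _Transcript:
    tid: str
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exons: list  # [(start, end)] sorted genomically
    cds: list    # [(start, end, phase)] sorted genomically
    flagged: bool = False  # CDS length not divisible by 3 after phase trim


def _load_transcripts(gff3_path) -> list:
    """Parse gene models from GFF3 via gffutils (in-memory DB)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique",
        keep_order=True, force=True,
    )
    transcripts = []
    kinds = ("mRNA", "transcript")
    for kind in kinds:
        for t in db.features_of_type(kind):
            gene_id = t.attributes.get("Parent", [t.id])[0]
            exons = sorted(
                (f.start, f.end) for f in db.children(t, featuretype="exon")
            )
            cds = sorted(
                (f.start, f.end, 0 if f.frame in (".", None) else int(f.frame))
                for f in db.children(t, featuretype="CDS")
            )
            if not exons and cds:
                exons = [(s, e) for s, e, _ in cds]
            if not exons:
                exons = [(t.start, t.end)]
            transcripts.append(
                _Transcript(t.id, gene_id, t.seqid, t.start, t.end, t.strand, exons, cds)
            )
    if not transcripts:
        # GFF with bare gene features only: treat each gene as one exon transcript
        for g in db.features_of_type("gene"):
            transcripts.append(
                _Transcript(g.id, g.id, g.seqid, g.start, g.end, g.strand,
                            [(g.start, g.end)], [])
            )
    return transcripts


def _cds_sequence(t: _Transcript, seq_fetch) -> tuple:
    """Coding sequence in translation order and a map pos->CDS index.

    Returns (cds_string, index_of_genomic_position dict).  Applies the phase
    of the first CDS segment in transcript order.  Sets ``t.flagged`` when
    the trimmed length is not a codon multiple.
    """
    segs = t.cds if t.strand == "+" else t.cds[::-1]
    parts = []
    pos_map = {}
    k = 0
    for s, e, _ in segs:
        block = seq_fetch(t.chrom, s, e).upper()
        if t.strand == "-":
            block = "".join(_COMPLEMENT.get(b, "N") for b in reversed(block))
            rng = range(e, s - 1, -1)
        else:
            rng = range(s, e + 1)
        for p in rng:
            pos_map[p] = k
            k += 1
        parts.append(block)
    cds = "".join(parts)
    phase = segs[0][2] if segs else 0
    if phase:
        cds = cds[phase:]
        pos_map = {p: i - phase for p, i in pos_map.items() if i >= phase}
    if len(cds) % 3 != 0:
        t.flagged = True
    return cds, pos_map


def _classify_cds(t: _Transcript, pos: int, ref: str, alt: str, seq_fetch) -> str:
    cds, pos_map = _cds_sequence(t, seq_fetch)
    if t.flagged:
        warnings.warn(f"transcript {t.tid}: CDS length not divisible by 3; "
                      "coding consequences suppressed")
        return "intron"
    i = pos_map.get(pos)
    if i is None or i < 0:
        return "intron"
    ref_t = ref if t.strand == "+" else _COMPLEMENT[ref]
    alt_t = alt if t.strand == "+" else _COMPLEMENT[alt]
    if cds[i] != ref_t:
        logger.warning("reference mismatch at %s:%d (%s vs %s)", t.chrom, pos, cds[i], ref_t)
    ci = i // 3
    codon = cds[3 * ci : 3 * ci + 3]
    if len(codon) < 3:
        return "intron"
    alt_codon = codon[: i % 3] + alt_t + codon[i % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if ci == 0 and codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    if aa_ref == "*" and aa_alt != "*":
        return "stop_lost"
    if aa_alt == "*" and aa_ref != "*":
        return "stop_gained"
    return "synonymous" if aa_ref == aa_alt else "missense"


def _classify_intronic(t: _Transcript, pos: int) -> str:
    """Splice classes by distance into the intron from the flanking exons."""
    for (s1, e1), (s2, _) in zip(t.exons, t.exons[1:]):
        if e1 < pos < s2:
            d_left = pos - e1   # bases into intron from the left exon
            d_right = s2 - pos  # bases into intron from the right exon
            donor_d, acceptor_d = (d_left, d_right) if t.strand == "+" else (d_right, d_left)
            if donor_d <= 2:
                return "splice_donor"
            if acceptor_d <= 2:
                return "splice_acceptor"
            if min(d_left, d_right) <= 8:
                return "splice_region"
            return "intron"
    return "intron"


def _classify_exonic_noncoding(t: _Transcript, pos: int) -> str:
    if not t.cds:
        return "intron"  # non-coding transcript: treated as a modifier class
    cds_start = min(s for s, _, _ in t.cds)
    cds_end = max(e for _, e, _ in t.cds)
    if pos < cds_start:
        return "5'UTR" if t.strand == "+" else "3'UTR"
    if pos > cds_end:
        return "3'UTR" if t.strand == "+" else "5'UTR"
    return "intron"


def _classify_against(t: _Transcript, pos: int, ref: str, alt: str,
                      seq_fetch, updown_bp: int) -> str:
    if t.start <= pos <= t.end:
        in_exon = any(s <= pos <= e for s, e in t.exons)
        in_cds = any(s <= pos <= e for s, e, _ in t.cds)
        if in_cds:
            cls = _classify_cds(t, pos, ref, alt, seq_fetch)
            if not t.flagged or cls != "intron":
                return cls
            # flagged transcript: fall back to exon/intron classes
        if in_exon:
            return _classify_exonic_noncoding(t, pos)
        return _classify_intronic(t, pos)
    if pos < t.start:
        d = t.start - pos
        side = "upstream" if t.strand == "+" else "downstream"
    else:
        d = pos - t.end
        side = "downstream" if t.strand == "+" else "upstream"
    return side if d <= updown_bp else "intergenic"


def annotate(gm, gff3_path, fasta_path, updown_bp: int = 5000) -> list:
    """Annotate every marker of a GenotypeMatrix; one class per variant.

    Parameters
    ----------
    gm : GenotypeMatrix
    gff3_path, fasta_path : paths to gene models and genome sequence
    updown_bp : flanking window for upstream/downstream classes (default 5000)
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path), sequence_always_upper=True)

    def seq_fetch(chrom, start, end):
        return str(fasta[chrom][start - 1 : end])

    transcripts = _load_transcripts(gff3_path)
    trees: dict = {}
    for t in transcripts:
        trees.setdefault(t.chrom, IntervalTree()).addi(
            max(1, t.start - updown_bp), t.end + updown_bp + 1, t
        )

    out = []
    for rec in gm.markers.itertuples(index=False):
        best_cls, best_gene = "intergenic", ""
        tree = trees.get(rec.chrom)
        if tree is not None:
            for iv in sorted(tree[rec.pos], key=lambda iv: iv.data.tid):
                t = iv.data
                cls = _classify_against(t, rec.pos, rec.ref, rec.alt, seq_fetch, updown_bp)
                if _RANK[cls] < _RANK[best_cls]:
                    best_cls, best_gene = cls, t.gene_id
        out.append(
            VariantAnnotation(rec.chrom, rec.pos, rec.ref, rec.alt,
                              best_cls, IMPACT[best_cls], best_gene)
        )
    return out


def class_proportions(annos: list) -> dict:
    n = len(annos)
    props: dict = {}
    for a in annos:
        props[a.region_class] = props.get(a.region_class, 0) + 1
    return {k: v / n for k, v in sorted(props.items(), key=lambda kv: _RANK[kv[0]])}


def genic_subset(annos: list, gm):
    """Restrict a matrix to non-intergenic ("gene body") SNPs.

    Returns (subset matrix, class-proportion dict).  Annotation order must
    match the marker order of ``gm``.
    """
    if len(annos) != gm.n_markers:
        raise ValueError("annotations do not cover all markers")
    keep = np.array([a.region_class != "intergenic" for a in annos])
    return gm.subset_markers(keep), class_proportions(annos)


def random_marker_subset(gm, size: int, seed: int):
    """Size-matched random marker panel (control for the genic panel)."""
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(gm.n_markers, size=size, replace=False))
    return gm.subset_markers(idx)


# ---------------------------------------------------------------------------
# Synthetic reference (genome + gene models) for simulated studies
# ---------------------------------------------------------------------------

def synthetic_reference(gm, fasta_path, gff3_path, genes_per_chrom: int | None = None,
                        updown_bp: int = 5000, genic_fraction: float = 0.2,
                        seed: int = 0) -> None:
    """Write a synthetic genome FASTA and GFF3 consistent with a marker set.

    Purely synthetic stand-ins for a real assembly and annotation: random
    sequence with the marker reference alleles planted at their positions,
    and two-exon protein-coding genes (with UTRs and phase-0 CDS of codon
    length) tiled on alternating strands.  When ``genes_per_chrom`` is not
    given, the tiling density targets ``genic_fraction`` of the genome
    falling within a gene body or its ``updown_bp`` flanks (so roughly that
    share of uniformly placed SNPs annotates as non-intergenic).  Intended
    for end-to-end runs and tests of the annotation stage on simulated
    populations.
    """
    rng = np.random.default_rng(seed)
    lines_fa = []
    lines_gff = ["##gff-version 3"]
    for chrom, sub in gm.markers.groupby("chrom", sort=True):
        length = int(sub["pos"].max()) + 2000
        seq = rng.choice(list("ACGT"), size=length)
        for p, r in zip(sub["pos"], sub["ref"]):
            seq[p - 1] = r
        # tile genes: 5'UTR 99, CDS1 300, intron 200, CDS2 300, 3'UTR 150
        n_genes = genes_per_chrom
        if n_genes is None:
            footprint = 1049 + 2 * updown_bp
            n_genes = max(2, int(round(genic_fraction * length / footprint)))
        span = length // (n_genes + 1)
        for g in range(n_genes):
            start = g * span + span // 4 + 1
            strand = "+" if g % 2 == 0 else "-"
            u5, c1, ivn, c2, u3 = 99, 300, 200, 300, 150
            e1s, e1e = start, start + u5 + c1 - 1
            e2s = e1e + ivn + 1
            e2e = e2s + c2 + u3 - 1
            if e2e >= length:
                continue
            if strand == "+":
                cds1 = (e1s + u5, e1e)
                cds2 = (e2s, e2s + c2 - 1)
            else:
                cds1 = (e1s + u3, e1e)
                cds2 = (e2s, e2s + c2 - 1)
            gid = f"{chrom}g{g + 1:03d}"
            lines_gff.append(f"{chrom}\tsynth\tgene\t{e1s}\t{e2e}\t.\t{strand}\t.\tID={gid}")
            lines_gff.append(
                f"{chrom}\tsynth\tmRNA\t{e1s}\t{e2e}\t.\t{strand}\t.\tID={gid}.1;Parent={gid}"
            )
            for es, ee in ((e1s, e1e), (e2s, e2e)):
                lines_gff.append(
                    f"{chrom}\tsynth\texon\t{es}\t{ee}\t.\t{strand}\t.\tParent={gid}.1"
                )
            for cs, ce in (cds1, cds2):
                lines_gff.append(
                    f"{chrom}\tsynth\tCDS\t{cs}\t{ce}\t.\t{strand}\t0\tParent={gid}.1"
                )
        lines_fa.append(f">{chrom}")
        s = "".join(seq)
        lines_fa.extend(s[i : i + 60] for i in range(0, len(s), 60))
    with open(fasta_path, "wt") as fh:
        fh.write("\n".join(lines_fa) + "\n")
    with open(gff3_path, "wt") as fh:
        fh.write("\n".join(lines_gff) + "\n")
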