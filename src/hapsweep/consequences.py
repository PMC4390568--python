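"""Lightweight SNP consequence classification from transcript models.

Classifies each SNP against every supplied transcript as intergenic,
intronic, UTR, synonymous, missense, stop_gained, stop_lost, start_lost or
splice_site (the essential splice region: the 2 intronic bases on either
side of an exon-intron junction), and resolves the SNP-level category by
the most severe call across transcripts.  Coding calls translate the
affected codon with the standard genetic code, strand aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "SEVERITY",
    "TranscriptModel",
    "Consequence",
    "transcripts_from_gff",
    "classify_snp",
    "tally",
]

#: least to most severe
SEVERITY = [
    "intergenic", "intronic", "UTR", "synonymous", "missense",
    "stop_gained", "stop_lost", "start_lost", "splice_site",
]
_RANK = {c: i for i, c in enumerate(SEVERITY)}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class DataConsistencyError(ValueError):
    """Genome base does not match the declared reference allele."""


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript (1-based inclusive intervals).

    Exons and CDS are kept in genomic order; UTR status is derived as
    exonic-but-not-CDS.  The total CDS length must be a multiple of 3.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list
    cds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for (a, b) in self.exons:
            if a > b:
                raise ValueError("exon start > end")
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 <= b1:
                raise ValueError("overlapping exons")
        clen = sum(b - a + 1 for a, b in self.cds)
        if self.cds and clen % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {clen} not divisible by 3")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_index(self, pos: int) -> int | None:
        """0-based index of a genomic position within the spliced CDS."""
        off = 0
        if self.strand == "+":
            for a, b in self.cds:
                if a <= pos <= b:
                    return off + pos - a
                off += b - a + 1
        else:
            for a, b in reversed(self.cds):
                if a <= pos <= b:
                    return off + b - pos
                off += b - a + 1
        return None


@dataclass
class Consequence:
    category: str
    gene_id: str | None = None
    transcript_id: str | None = None
    codon_change: str | None = None

    @property
    def rank(self) -> int:
        return _RANK[self.category]


def transcripts_from_gff(gff: str | Path) -> list:
    """Build :class:`TranscriptModel` objects from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(gff), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out = []
    for t in db.features_of_type(("mRNA", "transcript")):
        exons = [(f.start, f.end) for f in db.children(t, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(t, featuretype="CDS")]
        gene = list(db.parents(t, featuretype="gene"))
        gene_id = gene[0].id if gene else t.id
        if not exons:
            exons = cds[:]
        out.append(TranscriptModel(gene_id=gene_id, transcript_id=t.id,
                                   chrom=t.seqid, strand=t.strand,
                                   exons=exons, cds=cds))
    return out


def _genome_base(genome, chrom: str, pos: int) -> str:
    seq = genome[chrom]
    return str(seq[pos - 1: pos]).upper()


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    return str(genome[chrom][start - 1: end]).upper()


def _cds_sequence(t: TranscriptModel, genome) -> str:
    parts = [_fetch(genome, t.chrom, a, b) for a, b in t.cds]
    seq = "".join(parts)
    if t.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def _classify_transcript(t: TranscriptModel, pos: int, ref: str, alt: str,
                         genome) -> Consequence | None:
    if pos < t.start or pos > t.end:
        return None
    # essential splice region: 2 intronic bases flanking each junction
    for (a1, b1), (a2, b2) in zip(t.exons, t.exons[1:]):
        if b1 + 1 <= pos <= b1 + 2 or a2 - 2 <= pos <= a2 - 1:
            return Consequence("splice_site", t.gene_id, t.transcript_id)
    idx = t.cds_index(pos)
    if idx is not None:
        cds = _cds_sequence(t, genome)
        ref_c, alt_c = ref.upper(), alt.upper()
        if t.strand == "-":
            ref_c = ref_c.translate(_COMPLEMENT)
            alt_c = alt_c.translate(_COMPLEMENT)
        if cds[idx] != ref_c:
            raise DataConsistencyError(
                f"CDS base {cds[idx]} != ref {ref} at {t.chrom}:{pos} "
                f"({t.transcript_id})")
        ci = idx // 3
        codon = cds[3 * ci: 3 * ci + 3]
        mpos = idx % 3
        codon_alt = codon[:mpos] + alt_c + codon[mpos + 1:]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(codon_alt).translate())
        change = f"{codon}/{codon_alt}"
        if ci == 0 and aa_ref == "M" and aa_alt != "M":
            cat = "start_lost"
        elif aa_ref == "*" and aa_alt != "*":
            cat = "stop_lost"
        elif aa_alt == "*" and aa_ref != "*":
            cat = "stop_gained"
        elif aa_ref == aa_alt:
            cat = "synonymous"
        else:
            cat = "missense"
        return Consequence(cat, t.gene_id, t.transcript_id, change)
    if any(a <= pos <= b for a, b in t.exons):
        return Consequence("UTR", t.gene_id, t.transcript_id)
    return Consequence("intronic", t.gene_id, t.transcript_id)


def classify_snp(chrom: str, pos: int, ref: str, alt: str,
                 transcripts: Sequence[TranscriptModel],
                 genome: Mapping[str, object]) -> Consequence:
    """Most-severe consequence of a SNP across the supplied transcripts.

    ``genome`` maps chromosome name to a sliceable sequence (a dict of
    strings or a ``pyfaidx.Fasta``).  The genome base at ``pos`` must
    equal ``ref``.
    """
    base = _genome_base(genome, chrom, pos)
    if base != ref.upper():
        raise DataConsistencyError(
            f"reference mismatch at {chrom}:{pos}: genome {base}, ref {ref}")
    best: Consequence | None = None
    for t in transcripts:
        if t.chrom != chrom:
            continue
        c = _classify_transcript(t, pos, ref, alt, genome)
        if c is not None and (best is None or c.rank > best.rank):
            best = c
    return best if best is not None else Consequence("intergenic")


def tally(consequences: Sequence[Consequence]) -> pd.DataFrame:
    """Category counts and proportions, overall and within the coding set.

    The coding set is {synonymous, missense, stop_gained, stop_lost,
    start_lost, splice_site}; its proportions mirror the within-coding
    breakdown reported for divergent-line WGS scans.
    """
    cats = [c.category for c in consequences]
    rows = []
    n = len(cats)
    counts = pd.Series(cats, dtype=object).value_counts() if n else pd.Series(dtype=int)
    coding = {"synonymous", "missense", "stop_gained", "stop_lost",
              "start_lost", "splice_site"}
    n_coding = sum(counts.get(c, 0) for c in coding)
    for cat in SEVERITY:
        cnt = int(counts.get(cat, 0))
        rows.append({
            "category": cat,
            "count": cnt,
            "proportion": cnt / n if n else np.nan,
            "proportion_coding": (cnt / n_coding
                                  if cat in coding and n_coding else np.nan),
        })
    return pd.DataFrame(rows)
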