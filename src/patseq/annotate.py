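"""PAC annotation against a GFF3 gene model with extended 3'UTRs.

PAT-Seq cleavage sites frequently fall a short distance downstream of the
annotated transcript end, so every 3'UTR is extended by a fixed number of
nucleotides (default 120) in the transcription direction before assignment;
the extension is truncated where it would run into the next annotated gene
on the same strand. Each PAC is assigned at its representative position with
region precedence extended-3'UTR > CDS > 5'UTR > intron; positions hitting
no gene are intergenic. When extended gene footprints overlap, the gene
whose 3' end is nearest wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from intervaltree import IntervalTree

Interval = Tuple[int, int]  # 0-based half-open


class AnnotationError(ValueError):
    pass


@dataclass
class GeneModel:
    """One gene in internal 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: List[Interval] = field(default_factory=list)
    utr5: List[Interval] = field(default_factory=list)
    utr3: List[Interval] = field(default_factory=list)
    utr3_extended: List[Interval] = field(default_factory=list)
    introns: List[Interval] = field(default_factory=list)

    @property
    def three_prime_end(self) -> int:
        """Coordinate of the 3'-most transcribed base (transcription direction)."""
        return self.end - 1 if self.strand == "+" else self.start


def _merge(intervals: List[Interval]) -> List[Interval]:
    out: List[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(span: Interval, blocks: List[Interval]) -> List[Interval]:
    """span minus the union of blocks."""
    out, cur = [], span[0]
    for s, e in _merge(blocks):
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < span[1]:
        out.append((cur, span[1]))
    return out


def load_annotation(gff3_path, extension: int = 120) -> List[GeneModel]:
    """Parse GFF3 gene models and compute extended 3'UTRs.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Introns are derived as the gene span minus all exonic features. The
    3'UTR extension (``extension`` nt past the annotated UTR end in the
    transcription direction) is truncated at the nearest downstream gene on
    the same strand.
    """
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    models: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gm = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            start=gene.start - 1, end=gene.end,
        )
        exonic: List[Interval] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            for feat in db.children(mrna):
                iv = (feat.start - 1, feat.end)
                if feat.featuretype == "CDS":
                    gm.cds.append(iv)
                elif feat.featuretype == "five_prime_UTR":
                    gm.utr5.append(iv)
                elif feat.featuretype == "three_prime_UTR":
                    gm.utr3.append(iv)
                if feat.featuretype in ("CDS", "five_prime_UTR", "three_prime_UTR", "exon"):
                    exonic.append(iv)
        # features attached directly to the gene (annotation without mRNA level)
        for feat in db.children(gene, level=1):
            iv = (feat.start - 1, feat.end)
            if feat.featuretype == "CDS" and iv not in gm.cds:
                gm.cds.append(iv)
                exonic.append(iv)
            elif feat.featuretype == "five_prime_UTR" and iv not in gm.utr5:
                gm.utr5.append(iv)
                exonic.append(iv)
            elif feat.featuretype == "three_prime_UTR" and iv not in gm.utr3:
                gm.utr3.append(iv)
                exonic.append(iv)
        gm.cds = _merge(gm.cds)
        gm.utr5 = _merge(gm.utr5)
        gm.utr3 = _merge(gm.utr3)
        gm.introns = _subtract((gm.start, gm.end), exonic) if exonic else []
        models.append(gm)

    _extend_utr3(models, extension)
    return models


def _extend_utr3(models: List[GeneModel], extension: int) -> None:
    """Fill ``utr3_extended`` on every model, truncating at the next gene."""
    by_key: Dict[Tuple[str, str], List[GeneModel]] = {}
    for gm in models:
        by_key.setdefault((gm.chrom, gm.strand), []).append(gm)
    for (_, strand), group in by_key.items():
        group.sort(key=lambda g: g.start)
        for i, gm in enumerate(group):
            gm.utr3_extended = [iv for iv in gm.utr3]
            if not gm.utr3:
                continue
            if strand == "+":
                last = max(gm.utr3, key=lambda iv: iv[1])
                limit = last[1] + extension
                for other in group[i + 1:]:
                    if other.start >= last[1]:
                        limit = min(limit, other.start)
                        break
                ext = (last[1], limit)
            else:
                first = min(gm.utr3, key=lambda iv: iv[0])
                limit = first[0] - extension
                for other in reversed(group[:i]):
                    if other.end <= first[0]:
                        limit = max(limit, other.end)
                        break
                ext = (limit, first[0])
            if ext[1] > ext[0]:
                gm.utr3_extended = _merge(gm.utr3 + [ext])


REGIONS = ("3UTR", "CDS", "5UTR", "intron", "intergenic")


class AnnotationIndex:
    """Interval lookup over gene models, including the extended footprints."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = list(models)
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for gm in self.models:
            tree = self._trees.setdefault((gm.chrom, gm.strand), IntervalTree())
            lo, hi = gm.start, gm.end
            for s, e in gm.utr3_extended:
                lo, hi = min(lo, s), max(hi, e)
            tree.addi(lo, hi, gm)

    def assign(self, chrom: str, strand: str, position: int) -> Tuple[Optional[str], str]:
        """(gene_id, region) at a single position; (None, 'intergenic') if no hit."""
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return None, "intergenic"
        hits = [iv.data for iv in tree.at(position)]
        candidates = []
        for gm in hits:
            region = self._classify(gm, position)
            if region is not None:
                candidates.append((abs(position - gm.three_prime_end), gm.gene_id, region))
        if not candidates:
            return None, "intergenic"
        candidates.sort()  # nearest gene 3' end wins; gene_id breaks exact ties
        _, gene_id, region = candidates[0]
        return gene_id, region

    @staticmethod
    def _classify(gm: GeneModel, position: int) -> Optional[str]:
        def within(intervals: List[Interval]) -> bool:
            return any(s <= position < e for s, e in intervals)

        if within(gm.utr3_extended):
            return "3UTR"
        if within(gm.cds):
            return "CDS"
        if within(gm.utr5):
            return "5UTR"
        if gm.start <= position < gm.end:
            return "intron"
        return None


def annotate_pacs(pacs: pd.DataFrame, index: AnnotationIndex) -> pd.DataFrame:
    """Attach gene_id and region columns, assigned at the representative position."""
    gene_ids, regions = [], []
    for row in pacs.itertuples():
        gid, region = index.assign(row.chrom, row.strand, row.representative)
        gene_ids.append(gid)
        regions.append(region)
    out = pacs.copy()
    out["gene_id"] = gene_ids
    out["region"] = regions
    return out


def gene_counts(annotated_pacs: pd.DataFrame,
                samples: Sequence[str]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Sum PAC counts per gene; intergenic PACs are reported separately.

    Returns (gene_matrix, intergenic_pacs): the matrix is gene x sample with
    integer counts, and the conservation identity
    gene_matrix.sum() + intergenic[samples].sum() == annotated_pacs[samples].sum()
    holds by construction.
    """
    samples = list(samples)
    genic = annotated_pacs[annotated_pacs["gene_id"].notna()]
    intergenic = annotated_pacs[annotated_pacs["gene_id"].isna()].reset_index(drop=True)
    if len(genic) == 0:
        matrix = pd.DataFrame(columns=samples, dtype=int)
        matrix.index.name = "gene_id"
        return matrix, intergenic
    matrix = genic.groupby("gene_id", sort=True)[samples].sum()
    return matrix, intergenic
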