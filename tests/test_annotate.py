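"""GFF3 loading, 3'UTR extension, region assignment, gene-level counting."""

import numpy as np
import pandas as pd
import pytest

from patseq import (AnnotationIndex, PacParams, annotate_pacs, build_pas,
                    cluster_pas, filter_pacs, gene_counts, load_annotation)


def _write_gff(tmp_path, body):
    path = tmp_path / "test.gff3"
    path.write_text("##gff-version 3\n" + body)
    return str(path)


def _gene(chrom, gid, start, end, strand, utr5, cds, utr3):
    # coordinates given 0-based half-open; rendered 1-based inclusive
    rows = [
        f"{chrom}\tt\tgene\t{start+1}\t{end}\t.\t{strand}\t.\tID={gid}",
        f"{chrom}\tt\tmRNA\t{start+1}\t{end}\t.\t{strand}\t.\tID={gid}.1;Parent={gid}",
        f"{chrom}\tt\tfive_prime_UTR\t{utr5[0]+1}\t{utr5[1]}\t.\t{strand}\t.\tID={gid}.u5;Parent={gid}.1",
        f"{chrom}\tt\tCDS\t{cds[0]+1}\t{cds[1]}\t.\t{strand}\t0\tID={gid}.c;Parent={gid}.1",
        f"{chrom}\tt\tthree_prime_UTR\t{utr3[0]+1}\t{utr3[1]}\t.\t{strand}\t.\tID={gid}.u3;Parent={gid}.1",
    ]
    return "\n".join(rows) + "\n"


class TestExtension:
    def test_plus_strand_extension_arithmetic(self, tmp_path):
        gff = _write_gff(tmp_path, _gene("chr1", "g1", 100, 1000, "+",
                                         (100, 200), (200, 900), (900, 1000)))
        (gm,) = load_annotation(gff, extension=120)
        assert gm.utr3 == [(900, 1000)]
        assert gm.utr3_extended == [(900, 1120)]

    def test_minus_strand_extension_goes_upstream(self, tmp_path):
        gff = _write_gff(tmp_path, _gene("chr1", "g1", 500, 1400, "-",
                                         (1300, 1400), (600, 1300), (500, 600)))
        (gm,) = load_annotation(gff, extension=120)
        assert gm.utr3_extended == [(380, 600)]

    def test_extension_truncated_at_next_gene(self, tmp_path):
        body = _gene("chr1", "g1", 100, 1000, "+", (100, 200), (200, 900), (900, 1000))
        body += _gene("chr1", "g2", 1100, 2000, "+", (1100, 1200), (1200, 1900), (1900, 2000))
        gff = _write_gff(tmp_path, body)
        g1 = [m for m in load_annotation(gff, extension=120) if m.gene_id == "g1"][0]
        assert g1.utr3_extended == [(900, 1100)]

    def test_coordinate_round_trip(self, small_sim, small_gff):
        """GFF3 (1-based) -> internal 0-based -> matches the generating truth."""
        models = {m.gene_id: m for m in load_annotation(small_gff)}
        for g in small_sim["truth"].genes.itertuples():
            m = models[g.gene_id]
            assert (m.start, m.end) == (g.start, g.end)
            assert m.cds == [(g.cds_start, g.cds_end)]
            assert m.utr3 == [(g.utr3_start, g.utr3_end)]


class TestAssignRegion:
    @pytest.fixture()
    def index(self, tmp_path):
        body = _gene("chr1", "g1", 100, 1000, "+", (100, 200), (200, 900), (900, 1000))
        return AnnotationIndex(load_annotation(_write_gff(tmp_path, body)))

    @pytest.mark.parametrize(
        "position, gene, region",
        [
            (950, "g1", "3UTR"),      # inside annotated 3'UTR
            (1049, "g1", "3UTR"),     # 50 nt past the UTR end: inside extension
            (1119, "g1", "3UTR"),     # last extended base
            (1130, None, "intergenic"),  # 130 nt past the UTR end
            (500, "g1", "CDS"),
            (150, "g1", "5UTR"),
            (50, None, "intergenic"),
        ],
    )
    def test_precedence_and_extension(self, index, position, gene, region):
        assert index.assign("chr1", "+", position) == (gene, region)

    def test_wrong_strand_is_intergenic(self, index):
        assert index.assign("chr1", "-", 500) == (None, "intergenic")

    def test_unknown_chromosome_is_intergenic(self, index):
        assert index.assign("chrX", "+", 500) == (None, "intergenic")

    def test_overlapping_genes_resolved_by_nearest_three_prime_end(self, tmp_path):
        # g2 starts inside g1's 3'UTR, so g1's extension overlaps g2's CDS
        body = _gene("chr1", "g1", 100, 1100, "+", (100, 200), (200, 1000), (1000, 1100))
        body += _gene("chr1", "g2", 1050, 2100, "+", (1050, 1150), (1150, 2000), (2000, 2100))
        index = AnnotationIndex(load_annotation(_write_gff(tmp_path, body)))
        # 1160 is in g1's extension and g2's CDS; g1's 3' end (1099) is much
        # nearer than g2's (2099), so the extended-3'UTR call wins
        assert index.assign("chr1", "+", 1160) == ("g1", "3UTR")


@pytest.fixture(scope="module")
def annotated(small_sim, small_gff, sample_ids):
    pas = build_pas(small_sim["tags"], sample_ids)
    pacs, _ = filter_pacs(cluster_pas(pas, PacParams(), sample_ids), PacParams())
    index = AnnotationIndex(load_annotation(small_gff))
    return annotate_pacs(pacs, index)


class TestPipelineAnnotation:
    def test_every_pac_gets_one_region_label(self, annotated):
        assert annotated["region"].notna().all()
        assert set(annotated["region"]) <= {"3UTR", "CDS", "5UTR", "intron", "intergenic"}
        assert (annotated["gene_id"].isna() == (annotated["region"] == "intergenic")).all()

    def test_labels_match_planted_site_regions(self, annotated, small_sim):
        """Jitter-free PAC labels reproduce the planted region of each site."""
        sites = small_sim["truth"].sites.set_index(["chrom", "position"])
        for row in annotated.itertuples():
            planted = sites.loc[(row.chrom, row.representative)]
            assert planted["region"] == row.region
            if row.region != "intergenic":
                assert planted["gene_id"] == row.gene_id

    def test_gene_counts_conservation(self, annotated, sample_ids):
        matrix, intergenic = gene_counts(annotated, sample_ids)
        total = annotated[sample_ids].to_numpy().sum()
        assert (matrix.to_numpy().sum()
                + intergenic[sample_ids].to_numpy().sum()) == total

    def test_gene_counts_sum_pacs(self, annotated, sample_ids):
        matrix, _ = gene_counts(annotated, sample_ids)
        gid = annotated["gene_id"].dropna().iloc[0]
        expected = annotated[annotated["gene_id"] == gid][sample_ids].sum()
        assert (matrix.loc[gid] == expected).all()

    def test_all_intergenic_gives_empty_matrix(self, sample_ids):
        pacs = pd.DataFrame({
            "pac_id": ["PAC00001"], "chrom": ["chr1"], "strand": ["+"],
            "start": [10], "end": [11], "representative": [10],
            "n_sites": [1], "total": [12], "gene_id": [None],
            "region": ["intergenic"],
            **{s: [2] for s in sample_ids},
        })
        matrix, intergenic = gene_counts(pacs, sample_ids)
        assert matrix.empty and len(intergenic) == 1
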