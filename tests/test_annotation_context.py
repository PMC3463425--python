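import pandas as pd
import pytest

from crebox import (
    GeneContext,
    add_known_sites,
    assign_hits,
    cre_tss_distance,
    load_annotation,
)
from crebox.annotation_context import signed_offset, write_sites_tsv, _make_site
from crebox.genome_scan import MotifHit


def hit_at_g8(g8: int, strand: str = "+", contig: str = "genome") -> MotifHit:
    """A width-14 hit whose central G sits at 0-based coordinate g8."""
    start = g8 - 7 if strand == "+" else g8 - 6
    return MotifHit(contig, start, strand, "TGAAAGCGCTTTCA", 10.0, g8)


class TestLoadAnnotation:
    def test_tsv_with_tss_and_nd(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "gene_id\toperon_id\tstrand\tstart_codon\ttss\n"
            "geneX\topX\t+\t1000\t950\n"
            "geneY\topY\t-\t2000\tND\n"
        )
        ctxs = {c.gene_id: c for c in load_annotation(path)}
        assert ctxs["geneX"].tss == 949 and ctxs["geneX"].start_codon == 999
        assert ctxs["geneY"].tss is None

    def test_missing_columns_listed(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("gene_id\tstrand\n" "geneX\t+\n")
        with pytest.raises(ValueError, match="operon_id.*start_codon"):
            load_annotation(path)

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "gene_id\toperon_id\tstrand\tstart_codon\n"
            "geneX\topX\t+\t100\ngeneX\topY\t+\t200\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_annotation(path)

    def test_gff3_strands_and_first_gene(self, tmp_path):
        """Reverse-strand start codon is the feature end; the promoter-proximal
        gene of a multi-gene operon is kept."""
        path = tmp_path / "ann.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr\tsrc\tgene\t100\t400\t.\t+\t.\tID=gA;operon=op1;tss=80\n"
            "chr\tsrc\tgene\t500\t900\t.\t+\t.\tID=gB;operon=op1\n"
            "chr\tsrc\tgene\t2000\t2600\t.\t-\t.\tID=gC;operon=op2\n"
        )
        ctxs = {c.gene_id: c for c in load_annotation(path)}
        assert set(ctxs) == {"gA", "gC"}  # gB is not the operon first gene
        assert ctxs["gA"].start_codon == 99 and ctxs["gA"].tss == 79
        assert ctxs["gC"].start_codon == 2599  # end, in reading direction


class TestAssignHits:
    fwd = GeneContext("gF", "opF", "+", start_codon=999)
    rev = GeneContext("gR", "opR", "-", start_codon=999)

    @pytest.mark.parametrize(
        "gene,g8,expect_dist,kept",
        [
            ("fwd", 519, -480, True),   # interior of the window
            ("fwd", 498, -501, False),  # one base outside
            ("fwd", 1099, 100, True),   # downstream closed bound
            ("rev", 1029, -30, True),   # upstream of a reverse gene
            ("rev", 1500, -501, False),
        ],
    )
    def test_window_boundaries(self, gene, g8, expect_dist, kept):
        ctx = self.fwd if gene == "fwd" else self.rev
        sites = assign_hits([hit_at_g8(g8)], [ctx])
        if kept:
            assert len(sites) == 1 and sites[0].dist_start_codon == expect_dist
        else:
            assert sites == []
            assert signed_offset(g8, ctx.start_codon, ctx.strand) == expect_dist

    def test_one_hit_multiple_genes(self):
        divergent = [
            GeneContext("gL", "opL", "-", start_codon=980),
            GeneContext("gR2", "opR2", "+", start_codon=1060),
        ]
        sites = assign_hits([hit_at_g8(1000)], divergent)
        assert {s.gene_id for s in sites} == {"gL", "gR2"}

    def test_translation_invariance(self):
        """Shifting every coordinate by a constant changes no distance."""
        shift = 12345
        ctx = GeneContext("g", "op", "+", start_codon=999, tss=949)
        moved = GeneContext("g", "op", "+", start_codon=999 + shift, tss=949 + shift)
        a = assign_hits([hit_at_g8(970)], [ctx])[0]
        b = assign_hits([hit_at_g8(970 + shift)], [moved])[0]
        assert (a.dist_start_codon, a.dist_tss) == (b.dist_start_codon, b.dist_tss)

    def test_tss_offset_is_per_gene_constant(self):
        ctx = GeneContext("g", "op", "+", start_codon=999, tss=949)
        sites = assign_hits([hit_at_g8(960), hit_at_g8(1020)], [ctx])
        diffs = {s.dist_tss - s.dist_start_codon for s in sites}
        assert diffs == {50}  # the TSS-to-start-codon leader length


class TestKnownSites:
    ctx = GeneContext("iolA", "iolA", "+", start_codon=999, tss=949)

    def test_far_downstream_site_retained(self):
        table = pd.DataFrame(
            [{"gene_id": "iolA", "sequence": "TGAAAACGTTGTCA", "strand": "-", "g8_position": 3354}]
        )
        sites = add_known_sites(table, [self.ctx])
        assert sites[0].dist_tss == 2404  # far beyond +100, kept anyway
        assert sites[0].source == "literature"

    def test_duplicate_predicted_site_replaced(self):
        predicted = assign_hits([hit_at_g8(970)], [self.ctx])
        table = pd.DataFrame(
            [{"gene_id": "iolA", "sequence": "TGAAAACGTTGTCA", "strand": "+", "g8_position": 971}]
        )
        merged = add_known_sites(table, [self.ctx], predicted=predicted)
        assert len(merged) == 1 and merged[0].source == "literature"

    def test_sequence_only_site(self):
        table = pd.DataFrame([{"gene_id": "iolA", "sequence": "TGAAAACGTTGTCA", "strand": "+"}])
        site = add_known_sites(table, [self.ctx])[0]
        assert site.g8_position is None
        assert site.dist_tss is None and site.dist_start_codon is None

    def test_unknown_gene_rejected(self):
        table = pd.DataFrame([{"gene_id": "nope", "sequence": "A" * 14, "strand": "+"}])
        with pytest.raises(KeyError, match="nope"):
            add_known_sites(table, [self.ctx])


class TestTssDistance:
    @pytest.mark.parametrize(
        "strand,tss,g8,expect",
        [
            ("+", 949, 949, 0),    # central G at the TSS
            ("+", 949, 993, 44),   # downstream of a forward gene
            ("-", 949, 976, -27),  # genomically downstream = upstream in reading
        ],
    )
    def test_sign_convention(self, strand, tss, g8, expect):
        ctx = GeneContext("g", "op", strand, start_codon=999, tss=tss)
        site = _make_site(ctx, "TGAAAGCGCTTTCA", "+", g8, "predicted")
        assert cre_tss_distance(site) == expect

    def test_absent_tss_gives_none_not_zero(self):
        ctx = GeneContext("g", "op", "+", start_codon=999, tss=None)
        site = _make_site(ctx, "TGAAAGCGCTTTCA", "+", 999, "predicted")
        assert cre_tss_distance(site) is None


def test_sites_tsv_writes_nd(tmp_path):
    ctx = GeneContext("g", "op", "+", start_codon=999, tss=None)
    site = _make_site(ctx, "TGAAAGCGCTTTCA", "+", None, "literature")
    path = tmp_path / "sites.tsv"
    write_sites_tsv([site], path)
    fields = path.read_text().splitlines()[1].split("\t")
    assert fields[4] == "ND" and fields[6] == "ND"
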