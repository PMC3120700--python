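import numpy as np
import pytest

from hmboost.core import GeneModel, TagTrack
from hmboost.features import (
    body_features,
    classify_cpg,
    control_features,
    nucleosome_grid,
    promoter_features,
    regional_signal_density,
    to_relative,
)

from conftest import track_from


class TestNucleosomeGrid:
    def test_has_26_intervals(self):
        assert len(nucleosome_grid()) == 26

    @pytest.mark.parametrize(
        "index, interval",
        [
            (-2, (-370, -196)),
            (-1, (-195, -46)),
            (1, (-45, 134)),
            (2, (135, 314)),
            (3, (315, 494)),
            (4, (495, 674)),
            (5, (675, 859)),
        ],
    )
    def test_printed_anchor_positions(self, index, interval):
        assert nucleosome_grid().interval(index) == interval

    def test_extensions_are_150bp_abutting(self):
        g = nucleosome_grid()
        assert g.interval(-3) == (-520, -371)
        assert g.interval(6) == (860, 1009)
        for k in list(range(-6, -2)) + list(range(6, 21)):
            lo, hi = g.interval(k)
            assert hi - lo + 1 == 150
        # every interval abuts its neighbour with no gaps
        for (_, a), (b, _) in zip(g.intervals, g.intervals[1:]):
            assert b == a + 1

    def test_alternate_extent(self):
        g = nucleosome_grid(upstream=6, downstream=9)
        assert len(g) == 15
        assert g.indices[0] == -6 and g.indices[-1] == 9


class TestToRelative:
    def test_plus_strand(self, plus_gene):
        assert to_relative(plus_gene.tss + 5, plus_gene) == 5

    def test_minus_strand_mirrors(self, minus_gene):
        assert to_relative(minus_gene.tss - 5, minus_gene) == 5

    def test_tss_base_falls_in_plus1(self, plus_gene):
        rel = to_relative(plus_gene.tss, plus_gene)
        lo, hi = nucleosome_grid().interval(1)
        assert rel == 0 and lo <= rel <= hi


class TestClassifyCpg:
    def make_islands(self, *ivals):
        return {"chr1": np.asarray(ivals, dtype=np.int64).reshape(-1, 2)}

    def test_island_inside_window(self, plus_gene):
        assert classify_cpg(plus_gene, self.make_islands((99_900, 100_100)))

    def test_island_3kb_upstream_is_outside(self, plus_gene):
        assert not classify_cpg(plus_gene, self.make_islands((96_500, 96_900)))

    def test_one_bp_overlap_counts(self, plus_gene):
        # window is [tss-2000, tss+500]; island touching the downstream edge
        assert classify_cpg(plus_gene, self.make_islands((100_500, 100_900)))
        assert not classify_cpg(plus_gene, self.make_islands((100_501, 100_900)))

    def test_minus_strand_window_is_mirrored(self, minus_gene):
        # upstream of a minus gene is at higher coordinates: window
        # [tss-500, tss+2000] = [199500, 202000]
        assert classify_cpg(minus_gene, self.make_islands((201_500, 201_900)))
        assert not classify_cpg(minus_gene, self.make_islands((202_500, 202_900)))
        assert not classify_cpg(minus_gene, self.make_islands((198_900, 199_400)))


class TestPromoterFeatures:
    def test_no_tags_gives_zero_table(self, plus_gene):
        table = promoter_features([plus_gene], [track_from({"chr1": []})])
        assert (table.data.values == 0).all()
        assert table.data.shape == (1, 26)

    def test_single_tag_at_tss(self, plus_gene):
        table = promoter_features(
            [plus_gene], [track_from({"chr1": [plus_gene.tss]})]
        )
        row = table.data.loc[plus_gene.id]
        assert row["markA:+1"] == 1
        assert row.sum() == 1

    def test_tags_land_in_printed_nucleosomes(self, plus_gene):
        tss = plus_gene.tss
        track = track_from({"chr1": [tss - 200, tss - 100, tss + 700]})
        row = promoter_features([plus_gene], [track]).data.loc[plus_gene.id]
        assert row["markA:-2"] == 1
        assert row["markA:-1"] == 1
        assert row["markA:+5"] == 1
        assert row.sum() == 3

    def test_tag_conservation_against_brute_force(self, plus_gene, minus_gene,
                                                  uniform_track):
        """Summed nucleosome counts equal a direct scan of the promoter span."""
        grid = nucleosome_grid()
        table = promoter_features([plus_gene, minus_gene], [uniform_track], grid)
        for gene in (plus_gene, minus_gene):
            brute = sum(
                1
                for pos in uniform_track.tags["chr1"]
                if grid.span[0] <= to_relative(int(pos), gene) <= grid.span[1]
            )
            assert table.data.loc[gene.id].sum() == brute

    def test_strand_symmetry_under_genome_mirror(self, plus_gene, uniform_track):
        """Mirroring all coordinates and flipping strand leaves counts equal."""
        L = 1_000_000
        mirrored_gene = GeneModel(
            id=plus_gene.id, chrom="chr1", strand="-", tss=L + 1 - plus_gene.tss,
            exons=tuple((L + 1 - e, L + 1 - s) for s, e in plus_gene.exons),
        )
        mirrored_track = track_from(
            {"chr1": [L + 1 - int(p) for p in uniform_track.tags["chr1"]]}
        )
        orig = promoter_features([plus_gene], [uniform_track]).data
        mirr = promoter_features([mirrored_gene], [mirrored_track]).data
        assert (orig.values == mirr.values).all()

    def test_permutation_invariance(self, plus_gene, minus_gene, uniform_track):
        t2 = track_from({"chr1": [100_010, 199_800]}, mark="markB")
        a = promoter_features([plus_gene, minus_gene], [uniform_track, t2]).data
        b = promoter_features([minus_gene, plus_gene], [t2, uniform_track]).data
        assert (a.loc[b.index.sort_values()].values
                == b.loc[b.index.sort_values()].values).all()
        assert list(a.columns) == list(b.columns)

    def test_missing_chromosome_gives_zeros(self, plus_gene):
        table = promoter_features([plus_gene], [track_from({"chr9": [5]})])
        assert (table.data.values == 0).all()


class TestBodyFeatures:
    def test_zero_tags_zero_features(self, plus_gene):
        table = body_features([plus_gene], [track_from({"chr1": []})])
        assert (table.data.values == 0).all()
        assert table.data.shape == (1, 7)

    def test_exon_sum_and_density(self, plus_gene):
        # 10 tags uniformly inside the 1000-bp first exon
        tags = list(range(100_050, 100_999, 100))
        table = body_features([plus_gene], [track_from({"chr1": tags})])
        row = table.data.loc[plus_gene.id]
        assert row["markA:first_exon_sum"] == 10
        assert row["markA:first_exon_avg"] == pytest.approx(0.01)
        assert row["markA:body_sum"] == 10
        assert row["markA:body_avg"] == pytest.approx(10 / plus_gene.body_length)

    def test_first_intron_on_minus_strand(self, minus_gene):
        # minus gene: first intron is [197001, 199000] (between 5'-most exons)
        tags = [197_500, 198_000]
        row = body_features([minus_gene], [track_from({"chr1": tags})]).data.iloc[0]
        assert row["markA:first_intron_sum"] == 2
        assert row["markA:first_intron_avg"] == pytest.approx(2 / 2000)

    def test_intronless_gene_flagged_with_zero_intron_features(self):
        g = GeneModel("mono", "chr1", "+", 5_000, ((5_000, 6_999),))
        table = body_features([g], [track_from({"chr1": [5_500]})])
        assert table.data.loc["mono", "markA:first_intron_sum"] == 0
        assert "mono" in table.data.attrs["intronless"]

    def test_post_exon1_windows_truncate_at_transcript_end(self, plus_gene):
        """Body ends ~5 windows after exon 1; tags past it are not counted."""
        # first exon ends at 100999; transcript end 103999 -> post region
        # is [101000, 103999], shorter than 20*150=3000 only by truncation
        inside = [101_100, 102_000, 103_999]
        outside = [104_000, 105_000]
        row = body_features(
            [plus_gene], [track_from({"chr1": inside + outside})]
        ).data.iloc[0]
        assert row["markA:post_exon1_nuc_sum"] == 3


class TestControlFeatures:
    def test_anchor_is_50kb_upstream(self, plus_gene):
        # tag at the control anchor lands in the control +1 nucleosome
        anchor = plus_gene.tss - 50_000
        table = control_features([plus_gene], [track_from({"chr1": [anchor]})])
        assert table.region_kind == "control"
        assert table.data.loc[plus_gene.id, "markA:+1"] == 1

    def test_minus_strand_control_is_downstream_in_genomic_terms(self, minus_gene):
        anchor = minus_gene.tss + 50_000
        table = control_features([minus_gene], [track_from({"chr1": [anchor]})])
        assert table.data.loc[minus_gene.id, "markA:+1"] == 1

    def test_gene_too_close_to_chromosome_start_dropped(self):
        g = GeneModel("near", "chr1", "+", 10_000, ((10_000, 11_000),))
        table = control_features([g], [track_from({"chr1": []})])
        assert table.data.shape[0] == 0


class TestRegionalSignalDensity:
    def test_exonic_density(self, plus_gene):
        # 20 tags over the 2000 exonic bp
        tags = list(range(100_000, 100_999, 100)) + list(range(103_000, 103_999, 100))
        track = track_from({"chr1": tags})
        assert regional_signal_density(plus_gene, track, "exonic") == pytest.approx(0.01)

    def test_expression_control_halves_density(self, plus_gene):
        tags = list(range(100_000, 100_999, 100)) + list(range(103_000, 103_999, 100))
        track = track_from({"chr1": tags})
        d = regional_signal_density(plus_gene, track, "exonic", expression=2.0)
        assert d == pytest.approx(0.005)

    def test_empty_region_is_zero_density(self, plus_gene):
        track = track_from({"chr1": []})
        assert regional_signal_density(plus_gene, track, "intronic") == 0.0

    def test_zero_length_region_is_error(self):
        g = GeneModel("mono", "chr1", "+", 5_000, ((5_000, 6_999),))
        with pytest.raises(ValueError, match="zero-length"):
            regional_signal_density(g, track_from({"chr1": []}), "intronic")
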