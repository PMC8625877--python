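import numpy as np
import pytest
from scipy import stats as sps

from numtforge.characterize import (
    classify_position,
    flank_at,
    genes_of_origin,
    genome_at,
    length_histogram,
    pearson_test,
)
from numtforge.genome_io import (
    AnnotatedGenome,
    GeneModel,
    GenomicInterval,
    MitoGene,
    Mitogenome,
    Scaffold,
)
from numtforge.numt_detect import NumtRecord

from .oracles import pearson_oracle


def numt(scaf="s1", start=1000, end=1300, mito=((0, 300, "+"),), nid="N1"):
    return NumtRecord(
        numt_id=nid,
        locus=GenomicInterval(scaf, start, end, "."),
        mito_intervals=list(mito),
        best_evalue=1e-30,
        mean_identity=0.99,
        support_hits=1,
    )


class TestLengthHistogram:
    def _numts(self, lengths):
        return [numt(start=10_000 * i, end=10_000 * i + L, nid=f"N{i}")
                for i, L in enumerate(lengths)]

    def test_half_open_bin_assignment(self):
        hist = length_histogram(self._numts([150, 199, 200]), 200, 2000)
        counts = {lo: c for (lo, _hi, c) in hist}
        assert counts[0] == 2 and counts[200] == 1

    def test_tail_boundary(self):
        hist = length_histogram(self._numts([2000]), 200, 2000)
        assert hist[-1] == (2000, None, 1)

    def test_counts_sum_to_cohort_size(self):
        lengths = [100, 150, 350, 420, 1999, 2000, 5000]
        hist = length_histogram(self._numts(lengths), 200, 2000)
        assert sum(c for (_l, _h, c) in hist) == len(lengths)

    def test_empty_cohort_allowed(self):
        assert sum(c for (_l, _h, c) in length_histogram([], 200, 2000)) == 0

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            length_histogram([], 0, 2000)


@pytest.fixture()
def mito():
    return Mitogenome(
        sequence="A" * 2000,
        circular=True,
        genes=[
            MitoGene("COX1", "PCG", 100, 700),
            MitoGene("COX2", "PCG", 700, 1000),
            MitoGene("trnK", "tRNA", 1000, 1070),
        ],
    )


class TestGenesOfOrigin:
    def test_containment(self, mito):
        r = numt(mito=((200, 500, "+"),))
        assert genes_of_origin(r, mito) == [("COX1", 300)]

    def test_junction_spanning_interval_reports_both(self, mito):
        r = numt(mito=((600, 800, "+"),))
        out = dict(genes_of_origin(r, mito))
        assert out == {"COX1": 100, "COX2": 100}
        assert sum(out.values()) <= 200

    def test_non_pcg_only_source_is_empty(self, mito):
        r = numt(mito=((1000, 1070, "+"),))
        assert genes_of_origin(r, mito) == []

    def test_origin_wrap_is_modular(self, mito):
        # interval spanning the origin: [1900, 2150) -> [1900,2000)+[0,150)
        r = numt(mito=((1900, 2150, "+"),))
        assert genes_of_origin(r, mito) == [("COX1", 50)]

    def test_overlap_bookkeeping_never_exceeds_interval(self, mito):
        r = numt(mito=((0, 1200, "+"),))
        total = sum(ov for (_g, ov) in genes_of_origin(r, mito))
        assert total <= 1200


class TestFlankAt:
    def test_pure_at_upstream(self):
        seq = "AT" * 50 + "G" * 300 + "C" * 100
        g = AnnotatedGenome(scaffolds=[Scaffold("s1", seq)])
        p = flank_at(numt(start=100, end=400), g, flank=100)
        assert p.upstream_at == 1.0 and p.downstream_at == 0.0
        assert p.combined_at == 0.5 and p.upstream_len == 100

    def test_truncated_flank_uses_available_bases(self):
        seq = "A" * 40 + "G" * 200 + "T" * 500
        g = AnnotatedGenome(scaffolds=[Scaffold("s1", seq)])
        p = flank_at(numt(start=40, end=240), g, flank=100)
        assert p.upstream_len == 40 and p.upstream_at == 1.0

    def test_all_n_flank_is_undefined(self):
        seq = "N" * 100 + "G" * 100 + "A" * 100
        g = AnnotatedGenome(scaffolds=[Scaffold("s1", seq)])
        p = flank_at(numt(start=100, end=200), g, flank=100)
        assert p.upstream_at is None and p.downstream_at == 1.0

    def test_strandless_symmetry_under_reverse_complement(self):
        from numtforge.aligner import reverse_complement

        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        g = AnnotatedGenome(scaffolds=[Scaffold("s1", seq)])
        r = numt(start=600, end=900)
        p = flank_at(r, g, flank=100)
        g_rc = AnnotatedGenome(scaffolds=[Scaffold("s1", reverse_complement(seq))])
        L = len(seq)
        r_rc = numt(start=L - 900, end=L - 600)
        p_rc = flank_at(r_rc, g_rc, flank=100)
        assert p_rc.upstream_at == pytest.approx(p.downstream_at, abs=1e-12)
        assert p_rc.downstream_at == pytest.approx(p.upstream_at, abs=1e-12)


class TestGenomeAt:
    def test_basic_values(self):
        assert genome_at(AnnotatedGenome(scaffolds=[Scaffold("s", "ACGT")])) == 0.5
        assert genome_at(AnnotatedGenome(scaffolds=[Scaffold("s", "AATT")])) == 1.0

    def test_concatenation_invariance(self):
        a, b = "ACGTAAT", "GGCCATA"
        two = AnnotatedGenome(scaffolds=[Scaffold("x", a), Scaffold("y", b)])
        one = AnnotatedGenome(scaffolds=[Scaffold("z", a + b)])
        assert genome_at(two) == genome_at(one)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            genome_at(AnnotatedGenome(scaffolds=[Scaffold("s", "NNNN")]))


class TestClassifyPosition:
    @pytest.fixture()
    def genes(self):
        return [
            GeneModel("g1", "s1", "+", 10_000, 20_000,
                      exons=[(10_000, 12_000), (15_000, 20_000)]),
        ]

    def test_exonic_inside_exon(self, genes):
        pc = classify_position(numt(start=10_500, end=10_800), genes)
        assert pc.position_class == "exonic" and pc.distance_bp == 0
        assert pc.nearest_gene_id == "g1"

    def test_exon_intron_boundary_is_exonic(self, genes):
        pc = classify_position(numt(start=11_900, end=12_100), genes)
        assert pc.position_class == "exonic"

    def test_intronic(self, genes):
        pc = classify_position(numt(start=13_000, end=13_200), genes)
        assert pc.position_class == "intronic" and pc.distance_bp == 0

    def test_flank_inclusive_boundary_at_2000(self, genes):
        pc = classify_position(numt(start=22_000, end=22_300), genes)
        assert pc.position_class == "flank2kb" and pc.distance_bp == 2000
        pc2 = classify_position(numt(start=22_001, end=22_300), genes)
        assert pc2.position_class == "intergenic" and pc2.distance_bp == 2001

    def test_no_genes_on_scaffold(self):
        pc = classify_position(numt(start=100, end=200), [])
        assert pc.position_class == "intergenic"
        assert pc.nearest_gene_id is None and pc.distance_bp is None

    def test_total_over_cohort(self, small_dataset, small_detection):
        from numtforge.characterize import position_class_counts

        records, _ = small_detection
        counts = position_class_counts(records, small_dataset.genome.genes)
        assert sum(counts.values()) == len(records)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_test(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0) and res.p_value == pytest.approx(0.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 2.0], [3.0, 4.0])

    def test_fixed_eight_point_case_matches_textbook_oracle(self):
        x = [2.0, 4.0, 5.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        y = [10.0, 12.0, 10.0, 14.0, 13.0, 15.0, 14.0, 19.0]
        r_o, t_o, p_o = pearson_oracle(x, y)
        res = pearson_test(x, y)
        assert res.r == pytest.approx(r_o, abs=1e-12)
        assert res.t_stat == pytest.approx(t_o, abs=1e-12)
        assert res.p_value == pytest.approx(p_o, abs=1e-12)

    def test_random_instances_match_oracle_and_scipy(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.3 * x
            res = pearson_test(x, y)
            r_o, t_o, p_o = pearson_oracle(x, y)
            assert res.r == pytest.approx(r_o, abs=1e-12)
            assert res.p_value == pytest.approx(p_o, abs=1e-12)
            r_sp, p_sp = sps.pearsonr(x, y)
            assert res.r == pytest.approx(r_sp, abs=1e-10)
            assert res.p_value == pytest.approx(p_sp, abs=1e-10)
            assert res.r_squared == pytest.approx(res.r ** 2)
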