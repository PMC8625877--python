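import math

import numpy as np
import pytest
from scipy import stats as sps

from numtforge.characterize import genome_at
from numtforge.genome_io import mitogenome_summary
from numtforge.numt_detect import NumtRecord
from numtforge.genome_io import GenomicInterval
from numtforge.synthetic_data import (
    PlantedCopy,
    SimulationConfig,
    SimulationError,
    mutate_sequence,
    plant_numts,
    sample_insertion_sites,
    score_detection,
    simulate_mitogenome,
    simulate_nuclear_genome,
    simulate_transcriptome,
)

from .conftest import make_small_config


class TestSimulateMitogenome:
    def test_canonical_gene_content(self):
        mito = simulate_mitogenome(SimulationConfig(seed=1))
        s = mitogenome_summary(mito)
        assert (s["n_pcg"], s["n_rrna"], s["n_trna"]) == (13, 2, 22)
        assert mito.circular and mito.length == 16500

    def test_genes_tile_without_overlap(self):
        mito = simulate_mitogenome(SimulationConfig(seed=2))
        genes = sorted(mito.genes, key=lambda g: g.start)
        assert all(a.end <= b.start for a, b in zip(genes, genes[1:]))

    def test_at_content_near_eighty_percent(self):
        mito = simulate_mitogenome(SimulationConfig(seed=3))
        at = (mito.sequence.count("A") + mito.sequence.count("T")) / mito.length
        assert at == pytest.approx(0.80, abs=0.02)

    def test_deterministic_under_seed(self):
        a = simulate_mitogenome(SimulationConfig(seed=7))
        b = simulate_mitogenome(SimulationConfig(seed=7))
        assert a.sequence == b.sequence and a.genes == b.genes

    def test_too_short_to_tile_rejected(self):
        with pytest.raises(SimulationError):
            simulate_mitogenome(SimulationConfig(seed=1, mito_length=1000))


class TestSimulateNuclearGenome:
    def test_realized_at_close_to_target(self):
        cfg = SimulationConfig(seed=5, n_scaffolds=2, scaffold_length=1_000_000)
        g = simulate_nuclear_genome(cfg)
        assert genome_at(g) == pytest.approx(cfg.nuclear_at, abs=0.01)

    def test_gene_models_valid_by_construction(self):
        cfg = SimulationConfig(seed=6, n_scaffolds=1, scaffold_length=300_000)
        g = simulate_nuclear_genome(cfg)  # GeneModel validates on build
        assert len(g.genes) > 5
        per_scaf = sorted((gm.scaffold_id, gm.start, gm.end) for gm in g.genes)
        assert all(
            a[2] <= b[1] or a[0] != b[0] for a, b in zip(per_scaf, per_scaf[1:])
        ), "genes must not overlap"

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=8, n_scaffolds=1, scaffold_length=100_000)
        a = simulate_nuclear_genome(cfg)
        b = simulate_nuclear_genome(cfg)
        assert a.scaffolds[0].sequence == b.scaffolds[0].sequence
        assert a.genes == b.genes


class TestMutateSequence:
    def test_zero_rates_identity(self):
        seq = "ACGT" * 100
        assert mutate_sequence(seq, 0.0, 0.0, seed=1) == seq

    def test_forced_substitution_changes_every_base(self):
        seq = "ACGT" * 250
        out = mutate_sequence(seq, 1.0, 0.0, seed=2)
        assert len(out) == len(seq)
        assert all(a != b for a, b in zip(seq, out))

    def test_realized_substitution_fraction_within_binomial_bound(self):
        seq = mutate_sequence("A" * 10_000, 0.0, 0.0, seed=0)  # plain sequence
        bound = 3 * math.sqrt(0.02 * 0.98 / 10_000)
        for seed in range(30):
            out = mutate_sequence(seq, 0.02, 0.0, seed=seed)
            frac = sum(a != b for a, b in zip(seq, out)) / len(seq)
            assert abs(frac - 0.02) < bound

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACGT", 1.5, 0.0)


class TestInsertionSites:
    def test_unbiased_sites_match_background_at_distribution(self):
        cfg = SimulationConfig(seed=10, n_scaffolds=2, scaffold_length=2_000_000)
        g = simulate_nuclear_genome(cfg)
        rng = np.random.default_rng(11)
        sites = sample_insertion_sites(
            g, 1000, beta=0.0, rng=rng, min_separation=500
        )
        at_sites = _window_at(g, sites, 200)
        # independent uniform draws from the same candidate universe
        uni = [
            (g.scaffolds[i].id, int(p))
            for i, p in zip(
                rng.integers(0, 2, 1000),
                rng.integers(1000, 2_000_000 - 1000, 1000),
            )
        ]
        at_uni = _window_at(g, uni, 200)
        ks = sps.ks_2samp(at_sites, at_uni)
        assert ks.pvalue > 0.01

    def test_biased_sites_prefer_at_rich_windows(self):
        cfg = SimulationConfig(seed=12, n_scaffolds=1, scaffold_length=1_000_000)
        g = simulate_nuclear_genome(cfg)
        hits = 0
        for seed in range(10):
            sites = sample_insertion_sites(
                g, 40, beta=4.0, rng=np.random.default_rng(seed), min_separation=1000
            )
            if np.mean(_window_at(g, sites, 200)) > genome_at(g):
                hits += 1
        assert hits >= 9

    def test_impossible_placement_rejected(self):
        cfg = SimulationConfig(seed=13, n_scaffolds=1, scaffold_length=50_000)
        g = simulate_nuclear_genome(cfg)
        with pytest.raises(SimulationError):
            sample_insertion_sites(g, 1000, beta=0.0, rng=np.random.default_rng(1))


def _window_at(genome, sites, window):
    out = []
    for sid, pos in sites:
        seq = genome.scaffold(sid).sequence[pos - window // 2 : pos + window // 2]
        out.append((seq.count("A") + seq.count("T")) / max(len(seq), 1))
    return out


class TestPlantNumts:
    def test_degenerate_weights_all_sources_overlap_cox1(self):
        cfg = make_small_config(
            seed=14, gene_weights={"COX1": 1.0}, n_numts=8
        )
        mito = simulate_mitogenome(cfg)
        genome = simulate_nuclear_genome(cfg)
        _planted, truth = plant_numts(genome, mito, cfg)
        cox1 = next(g for g in mito.genes if g.name == "COX1")
        for t in truth:
            segs = (
                [(t.source_start, t.source_end)]
                if t.source_end <= mito.length
                else [(t.source_start, mito.length), (0, t.source_end - mito.length)]
            )
            assert any(a < cox1.end and cox1.start < b for (a, b) in segs)

    def test_sites_respect_end_distance_and_separation(self, small_dataset):
        ds = small_dataset
        by_scaf = {}
        for t in ds.truth:
            L = ds.genome.scaffold(t.site.scaffold_id).length
            assert t.site.start >= 1000 and t.site.end <= L - 900
            by_scaf.setdefault(t.site.scaffold_id, []).append(t)
        for group in by_scaf.values():
            group.sort(key=lambda t: t.site.start)
            assert all(
                b.site.start >= a.site.end for a, b in zip(group, group[1:])
            ), "planted sites must not overlap"

    def test_planted_sequence_present_at_truth_coordinates(self, small_dataset):
        ds = small_dataset
        t = ds.truth[0]
        seq = ds.genome.scaffold(t.site.scaffold_id).sequence
        assert len(seq) > t.site.end
        assert t.realized_length == t.site.end - t.site.start

    def test_gene_models_survive_coordinate_lifting(self, small_dataset):
        # AnnotatedGenome construction re-validates every lifted gene; also
        # check exon sequences away from insertions are preserved
        ds = small_dataset
        assert len(ds.genome.genes) > 0
        for g in ds.genome.genes:
            assert g.start < g.end
            for (a, b) in g.exons:
                assert g.start <= a < b <= g.end


class TestTranscriptome:
    def test_chimeric_transcripts_contain_numt_and_flanks(self, small_dataset):
        ds = small_dataset
        tx = {t.id: t.sequence for t in ds.transcripts}
        for t in ds.truth:
            for tx_id in t.chimeric_transcript_ids:
                scaf = ds.genome.scaffold(t.site.scaffold_id)
                expected = scaf.sequence[t.site.start - 60 : t.site.end + 60]
                assert tx[tx_id] == expected

    def test_decoys_are_verbatim_mito_segments(self, small_dataset):
        ds = small_dataset
        doubled = ds.mito.sequence * 2
        for t in ds.transcripts:
            if t.id.startswith("TX_MITO"):
                assert t.sequence in doubled

    def test_chimeras_require_truth(self):
        cfg = make_small_config(seed=15)
        mito = simulate_mitogenome(cfg)
        genome = simulate_nuclear_genome(cfg)
        with pytest.raises(SimulationError):
            simulate_transcriptome(genome, [], mito, cfg)


class TestScoreDetection:
    def _truth(self, scaf, start, end, pid="P1"):
        return PlantedCopy(
            plant_id=pid,
            site=GenomicInterval(scaf, start, end, "+"),
            source_start=0,
            source_end=end - start,
            source_strand="+",
            realized_length=end - start,
            divergence_applied=0.0,
        )

    def _rec(self, scaf, start, end, nid="N1"):
        return NumtRecord(
            numt_id=nid,
            locus=GenomicInterval(scaf, start, end, "."),
            mito_intervals=[(0, end - start, "+")],
            best_evalue=1e-30,
            mean_identity=1.0,
            support_hits=1,
        )

    def test_reciprocal_overlap_matching(self):
        truth = [self._truth("s1", 1000, 1400)]
        recs = [self._rec("s1", 1100, 1450)]
        sc = score_detection(recs, truth)
        assert sc["n_matched"] == 1 and sc["sensitivity"] == 1.0

    def test_insufficient_overlap_rejected(self):
        truth = [self._truth("s1", 1000, 2000)]
        recs = [self._rec("s1", 1900, 2100)]  # covers 10% of truth
        sc = score_detection(recs, truth)
        assert sc["n_matched"] == 0 and sc["precision"] == 0.0

    def test_one_to_one_matching(self):
        truth = [self._truth("s1", 1000, 1400, "P1")]
        recs = [self._rec("s1", 1000, 1400, "N1"), self._rec("s1", 1010, 1400, "N2")]
        sc = score_detection(recs, truth)
        assert sc["n_matched"] == 1 and sc["precision"] == 0.5
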