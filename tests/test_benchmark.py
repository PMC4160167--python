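import numpy as np
import pytest

from motifsieve import (
    ALPHABET,
    BenchmarkConfig,
    MotifStats,
    YEAST_AA_FREQS,
    build_benchmark,
    canonical_mask,
    count_in_background,
    derive_motifs,
    evaluate_topmotif_accuracy,
    generate_masks,
    generate_synthetic_proteome,
    read_fasta,
    read_manifest,
    realize_spiked_set,
    spike_motif,
)
from motifsieve.benchmark import _freq_vector


class TestSyntheticProteome:
    def test_deterministic_for_fixed_seed(self):
        a = generate_synthetic_proteome(50, (100, 500), seed=1)
        b = generate_synthetic_proteome(50, (100, 500), seed=1)
        assert [r.residues for r in a] == [r.residues for r in b]
        assert a.ids() == b.ids()

    def test_lengths_within_bounds(self):
        seqs = generate_synthetic_proteome(200, (100, 500), seed=2)
        assert len(seqs) == 200
        assert all(100 <= len(r) <= 500 for r in seqs)

    def test_empirical_frequencies_track_the_target(self):
        # ~10^5 residues: empirical composition within 1% absolute
        seqs = generate_synthetic_proteome(350, (100, 500), seed=3)
        joined = "".join(r.residues for r in seqs)
        assert len(joined) > 90_000
        freqs = _freq_vector(None)
        for i, aa in enumerate(ALPHABET):
            assert abs(joined.count(aa) / len(joined) - freqs[i]) < 0.01

    def test_invalid_frequency_vector_rejected(self):
        bad = np.full(20, 0.06)  # sums to 1.2
        with pytest.raises(ValueError, match="frequency"):
            generate_synthetic_proteome(5, (10, 20), aa_freqs=bad, seed=1)

    def test_frequency_table_is_normalized(self):
        assert sum(YEAST_AA_FREQS.values()) == pytest.approx(1.0, abs=2e-3)
        assert _freq_vector(None).sum() == pytest.approx(1.0, abs=1e-12)


class TestMasks:
    def test_full_grid_has_36_masks(self):
        assert len(generate_masks(range(3, 11))) == 36

    def test_single_length_count(self):
        masks = generate_masks([10])
        assert len(masks) == 8  # d = 3..10

    def test_ends_always_defined(self):
        for mask in generate_masks(range(3, 11)):
            assert mask.bits[0] == 1 and mask.bits[-1] == 1
            assert 3 <= mask.d <= mask.n

    def test_canonical_layout(self):
        assert canonical_mask(6, 4).bits == (1, 1, 1, 0, 0, 1)
        with pytest.raises(ValueError):
            canonical_mask(5, 2)


class TestDeriveMotifs:
    def test_distinct_patterns_with_mask_dimensions(self):
        mask = canonical_mask(10, 3)
        motifs = derive_motifs(mask, replicates=30, seed=5)
        patterns = [str(m) for m in motifs]
        assert len(set(patterns)) == 30
        for m in motifs:
            assert (m.n, m.d) == (10, 3)
            assert m.pattern[0] != "." and m.pattern[-1] != "."

    def test_fully_defined_mask_yields_exact_kmers(self):
        motifs = derive_motifs(canonical_mask(6, 6), replicates=30, seed=6)
        assert all(m.w == 0 for m in motifs)

    def test_interior_layout_is_shuffled(self):
        motifs = derive_motifs(canonical_mask(10, 4), replicates=30, seed=7)
        layouts = {tuple(i for i, c in enumerate(str(m)) if c != ".") for m in motifs}
        assert len(layouts) > 1  # not all replicates share one layout

    def test_deterministic_per_seed(self):
        a = derive_motifs(canonical_mask(7, 5), replicates=10, seed=8)
        b = derive_motifs(canonical_mask(7, 5), replicates=10, seed=8)
        assert [str(m) for m in a] == [str(m) for m in b]

    def test_exhausted_pattern_space_is_an_error(self):
        with pytest.raises(ValueError, match="space"):
            derive_motifs(canonical_mask(3, 3), replicates=8001, seed=9)


class TestSpikeMotif:
    def _base(self):
        return generate_synthetic_proteome(20, (30, 60), seed=10)

    def test_exactly_n_records_modified_each_matching(self):
        from motifsieve import MotifPattern, match_pattern

        base = self._base()
        motif = MotifPattern("K.LW.R")
        spiked = spike_motif(base, motif, 5, seed=11)
        changed = [
            (a, b) for a, b in zip(base, spiked) if a.residues != b.residues
        ]
        assert len(changed) == 5
        for _, rec in changed:
            assert match_pattern(motif, rec)

    def test_conserves_ids_lengths_and_order(self):
        base = self._base()
        spiked = spike_motif(base, "K.LW.R", 7, seed=12)
        assert spiked.ids() == base.ids()
        assert [len(r) for r in spiked] == [len(r) for r in base]

    def test_zero_spikes_is_identity(self):
        base = self._base()
        spiked = spike_motif(base, "K.LW.R", 0, seed=13)
        assert [r.residues for r in spiked] == [r.residues for r in base]

    def test_overfull_spike_is_an_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            spike_motif(self._base(), "K.LW.R", 21, seed=14)

    def test_deterministic_per_seed(self):
        base = self._base()
        a = spike_motif(base, "K.LW.R", 5, seed=15)
        b = spike_motif(base, "K.LW.R", 5, seed=15)
        assert [r.residues for r in a] == [r.residues for r in b]

    def test_truth_recoverable_by_scanning(self):
        # scanning the spiked set with the ground-truth pattern finds
        # at least N carriers (chance matches may add more)
        base = generate_synthetic_proteome(100, (100, 300), seed=16)
        counts = count_in_background(
            ["K.LW.R"], spike_motif(base, "K.LW.R", 12, seed=17))
        assert counts["K.LW.R"] >= 12


class TestBuildBenchmark:
    def test_scaled_config_cardinality(self):
        background = generate_synthetic_proteome(30, (50, 80), seed=18)
        config = BenchmarkConfig(lengths=(6,), occurrences=(5, 10),
                                 replicates=2, set_size=10)
        manifest = build_benchmark(config, background, seed=19)
        assert len(manifest) == 4 * 2 * 2  # length 6 has 4 masks

    def test_manifest_is_deterministic(self):
        background = generate_synthetic_proteome(30, (50, 80), seed=18)
        config = BenchmarkConfig(lengths=(5,), occurrences=(4,),
                                 replicates=2, set_size=10)
        assert build_benchmark(config, background, 20) == build_benchmark(
            config, background, 20)

    def test_insufficient_background_is_an_error(self):
        background = generate_synthetic_proteome(5, (50, 80), seed=21)
        config = BenchmarkConfig(lengths=(5,), occurrences=(3,),
                                 replicates=1, set_size=10)
        with pytest.raises(ValueError, match="background"):
            build_benchmark(config, background, 22)

    def test_materialized_sets_round_trip(self, tmp_path):
        background = generate_synthetic_proteome(30, (50, 80), seed=23)
        config = BenchmarkConfig(lengths=(4,), occurrences=(3,),
                                 replicates=1, set_size=10)
        manifest = build_benchmark(config, background, 24, out_dir=tmp_path)
        again = read_manifest(tmp_path / "manifest.tsv")
        assert again == manifest
        for entry in manifest:
            query = read_fasta(entry.query_path)
            per_bg = read_fasta(entry.background_path)
            assert len(query) == 10 and len(per_bg) == 30
            bg_by_id = {r.id: r.residues for r in per_bg}
            for rec in query:  # query is a subset of its background
                assert bg_by_id[rec.id] == rec.residues

    def test_realized_set_matches_manifest_seed(self):
        background = generate_synthetic_proteome(30, (50, 80), seed=23)
        config = BenchmarkConfig(lengths=(4,), occurrences=(3,),
                                 replicates=1, set_size=10)
        manifest = build_benchmark(config, background, 24)
        entry = manifest[0]
        q1, _ = realize_spiked_set(background, entry.pattern, entry.N, 10, entry.seed)
        q2, _ = realize_spiked_set(background, entry.pattern, entry.N, 10, entry.seed)
        assert [r.residues for r in q1] == [r.residues for r in q2]
        assert count_in_background([entry.pattern], q1)[entry.pattern] >= entry.N


class TestAccuracyReport:
    def _manifest_and_results(self, corrects):
        from motifsieve import SpikeManifest

        manifest, results = [], {}
        for i, correct in enumerate(corrects):
            sid = f"set{i}"
            manifest.append(SpikeManifest(
                set_id=sid, pattern="A.CD", n=4, d=3, N=5, replicate=i + 1, seed=i))
            top = "A.CD" if correct else "WXYZ"
            results[sid] = [MotifStats(top, 5, 5, 10, 100, 2, 1e-6, 2e-6)]
        return manifest, results

    def test_accuracy_fractions(self):
        manifest, results = self._manifest_and_results([True, False, True, True])
        report = evaluate_topmotif_accuracy(results, manifest)
        assert report.accuracy(4, 3, 5) == pytest.approx(0.75)
        assert report.overall() == pytest.approx(0.75)

    def test_all_and_none_correct(self):
        manifest, results = self._manifest_and_results([True, True])
        assert evaluate_topmotif_accuracy(results, manifest).accuracy(4, 3, 5) == 1.0
        manifest, results = self._manifest_and_results([False, False])
        assert evaluate_topmotif_accuracy(results, manifest).accuracy(4, 3, 5) == 0.0

    def test_empty_result_list_counts_as_incorrect(self):
        manifest, results = self._manifest_and_results([True])
        results[manifest[0].set_id] = []
        assert evaluate_topmotif_accuracy(results, manifest).overall() == 0.0

    def test_missing_result_is_an_error(self):
        manifest, results = self._manifest_and_results([True])
        del results[manifest[0].set_id]
        with pytest.raises(ValueError, match="no result"):
            evaluate_topmotif_accuracy(results, manifest)

    def test_frame_columns(self):
        manifest, results = self._manifest_and_results([True, False])
        frame = evaluate_topmotif_accuracy(results, manifest).to_frame()
        assert list(frame.columns) == ["n", "d", "N", "correct", "replicates", "accuracy"]
        assert frame.loc[0, "correct"] == 1 and frame.loc[0, "replicates"] == 2
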