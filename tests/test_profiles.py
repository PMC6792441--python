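import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cluster import KMeans

from fragmito import seqcore as sc
from fragmito.profiles import (ProfileError, assembly_stats,
                               canonical_tetramers, classify_contigs,
                               gc_content, tetra_profile)
from fragmito.simulate import random_background
from fragmito.som import train_som
from _oracles import n50_oracle

DNA = st.text(alphabet="ACGT", min_size=4, max_size=80)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GCGC", 1.0), ("ATAT", 0.0), ("GATCN", 0.5), ("ACGT", 0.5),
    ])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_all_n_undefined(self):
        with pytest.raises(ProfileError):
            gc_content("NNNN")


class TestAssemblyStats:
    def test_single_contig(self):
        s = assembly_stats({"a": "A" * 1000})
        assert s.n50 == 1000 and s.total_bp == 1000

    def test_small_example(self):
        s = assembly_stats({k: "A" * n for k, n in
                            zip("abcd", (1, 1, 1, 7))})
        assert s.n50 == 7

    def test_length_classes(self):
        s = assembly_stats({"a": "A" * 500, "b": "A" * 500, "c": "A" * 1000})
        assert s.bp_ge_1000 == 1000 and s.n_under_1000 == 2

    def test_n50_matches_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            lengths = rng.integers(1, 5000, size=rng.integers(1, 40))
            contigs = {f"c{i}": "A" * int(L) for i, L in enumerate(lengths)}
            assert assembly_stats(contigs).n50 == n50_oracle(lengths.tolist())

    def test_coverage_summary(self):
        s = assembly_stats({"a": "ACGT", "b": "ACGT"}, {"a": 10.0, "b": 20.0})
        assert s.mean_coverage == 15.0


class TestTetraProfile:
    def test_homopolymer(self):
        p = tetra_profile("AAAA")
        keys = canonical_tetramers()
        assert p.freqs[keys.index("AAAA")] == 1.0
        assert p.freqs.sum() == pytest.approx(1.0)

    def test_canonical_key_count(self):
        # oracle: enumerate 256 4-mers, collapse with reverse complements
        import itertools
        kmers = {"".join(p) for p in itertools.product("ACGT", repeat=4)}
        classes = {min(k, sc.reverse_complement(k)) for k in kmers}
        assert len(classes) == 136
        assert canonical_tetramers() == sorted(classes)

    @settings(deadline=None)
    @given(DNA)
    def test_reverse_complement_invariance(self, seq):
        a = tetra_profile(seq).freqs
        b = tetra_profile(sc.reverse_complement(seq)).freqs
        assert np.array_equal(a, b)

    def test_n_windows_skipped(self):
        p1 = tetra_profile("ACGTACGT")
        p2 = tetra_profile("ACGTACGT" + "N" + "TTTT")
        assert p2.freqs[canonical_tetramers().index("AAAA")] > 0
        assert p2.freqs.sum() == pytest.approx(1.0)
        assert p1.freqs.sum() == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ProfileError):
            tetra_profile("ACG")
        with pytest.raises(ProfileError):
            tetra_profile("ACNGT"[:5])  # no N-free window


@pytest.fixture(scope="module")
def two_cluster_profiles():
    rng = np.random.default_rng(0)
    seqs = [random_background(2000, 0.36, rng, 0.5) for _ in range(100)]
    seqs += [random_background(2000, 0.46, rng) for _ in range(100)]
    labels = np.array([0] * 100 + [1] * 100)
    profs = [tetra_profile(s, str(i)) for i, s in enumerate(seqs)]
    return profs, labels


class TestSom:
    def test_deterministic(self, two_cluster_profiles):
        profs, _ = two_cluster_profiles
        g1 = train_som(profs[:50], 6, 4, epochs=3, seed=5)
        g2 = train_som(profs[:50], 6, 4, epochs=3, seed=5)
        assert np.array_equal(g1.weights, g2.weights)

    def test_single_profile_converges(self, two_cluster_profiles):
        profs, _ = two_cluster_profiles
        rep = [profs[0]] * 30
        grid = train_som(rep, 4, 3, epochs=20, seed=0)
        assert grid.quantization_error(rep) < 1e-3

    def test_quantization_error_improves_with_epochs(self,
                                                     two_cluster_profiles):
        profs, _ = two_cluster_profiles
        qe = [train_som(profs, 10, 8, epochs=e, seed=0).quantization_error(profs)
              for e in (2, 4, 8)]
        assert qe[1] <= qe[0] and qe[2] <= qe[1]

    def test_two_clusters_split_with_kmeans_agreement(self,
                                                      two_cluster_profiles):
        profs, labels = two_cluster_profiles
        grid = train_som(profs, 10, 8, epochs=10, seed=0)
        bmus = np.array(grid.best_matching_units(profs))
        # majority-vote purity of SOM nodes
        purity_hits = 0
        for node in np.unique(bmus):
            members = labels[bmus == node]
            purity_hits += max((members == 0).sum(), (members == 1).sum())
        assert purity_hits / len(labels) >= 0.95
        # independent oracle: k-means on the same profiles
        X = np.array([p.freqs for p in profs])
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        agree = max((km.labels_ == labels).mean(),
                    (km.labels_ != labels).mean())
        assert agree >= 0.95

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            train_som([], 4, 4)


class TestClassifyContigs:
    def _toy_assembly(self):
        rng = np.random.default_rng(1)
        contigs = {f"n{i}": random_background(2000, 0.457, rng)
                   for i in range(12)}
        coverage = {c: 41.6 for c in contigs}
        contigs["m1"] = random_background(2000, 0.361, rng)
        coverage["m1"] = 196.0
        return contigs, coverage

    def test_paper_style_contig_is_candidate(self):
        contigs, coverage = self._toy_assembly()
        calls = {c.contig_id: c for c in classify_contigs(contigs, coverage)}
        assert calls["m1"].label == "organellar-candidate"
        assert calls["m1"].coverage_fold > 3

    def test_median_coverage_assembly_gc_is_nuclear(self):
        contigs, coverage = self._toy_assembly()
        calls = {c.contig_id: c for c in classify_contigs(contigs, coverage)}
        assert calls["n3"].label == "nuclear"

    def test_one_criterion_is_ambiguous(self):
        contigs, coverage = self._toy_assembly()
        coverage["n0"] = 500.0  # high coverage, nuclear GC
        calls = {c.contig_id: c for c in classify_contigs(contigs, coverage)}
        assert calls["n0"].label == "ambiguous"

    def test_missing_coverage_names_contig(self):
        contigs, coverage = self._toy_assembly()
        del coverage["n5"]
        with pytest.raises(ProfileError, match="n5"):
            classify_contigs(contigs, coverage)

    def test_recovery_on_default_simulation(self, sim_default):
        contigs, coverage, man = sim_default
        calls = classify_contigs(contigs, coverage)
        truth = {c for c, b in man.bins.items() if b == "mitochondrial"}
        pred = {c.contig_id for c in calls
                if c.label == "organellar-candidate"}
        tp = len(pred & truth)
        assert tp / len(pred) >= 0.95
        assert tp / len(truth) >= 0.95

    def test_seed_ids_admit_via_som(self, sim_default):
        contigs, coverage, man = sim_default
        truth = {c for c, b in man.bins.items() if b == "mitochondrial"}
        seeds = set(sorted(truth)[:8])
        calls = classify_contigs(contigs, coverage, seed_ids=seeds)
        pred = {c.contig_id for c in calls
                if c.label == "organellar-candidate"}
        base = {c.contig_id for c in classify_contigs(contigs, coverage)
                if c.label == "organellar-candidate"}
        assert pred >= base  # SOM admission only ever adds candidates
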