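import dataclasses
import json

import numpy as np
import pytest

from fragmito import io as fio
from fragmito import seqcore as sc
from fragmito.profiles import gc_content
from fragmito.simulate import (SimConfig, SimConfigError, TruthManifest,
                               fragment_gene, plant_u_appendage,
                               random_background, random_protein,
                               simulate_assembly, u_junction_residue_span)


class TestSimConfig:
    def test_validation_names_field(self):
        with pytest.raises(SimConfigError, match="mito_gc"):
            SimConfig(mito_gc=1.5).validate()
        with pytest.raises(SimConfigError, match="n_mito_contigs"):
            SimConfig(n_mito_contigs=-1).validate()
        with pytest.raises(SimConfigError, match="modules_per_gene"):
            SimConfig(modules_per_gene=(3, 13)).validate()


class TestDeterminism:
    def test_byte_identical_runs(self):
        cfg = SimConfig(seed=11, n_nuclear_contigs=20, n_mito_contigs=4,
                        n_cassette_only=4)
        out1 = simulate_assembly(cfg)
        out2 = simulate_assembly(dataclasses.replace(cfg))
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]
        assert json.dumps(dataclasses.asdict(out1[2]), sort_keys=True) == \
            json.dumps(dataclasses.asdict(out2[2]), sort_keys=True)


class TestEmptyMito:
    def test_no_mito_all_nuclear(self):
        cfg = SimConfig(seed=1, n_mito_contigs=0, n_cassette_only=0,
                        intron_rate=0, n_nuclear_genes=0,
                        n_nuclear_contigs=30, include_u1=False,
                        ref_proteins=[])
        contigs, cov, man = simulate_assembly(cfg)
        assert set(man.bins.values()) == {"nuclear"}
        assert man.modules == [] and man.introns == []
        assert set(cov) == set(contigs)


class TestComposition:
    def test_bin_gc_within_tolerance(self):
        # ~200 kb per bin; realized GC recomputed from the emitted contigs
        cfg = SimConfig(seed=3, n_nuclear_contigs=100,
                        nuclear_len_range=(1800, 2200),
                        n_mito_contigs=8, n_cassette_only=120,
                        intron_rate=0, n_nuclear_genes=0, include_u1=False)
        contigs, _, man = simulate_assembly(cfg)
        mito = "".join(contigs[c] for c, b in man.bins.items()
                       if b == "mitochondrial")
        nuc = "".join(contigs[c] for c, b in man.bins.items()
                      if b == "nuclear")
        assert len(mito) > 150_000 and len(nuc) > 190_000
        assert abs(gc_content(mito) - 0.361) <= 0.01
        assert abs(gc_content(nuc) - 0.457) <= 0.01

    def test_cpg_depletion_preserves_gc(self):
        rng = np.random.default_rng(0)
        s = random_background(200_000, 0.361, rng, cpg_factor=0.5)
        assert abs(gc_content(s) - 0.361) <= 0.01
        plain = random_background(200_000, 0.361, rng)
        assert s.count("CG") < 0.7 * plain.count("CG")

    def test_coverage_means(self):
        cfg = SimConfig(seed=5, n_nuclear_contigs=1000, n_mito_contigs=8,
                        n_cassette_only=120, intron_rate=0,
                        n_nuclear_genes=0, include_u1=False)
        contigs, cov, man = simulate_assembly(cfg)
        nuc = [cov[c] for c, b in man.bins.items() if b == "nuclear"]
        mito = [cov[c] for c, b in man.bins.items() if b == "mitochondrial"]
        assert abs(np.mean(nuc) - 41.6) <= 0.1 * 41.6
        assert abs(np.mean(mito) - 196.0) <= 0.1 * 196.0


class TestFragmentGene:
    def test_single_module_covers_protein(self):
        plan = fragment_gene("M" * 300, 1)
        assert [(m.prot_start, m.prot_end) for m in plan.modules] == [(0, 300)]

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        for seed in range(30):
            L = int(rng.integers(40, 400))
            n_lo = -(-L // 135)  # enough modules to satisfy the 135 aa cap
            n = int(rng.integers(n_lo, min(12, L // 5) + 1))
            plan = fragment_gene(random_protein(L, rng), n, max_module_aa=135,
                                 seed=seed, min_module_aa=5)
            intervals = [(m.prot_start, m.prot_end) for m in plan.modules]
            assert intervals[0][0] == 0 and intervals[-1][1] == L
            for (a, b), (c, d) in zip(intervals, intervals[1:]):
                assert b == c
            assert all(b - a <= 135 for a, b in intervals)

    def test_small_partition_respects_max(self):
        plan = fragment_gene("ACDEFGHIKL", 3, max_module_aa=4)
        sizes = [m.prot_end - m.prot_start for m in plan.modules]
        assert sum(sizes) == 10 and max(sizes) <= 4 and len(sizes) == 3

    def test_too_many_modules_rejected(self):
        with pytest.raises(SimConfigError):
            fragment_gene("MKL", 4)

    def test_scramble_never_identity(self):
        for seed in range(40):
            plan = fragment_gene("M" * 100, 5, scramble=True, seed=seed)
            assert plan.placement_order != [0, 1, 2, 3, 4]


class TestUAppendagePlanting:
    def _plan(self, k: int):
        prot = list(random_protein(120, np.random.default_rng(0)))
        plan = fragment_gene("".join(prot), 4, seed=1, min_module_aa=10)
        j = 2
        nl, nr = u_junction_residue_span(k)
        p = plan.modules[j].prot_start
        for r in range(p - nl, p + nr):
            prot[r] = "F"
        plan = dataclasses.replace(plan, protein="".join(prot))
        return plan, j

    def test_k_zero_rejected(self):
        plan, j = self._plan(3)
        with pytest.raises(SimConfigError):
            plant_u_appendage(plan, j, 0)

    def test_bad_junction_index(self):
        plan, _ = self._plan(3)
        with pytest.raises(SimConfigError):
            plant_u_appendage(plan, plan.n_modules, 3)

    def test_incompatible_junction_suggests_alternative(self):
        plan = fragment_gene("MKLV" * 30, 4, seed=1, min_module_aa=10)
        with pytest.raises(SimConfigError, match="junction"):
            plant_u_appendage(plan, 2, 6)

    def test_emitted_modules_lack_poly_t_span(self):
        # a 6xU junction omits the TTTTTT that spans the junction
        genes = [("toy", random_protein(150, np.random.default_rng(3)))]
        cfg = SimConfig(seed=9, ref_proteins=genes, modules_per_gene=(4, 4),
                        u_appendage_sites=[("toy", 2, 6)], n_mito_contigs=3,
                        n_cassette_only=0, n_nuclear_contigs=5,
                        n_nuclear_genes=0, include_u1=False, intron_rate=0)
        contigs, _, man = simulate_assembly(cfg)
        edit = man.junction_edits[0]
        assert edit.k == 6 and edit.gap_residues == "FF"
        left = next(m for m in man.modules if m.module_index == 1)
        right = next(m for m in man.modules if m.module_index == 2)
        # junction residues are absent from both flanking emitted modules
        assert left.prot_end == right.prot_start - 2
        ref = man.mito_refs["toy"]
        assert ref[left.prot_end : right.prot_start] == "FF"


class TestManifestInvariants:
    def test_module_intervals_tile_without_overlap(self, sim_default):
        _, _, man = sim_default
        for gene in man.mito_refs:
            mods = sorted(
                (m for m in man.modules if m.gene == gene),
                key=lambda m: m.prot_start,
            )
            assert mods[0].prot_start == 0
            assert mods[-1].prot_end == len(man.mito_refs[gene])
            for a, b in zip(mods, mods[1:]):
                assert a.prot_end == b.prot_start

    def test_intron_boundaries_in_emitted_sequence(self, sim_default):
        contigs, _, man = sim_default
        for i in man.introns:
            s = contigs[i.contig]
            assert s[i.start : i.start + 2] == "GT"
            assert s[i.end - 2 : i.end] == "AG"

    def test_cassettes_near_ends_similar_not_identical(self, sim_default):
        contigs, _, man = sim_default
        seqs = []
        for cid, a, b in man.cassettes:
            assert a <= 50 or b >= len(contigs[cid]) - 50
            seqs.append(contigs[cid][a:b])
        assert len(set(seqs)) == len(seqs)  # never identical copies

    def test_shortest_mito_contig_can_hold_max_module(self, sim_default):
        contigs, _, man = sim_default
        mito_lens = [len(contigs[c]) for c, b in man.bins.items()
                     if b == "mitochondrial"]
        assert min(mito_lens) >= 3 * 135

    def test_manifest_json_roundtrip(self, sim_default, tmp_path):
        _, _, man = sim_default
        man.to_json(tmp_path / "truth.json")
        man2 = TruthManifest.from_json(tmp_path / "truth.json")
        assert man2.bins == man.bins
        assert man2.modules == man.modules
        assert man2.permutations == man.permutations
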