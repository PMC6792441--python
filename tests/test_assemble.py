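import numpy as np
import pytest

from fragmito import seqcore as sc
from fragmito.assemble import (ChainError, ModuleChain, assemble_chain_seqs,
                               chain_modules, check_substitution_editing,
                               infer_u_appendage, refine_junctions,
                               render_module_diagram, scramble_report)
from fragmito.io import PipelineConfig
from fragmito.modulefind import Module, find_modules
from fragmito.pipeline import assemble_gene_chains
from fragmito.simulate import (SimConfig, random_background, random_protein,
                               reverse_translate, simulate_assembly)
from _oracles import brute_chain_objective, chain_objective


def _mod(ps, pe, contig="c", cs=None, strand="+", score=None, gene="g"):
    cs = cs if cs is not None else 3 * ps
    return Module(contig, cs, cs + 3 * (pe - ps), strand, 1, gene, ps, pe,
                  score if score is not None else float(5 * (pe - ps)), 1.0)


class TestChainModules:
    def test_tiling_modules_all_kept(self):
        chain = chain_modules([_mod(0, 100), _mod(100, 200)], "X" * 200)
        assert len(chain.modules) == 2
        assert chain.coverage_fraction == 1.0

    def test_duplicates_keep_one(self):
        chain = chain_modules([_mod(0, 50), _mod(0, 50)], "X" * 50)
        assert len(chain.modules) == 1

    def test_transcript_order_by_protein_coordinate(self):
        chain = chain_modules([_mod(100, 200), _mod(0, 100)], "X" * 200)
        assert [m.prot_start for m in chain.modules] == [0, 100]

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(1, 9))
            mods = []
            for _ in range(n):
                s = int(rng.integers(0, 80))
                e = s + int(rng.integers(3, 30))
                mods.append(_mod(s, e, score=float(rng.integers(10, 100))))
            chain = chain_modules(mods, "X" * 120, max_overlap_aa=5)
            assert chain_objective(chain) == brute_chain_objective(mods, 5)

    def test_mixed_genes_rejected(self):
        with pytest.raises(ChainError):
            chain_modules([_mod(0, 10, gene="a"), _mod(10, 20, gene="b")], "X" * 20)


class TestRefineJunctions:
    def _overlap_fixture(self):
        rng = np.random.default_rng(1)
        ref = random_protein(60, rng)
        # left module encodes ref[0:33] perfectly; right encodes ref[30:60]
        # but with its first three residues (the overlap) mismatched
        left_cds = reverse_translate(ref[:33], 4, 0.4, rng)
        bad = "".join("A" if c in "RNDCQEGHILKMFPSTWYV" else "G" for c in ref[30:33])
        right_cds = reverse_translate(bad + ref[33:60], 4, 0.4, rng)
        contigs = {
            "cL": random_background(30, 0.4, rng) + left_cds
                  + random_background(30, 0.4, rng),
            "cR": random_background(30, 0.4, rng) + right_cds
                  + random_background(30, 0.4, rng),
        }
        left = Module("cL", 30, 30 + len(left_cds), "+", 1, "g", 0, 33, 165.0, 1.0)
        right = Module("cR", 30, 30 + len(right_cds), "+", 1, "g", 30, 60, 150.0, 0.9)
        chain = chain_modules([left, right], ref)
        return chain, contigs, ref

    def test_overlap_split_favours_matching_side(self):
        chain, contigs, ref = self._overlap_fixture()
        refined = refine_junctions(chain, contigs)
        l, r = refined.modules
        assert l.prot_end == 33 and r.prot_start == 33
        assert r.contig_start == 30 + 9  # right module trimmed by 3 aa
        refined = assemble_chain_seqs(refined, contigs)
        assert refined.protein == ref

    def test_abutting_modules_unchanged(self):
        rng = np.random.default_rng(2)
        ref = random_protein(40, rng)
        cds = reverse_translate(ref, 4, 0.4, rng)
        contigs = {"c": cds}
        mods = [Module("c", 0, 60, "+", 1, "g", 0, 20, 100.0, 1.0),
                Module("c", 60, 120, "+", 1, "g", 20, 40, 100.0, 1.0)]
        chain = chain_modules(mods, ref)
        refined = refine_junctions(chain, contigs)
        assert [(m.prot_start, m.prot_end) for m in refined.modules] == \
            [(0, 20), (20, 40)]

    def test_excess_overlap_is_contract_violation(self):
        rng = np.random.default_rng(3)
        ref = random_protein(50, rng)
        contigs = {"c": reverse_translate(ref, 4, 0.4, rng)}
        chain = ModuleChain("g", ref, [
            Module("c", 0, 90, "+", 1, "g", 0, 30, 100.0, 1.0),
            Module("c", 30, 150, "+", 1, "g", 10, 50, 100.0, 1.0),
        ])
        with pytest.raises(ChainError):
            refine_junctions(chain, contigs)

    def test_short_module_collapsed_by_weak_extension(self):
        rng = np.random.default_rng(4)
        ref = random_protein(90, rng)
        # left neighbour's contig continues with a weak (half-identity,
        # stop-free) encoding of the short module's span
        weak = list(ref[40:50])
        for i in range(0, 10, 2):
            weak[i] = "A" if weak[i] != "A" else "G"
        weak = "".join(weak)
        left_cds = reverse_translate(ref[:40] + weak, 4, 0.4, rng)
        tiny_cds = reverse_translate(ref[40:50], 4, 0.4, rng)
        right_cds = reverse_translate(ref[50:90], 4, 0.4, rng)
        contigs = {
            "cL": left_cds + random_background(40, 0.4, rng),
            "cM": random_background(12, 0.4, rng) + tiny_cds
                  + random_background(12, 0.4, rng),
            "cR": right_cds,
        }
        mods = [
            Module("cL", 0, 120, "+", 1, "g", 0, 40, 200.0, 1.0),
            Module("cM", 12, 42, "+", 1, "g", 40, 50, 50.0, 1.0),
            Module("cR", 0, 120, "+", 1, "g", 50, 90, 200.0, 1.0),
        ]
        chain = chain_modules(mods, ref)
        collapsed = refine_junctions(chain, contigs, collapse_short=True)
        assert len(collapsed.modules) == 2
        assert collapsed.modules[0].prot_end == 50
        assert any("removed" in n for n in collapsed.notes)
        # without the flag the tiny module stays
        kept = refine_junctions(chain, contigs)
        assert len(kept.modules) == 3


class TestScrambleReport:
    def test_single_contig_in_order_no_trans_splicing(self):
        mods = [_mod(0, 50, cs=100), _mod(50, 100, cs=400)]
        rep = scramble_report(ModuleChain("g", "X" * 100, mods))
        assert not rep.trans_splicing_required
        assert rep.rationale == [] and rep.n_breakpoints == 0

    def test_reversed_order_single_contig(self):
        mods = [_mod(0, 50, cs=400), _mod(50, 100, cs=100)]
        rep = scramble_report(ModuleChain("g", "X" * 100, mods))
        assert rep.permuted_order and rep.trans_splicing_required
        assert rep.n_contigs == 1

    def test_published_cox1_topology(self):
        # modules 1,6 nearby on one contig; 4,3,5 in that order on another;
        # module 2 and module 7 on two further contigs
        placement = {
            "ctgA": [1, 6], "ctgB": [4, 3, 5], "ctgC": [2], "ctgD": [7],
        }
        mods = [None] * 7
        for contig, transcript_ids in placement.items():
            pos = 100
            for t in transcript_ids:
                mods[t - 1] = _mod(50 * (t - 1), 50 * t, contig=contig, cs=pos)
                pos += 400
        rep = scramble_report(ModuleChain("cox1", "X" * 350, mods))
        assert rep.n_contigs == 4
        assert rep.trans_splicing_required
        assert {"multi_contig", "permuted_order"} <= set(rep.rationale)
        assert rep.permutation == [0, 5, 3, 2, 4, 1, 6]

    def test_strand_mix_alone_forces_trans_splicing(self):
        mods = [_mod(0, 50, cs=100), _mod(50, 100, cs=400, strand="-")]
        rep = scramble_report(ModuleChain("g", "X" * 100, mods))
        assert rep.strand_mix and rep.trans_splicing_required


class TestUAppendageInference:
    def test_roundtrip_through_full_pipeline(self):
        genes = [("toy", random_protein(160, np.random.default_rng(0)))]
        cfg = SimConfig(seed=13, ref_proteins=genes, modules_per_gene=(4, 4),
                        u_appendage_sites=[("toy", 2, 3)], n_mito_contigs=3,
                        n_cassette_only=0, n_nuclear_contigs=6,
                        n_nuclear_genes=0, include_u1=False, intron_rate=0)
        contigs, _, man = simulate_assembly(cfg)
        mods = find_modules(contigs, man.mito_refs, table_id=4)
        chains = assemble_gene_chains(contigs, mods, man.mito_refs,
                                      PipelineConfig())
        chain = chains["toy"]
        ks = [j.k_u for j in chain.junctions]
        assert ks.count(3) == 1 and ks.count(0) == 2
        assert chain.protein == man.mito_refs["toy"]

    def test_abutting_junction_is_k_zero(self):
        rng = np.random.default_rng(5)
        ref = random_protein(40, rng)
        cds = reverse_translate(ref, 4, 0.4, rng)
        contigs = {"a": cds[:60] + random_background(50, 0.4, rng),
                   "b": random_background(50, 0.4, rng) + cds[60:]}
        mods = [Module("a", 0, 60, "+", 1, "g", 0, 20, 100.0, 1.0),
                Module("b", 50, 50 + len(cds) - 60, "+", 1, "g", 20, 40,
                       100.0, 1.0)]
        chain = infer_u_appendage(chain_modules(mods, ref), contigs)
        assert chain.junctions[0].k_u == 0
        assert chain.junctions[0].status == "abut"

    def test_tryptophan_gap_unresolved(self):
        rng = np.random.default_rng(6)
        ref = random_protein(41, rng)
        ref = ref[:20] + "W" + ref[21:]
        left_cds = reverse_translate(ref[:20], 4, 0.4, rng)
        right_cds = reverse_translate(ref[21:], 4, 0.4, rng)
        contigs = {"a": left_cds + "CCCCCC", "b": "CCCCCC" + right_cds}
        mods = [Module("a", 0, 60, "+", 1, "g", 0, 20, 100.0, 1.0),
                Module("b", 6, 6 + len(right_cds), "+", 1, "g", 21, 41,
                       100.0, 1.0)]
        chain = infer_u_appendage(chain_modules(mods, ref), contigs)
        assert chain.junctions[0].status == "unresolved"

    def test_large_gap_reported_as_missing_modules(self):
        rng = np.random.default_rng(7)
        ref = random_protein(100, rng)
        left_cds = reverse_translate(ref[:20], 4, 0.4, rng)
        right_cds = reverse_translate(ref[80:], 4, 0.4, rng)
        contigs = {"a": left_cds + "CCC", "b": "CCC" + right_cds}
        mods = [Module("a", 0, 60, "+", 1, "g", 0, 20, 100.0, 1.0),
                Module("b", 3, 63, "+", 1, "g", 80, 100, 100.0, 1.0)]
        chain = infer_u_appendage(chain_modules(mods, ref), contigs)
        assert chain.junctions[0].status == "missing_modules"


class TestSubstitutionEditing:
    def _chain_with_cds(self, cds, ref=None):
        n = len(cds) // 3
        chain = ModuleChain("g", ref or "X" * n,
                            [Module("c", 0, len(cds), "+", 1, "g", 0, n,
                                    100.0, 1.0)])
        chain.cds = cds
        return chain

    def test_simulated_gene_requires_no_editing(self, sim_default,
                                                sim_modules):
        contigs, _, man = sim_default
        chains = assemble_gene_chains(contigs, sim_modules, man.mito_refs,
                                      PipelineConfig())
        for gene, chain in chains.items():
            rep = check_substitution_editing(chain)
            assert rep.verdict == "none required"
            assert rep.identity_to_ref == 1.0

    def test_internal_stop_flagged_with_position(self):
        cds = "ATGGCTTAAGCTGCT"  # TAA at codon 2
        rep = check_substitution_editing(self._chain_with_cds(cds), table_id=1)
        assert rep.verdict == "candidate editing sites"
        assert rep.internal_stops == [2]

    def test_code_dependence(self):
        cds = "ATGGCTTAAGCTGCT"
        # under the ciliate nuclear code (table 6) TAA encodes Gln
        rep = check_substitution_editing(self._chain_with_cds(cds), table_id=6)
        assert rep.verdict == "none required"

    def test_requires_assembled_cds(self):
        chain = ModuleChain("g", "XX", [_mod(0, 2)])
        with pytest.raises(ChainError):
            check_substitution_editing(chain)


class TestDiagram:
    def test_renders_all_modules(self, sim_default, sim_modules):
        contigs, _, man = sim_default
        chains = assemble_gene_chains(contigs, sim_modules, man.mito_refs,
                                      PipelineConfig())
        for gene, chain in chains.items():
            text = render_module_diagram(chain, contigs)
            assert gene in text
            for m in chain.modules:
                assert m.contig_id in text
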