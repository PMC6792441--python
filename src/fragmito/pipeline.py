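"""End-to-end orchestration: classify -> find modules -> assemble ->
introns -> U1, writing one output directory with a machine-readable
summary."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import assemble as asm
from . import io as fio
from . import modulefind as mf
from . import profiles
from .introns import (donor_window, find_canonical_introns,
                      find_u1_candidate, u1_binding_score)
from .io import GffFeature, PipelineConfig

logger = logging.getLogger("fragmito")


def modules_to_gff(modules: list[mf.Module]) -> list[GffFeature]:
    return [
        GffFeature(
            seqid=m.contig_id,
            type="CDS_module",
            start=m.contig_start,
            end=m.contig_end,
            strand=m.strand,
            score=m.score,
            attributes={
                "gene": m.gene,
                "protein_start": m.prot_start,
                "protein_end": m.prot_end,
                "identity": f"{m.identity:.4f}",
                "frame": m.frame,
            },
        )
        for m in modules
    ]


def introns_to_gff(calls) -> list[GffFeature]:
    return [
        GffFeature(
            seqid=c.contig_id,
            type="intron",
            start=c.start,
            end=c.end,
            strand=c.strand,
            score=c.score_gain,
            attributes={"gene": c.gene, "donor": c.donor,
                        "acceptor": c.acceptor, "source": c.source},
        )
        for c in calls
    ]


def bin_calls_to_tsv(calls, path) -> None:
    pd.DataFrame(
        [
            {
                "contig": c.contig_id,
                "label": c.label,
                "coverage_fold": round(c.coverage_fold, 4),
                "gc": round(c.gc, 4),
                "gc_deviation": round(c.gc_deviation, 4),
                "som_node": c.som_node if c.som_node is not None else "",
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def mito_calls_to_tsv(calls, path) -> None:
    pd.DataFrame(
        [
            {
                "contig": c.contig_id,
                "status": c.status,
                "module_count": c.module_count,
                "cassette_partner": c.cassette_partner or "",
                "cassette_identity": (
                    round(c.cassette_identity, 4)
                    if c.cassette_identity is not None else ""
                ),
                "cassette_length": c.cassette_length or "",
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def assemble_gene_chains(
    contigs: dict[str, str],
    modules: list[mf.Module],
    ref_proteins: dict[str, str],
    cfg: PipelineConfig,
) -> dict[str, asm.ModuleChain]:
    """Chain, refine, decode junctions and assemble one chain per gene."""
    by_gene: dict[str, list[mf.Module]] = {}
    for m in modules:
        by_gene.setdefault(m.gene, []).append(m)
    chains: dict[str, asm.ModuleChain] = {}
    for ref_id, protein in ref_proteins.items():
        gene = ref_id.partition("|")[0]
        if gene not in by_gene:
            continue
        chain = asm.chain_modules(by_gene[gene], protein,
                                  max_overlap_aa=cfg.max_overlap_aa)
        chain = asm.refine_junctions(
            chain, contigs,
            max_overlap_aa=cfg.max_overlap_aa,
            extend_max_aa=cfg.extend_max_aa,
            u_gap_max_aa=cfg.u_gap_max_aa,
            table_id=cfg.mito_table_id,
        )
        chain = asm.infer_u_appendage(
            chain, contigs, k_max=cfg.k_max,
            u_gap_max_aa=cfg.u_gap_max_aa, table_id=cfg.mito_table_id,
        )
        chain = asm.assemble_chain_seqs(chain, contigs, cfg.mito_table_id)
        chains[gene] = chain
    return chains


def run_all(
    contigs: dict[str, str],
    coverage: dict[str, float],
    mito_refs: dict[str, str],
    outdir,
    nuclear_refs: dict[str, str] | None = None,
    u1_query: str | None = None,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Run the full analysis on one assembly and write all outputs.

    Returns the summary that is also written to ``summary.json``.
    """
    cfg = cfg or PipelineConfig()
    cfg.log_effective()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    lengths = {c: len(s) for c, s in contigs.items()}

    stats = profiles.assembly_stats(contigs, coverage)
    bin_calls = profiles.classify_contigs(
        contigs, coverage, r_min=cfg.r_min, gc_delta=cfg.gc_delta,
        som_min_len=cfg.som_min_len, som_seed=cfg.seed,
    )
    bin_calls_to_tsv(bin_calls, out / "bin_calls.tsv")

    modules = mf.find_modules(
        contigs, mito_refs, min_score=cfg.min_score,
        min_identity=cfg.min_identity, min_aa=cfg.min_module_aa,
        table_id=cfg.mito_table_id,
    )
    modules = mf.merge_hsps(modules, max_gap_aa=cfg.max_gap_aa)
    fio.write_gff3(modules_to_gff(modules), out / "modules.gff3", lengths)

    mito_calls = mf.call_mito_contigs(
        contigs, modules,
        min_len=cfg.mito_min_len,
        cassette_min_len=cfg.cassette_min_len,
        cassette_min_ident=cfg.cassette_min_ident,
        cassette_max_ident=cfg.cassette_max_ident,
        search_window=cfg.cassette_search_window,
    )
    mito_calls_to_tsv(mito_calls, out / "mito_calls.tsv")

    chains = assemble_gene_chains(contigs, modules, mito_refs, cfg)
    fio.write_report({g: c.to_dict() for g, c in chains.items()},
                     out / "chains.json")
    if chains:
        fio.write_fasta({f"{g}_cds": c.cds for g, c in chains.items()
                         if c.cds}, out / "assembled_cds.fasta")
        fio.write_fasta({f"{g}_protein": c.protein
                         for g, c in chains.items() if c.protein},
                        out / "assembled_proteins.fasta")
    scrambles = {g: asm.scramble_report(c) for g, c in chains.items()}
    editing = {g: asm.check_substitution_editing(c, cfg.mito_table_id)
               for g, c in chains.items() if c.cds}
    fio.write_report({g: s for g, s in scrambles.items()},
                     out / "scramble_reports.json")
    with open(out / "module_maps.txt", "w") as fh:
        for g in sorted(chains):
            fh.write(asm.render_module_diagram(chains[g], contigs) + "\n\n")

    intron_calls = []
    if nuclear_refs:
        shortlist = mf.find_modules(
            contigs, nuclear_refs, min_score=40.0,
            min_identity=cfg.min_identity, table_id=cfg.nuclear_table_id,
        )
        seen = {(m.contig_id, m.gene) for m in shortlist}
        for cid, gene in sorted(seen):
            ref = next(
                p for rid, p in nuclear_refs.items()
                if rid.partition("|")[0] == gene
            )
            intron_calls.extend(
                find_canonical_introns(
                    cid, contigs[cid], ref, gene=gene,
                    table_id=cfg.nuclear_table_id,
                    max_intron_bp=cfg.max_intron_bp,
                    search_bp=cfg.intron_search_bp,
                )
            )
    fio.write_gff3(introns_to_gff(intron_calls), out / "introns.gff3", lengths)

    u1_loci = []
    u1_matches = []
    if u1_query:
        u1_loci = find_u1_candidate(
            contigs, u1_query, min_identity=cfg.u1_min_identity,
            min_len=cfg.u1_min_len,
        )
        u1_seq = u1_query
        if u1_loci:
            top = u1_loci[0]
            u1_seq = contigs[top.contig_id][top.start : top.end]
            if top.strand == "-":
                from .seqcore import reverse_complement
                u1_seq = reverse_complement(u1_seq)
        for c in intron_calls:
            try:
                win = donor_window(contigs[c.contig_id], c.start
                                   if c.strand == "+" else c.end, c.strand)
            except Exception:
                continue
            m = u1_binding_score(u1_seq, win, cfg.u1_window_offset,
                                 cfg.u1_window_len)
            u1_matches.append(
                {
                    "contig": c.contig_id,
                    "intron_start": c.start,
                    "gene": c.gene,
                    "window": m.window,
                    "pairing": m.pairing,
                    "score": m.score,
                }
            )
        pd.DataFrame(
            [
                {
                    "contig": u.contig_id, "start": u.start, "end": u.end,
                    "strand": u.strand,
                    "identity": round(u.identity, 4),
                    "score": u.score, "length": u.length,
                }
                for u in u1_loci
            ]
        ).to_csv(out / "u1_candidates.tsv", sep="\t", index=False)
        pd.DataFrame(u1_matches).to_csv(out / "u1_matches.tsv", sep="\t",
                                        index=False)

    summary = {
        "seed": cfg.seed,
        "params": cfg.to_dict(),
        "assembly": {
            "n_contigs": stats.n_contigs,
            "total_bp": stats.total_bp,
            "n50": stats.n50,
            "gc": round(stats.gc, 4),
            "mean_coverage": round(stats.mean_coverage or 0.0, 2),
        },
        "binning": {
            "organellar_candidates": sum(
                1 for c in bin_calls if c.label == "organellar-candidate"
            ),
            "ambiguous": sum(1 for c in bin_calls if c.label == "ambiguous"),
            "nuclear": sum(1 for c in bin_calls if c.label == "nuclear"),
        },
        "mito_contigs": {
            "bona_fide": sum(1 for c in mito_calls if c.status == "bona_fide"),
            "putative": sum(1 for c in mito_calls if c.status == "putative"),
        },
        "n_modules": len(modules),
        "genes": {
            g: {
                "n_modules": len(c.modules),
                "n_contigs": len({m.contig_id for m in c.modules}),
                "coverage_fraction": round(c.coverage_fraction, 4),
                "trans_splicing_required":
                    scrambles[g].trans_splicing_required,
                "rationale": scrambles[g].rationale,
                "junction_k": [j.k_u for j in c.junctions],
                "editing_verdict": editing[g].verdict if g in editing else "",
            }
            for g, c in chains.items()
        },
        "introns": {
            "n_calls": len(intron_calls),
            "genes": sorted({c.gene for c in intron_calls}),
        },
        "u1": {
            "n_candidates": len(u1_loci),
            "best_identity": round(u1_loci[0].identity, 4) if u1_loci else None,
            "donor_scores": [m["score"] for m in u1_matches],
        },
    }
    fio.write_report(summary, out / "summary.json")
    logger.info("run-all complete: %s", out)
    return summary
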