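"""End-to-end orchestration of the simulate -> search -> domains ->
collinearity -> network -> phylogeny -> classification pipeline.

Everything is driven by a single seed and writes plain-text outputs, so a
rerun with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import collinearity, domains, fusion_dosage, homology, network, phylo
from . import seqio, simgenomes
from .simgenomes import EvolutionConfig, SpeciesTree

#: Species tree of the default simulation: four genomes, two sister pairs,
#: with a WGD planted on the root branch.
DEFAULT_TREE = "((A:0.08,B:0.08)ab:0.06,(C:0.08,D:0.08)cd:0.06)root:0.02;"


@dataclass
class PipelineConfig:
    tree_newick: str = DEFAULT_TREE
    evolution: dict = field(default_factory=dict)
    evalue_max: float = 1e-5
    top_n: int = 5
    gap_open: float = 11.0
    gap_extend: float = 1.0
    max_gap: int = 25
    gap_penalty: float = -1.0
    min_block_size: int = 5
    window: int = 25
    k: int = 3
    domain_evalue: float = 0.007
    max_ratio: float = 2.0
    tandem_gap: int = 5
    occupancy: float = 0.5
    bootstrap: int = 25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        evo = data.get("evolution") or {}
        if "background_len" in evo:
            evo["background_len"] = tuple(evo["background_len"])
        if "wgd_events" in evo:
            evo["wgd_events"] = [tuple(e) for e in evo["wgd_events"]]
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def default_evolution_config(seed: int = 0, **overrides) -> EvolutionConfig:
    """The default simulation scenario: 1 WGD on the root branch plus
    recurring tandem and transposed duplications and occasional losses."""
    params = dict(
        rate_tandem=3.0, rate_transposed=3.0, rate_loss=0.5,
        rate_fusion=0.0, p_domain_loss=0.3,
        wgd_events=[("root", 2)], wgd_retention=0.8,
        n_background_genes=30, n_chromosomes=4, n_family_genes=1,
        background_len=(50, 70),
        seed=seed,
    )
    params.update(overrides)
    return EvolutionConfig(**params)


def default_simulation(seed: int = 0, min_tandem: int = 5,
                       min_transposed: int = 3, **overrides):
    """Default-scenario dataset with the planted event minimums
    guaranteed: derived seeds are tried deterministically until the
    simulation contains at least ``min_tandem`` tandem and
    ``min_transposed`` transposed duplications.

    Returns (cfg, tree, genomes, log).
    """
    tree = SpeciesTree.from_newick(DEFAULT_TREE)
    for attempt in range(50):
        cfg = default_evolution_config(seed=seed + 100003 * attempt,
                                       **overrides)
        genomes, log = simgenomes.evolve(tree, cfg)
        if (len(log.events_of_kind("tandem_dup")) >= min_tandem
                and len(log.events_of_kind("transposed_dup")) >= min_transposed):
            return cfg, tree, genomes, log
    raise RuntimeError("could not realise the planted scenario in 50 tries")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path,
                 seed: int = 0) -> dict:
    """Run the full pipeline into ``outdir``; returns the in-memory
    results keyed by stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    evo_params = dict(cfg.evolution)
    evo_params["seed"] = seed
    evo = default_evolution_config(**evo_params)
    tree = SpeciesTree.from_newick(cfg.tree_newick)

    # 1. simulate and round-trip through the on-disk formats
    genomes, log = simgenomes.evolve(tree, evo)
    simgenomes.write_dataset(genomes, log, outdir)
    genomes = [
        seqio.load_genome(outdir / f"{g.genome_id}.faa",
                          outdir / f"{g.genome_id}.bed", g.genome_id)
        for g in genomes
    ]
    proteins = {g.gene_id: g.protein
                for genome in genomes for g in genome.genes()}

    # 2. domain profiles and scanning
    seed_alignments = simgenomes.domain_seed_alignments(evo)
    profiles = [domains.build_profile(rows, name=name)
                for name, rows in sorted(seed_alignments.items())]
    for name, rows in sorted(seed_alignments.items()):
        seqio.write_fasta({f"seed{i}": s for i, s in enumerate(rows)},
                          outdir / f"profile_{name}.faa")
    domain_hits = domains.scan_genes(proteins, profiles,
                                     evalue_threshold=cfg.domain_evalue,
                                     seed=seed)
    seqio.write_table(domains.hits_to_rows(domain_hits),
                      domains.DOMAIN_HIT_SCHEMA, outdir / "domain_hits.tsv")
    architectures = {gid: domains.classify_architecture(hits)
                     for gid, hits in domain_hits.items()}

    # 3. candidate family genes: domain-positive, then divergence-filtered
    domain_positive = {gid: proteins[gid] for gid, arch in architectures.items()
                       if arch != "none"}
    references = simgenomes.reference_sequences(evo)
    kept, removed = domains.filter_by_divergence(domain_positive, references,
                                                 max_ratio=cfg.max_ratio)
    candidates = kept
    with open(outdir / "candidates.tsv", "w") as fh:
        fh.write("gene_id\tarchitecture\tstatus\n")
        for gid in sorted(domain_positive):
            status = "kept" if gid in set(kept) else "removed"
            fh.write(f"{gid}\t{architectures[gid]}\t{status}\n")

    # 4. all-vs-all homology
    hits = homology.all_vs_all(
        genomes, evalue_max=cfg.evalue_max, top_n=cfg.top_n,
        gap_open=cfg.gap_open, gap_extend=cfg.gap_extend)
    seqio.write_table(homology.hits_to_rows(hits), seqio.HIT_SCHEMA,
                      outdir / "hits.tsv")

    # 5. collinear blocks
    params = collinearity.ChainParams(max_gap=cfg.max_gap,
                                      gap_penalty=cfg.gap_penalty,
                                      min_block_size=cfg.min_block_size)
    blocks = collinearity.collinearity_scan(genomes, hits, params)
    seqio.write_table(collinearity.blocks_to_rows(blocks),
                      collinearity.BLOCK_SCHEMA, outdir / "blocks.tsv")
    collinearity.write_collinearity_text(blocks, outdir / "blocks.collinearity")

    # 6. synteny network, family subnetwork, communities
    graph = network.build_network(blocks, genomes, architectures)
    seqio.write_table(network.graph_to_edge_rows(graph),
                      seqio.EDGE_SCHEMA, outdir / "network_edges.tsv")
    fam_graph = network.extract_family_subnetwork(graph, candidates,
                                                  window=cfg.window)
    seqio.write_table(network.graph_to_edge_rows(fam_graph),
                      seqio.EDGE_SCHEMA, outdir / "family_edges.tsv")
    communities = network.clique_communities(fam_graph, k=cfg.k)
    seqio.write_table(network.communities_to_rows(communities),
                      seqio.COMMUNITY_SCHEMA, outdir / "communities.tsv")

    # 7. trees: full sequences and domain-sliced sequences, same code path
    fam_proteins = {gid: proteins[gid] for gid in candidates}
    results_trees = {}
    if len(fam_proteins) >= 3:
        spans = {}
        for gid in candidates:
            first = [h for h in domain_hits[gid]
                     if h.domain_name == simgenomes.DOMAIN_FIRST]
            if len(first) == 1:
                spans[gid] = (first[0].start, first[0].end)
        for mode, seqs in (("full", fam_proteins),
                           ("domain", phylo.slice_to_domain(fam_proteins, spans))):
            if len(seqs) < 3:
                continue
            aln = phylo.progressive_msa(seqs)
            cleaned = phylo.clean_alignment(aln, cfg.occupancy)
            tree_out = phylo.bootstrap_support(cleaned, n_reps=cfg.bootstrap,
                                               seed=seed)
            seqio.write_newick(tree_out, outdir / f"tree_{mode}.nwk")
            results_trees[mode] = tree_out

    # 8. duplication classification and dosage profiles
    gene_map = {g.gene_id: g for genome in genomes for g in genome.genes()}
    family_records = [gene_map[gid] for gid in candidates]
    calls = fusion_dosage.classify_duplications(
        family_records, graph, communities, genomes, tandem_gap=cfg.tandem_gap)
    seqio.write_table(fusion_dosage.calls_to_rows(calls),
                      fusion_dosage.DUPLICATION_SCHEMA,
                      outdir / "duplication_calls.tsv")
    profiles_out = fusion_dosage.dosage_profile(
        genomes, family_records, communities, architectures)
    seqio.write_table(fusion_dosage.profiles_to_rows(profiles_out),
                      fusion_dosage.LOCUS_SCHEMA, outdir / "locus_profiles.tsv")

    return {
        "genomes": genomes, "log": log, "architectures": architectures,
        "candidates": candidates, "removed": removed, "hits": hits,
        "blocks": blocks, "network": graph, "family_network": fam_graph,
        "communities": communities, "trees": results_trees, "calls": calls,
        "profiles": profiles_out, "domain_hits": domain_hits,
    }
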