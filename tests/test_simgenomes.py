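import numpy as np
import pytest

from syntegraph import seqio, simgenomes
from syntegraph.simgenomes import (EvolutionConfig, SpeciesTree,
                                   build_ancestral_genome, evolve,
                                   make_chimera, write_dataset)

from oracles import replay_gene_orders


class TestSpeciesTree:
    def test_from_newick_labels_and_lengths(self):
        tree = SpeciesTree.from_newick("((A:1,B:1)ab:2,C:3)root:0.5;")
        assert set(tree.leaf_labels()) == {"A", "B", "C"}
        assert "ab" in tree.branch_ids()
        assert tree.root.label == "root"

    def test_unlabelled_root_gets_root_label(self):
        tree = SpeciesTree.from_newick("((A:1,B:1):2,C:3);")
        assert tree.root.label == "root"

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValueError, match="unique|duplicate"):
            SpeciesTree.from_newick("((A:1,A:1):2,C:3);")

    def test_nonpositive_branch_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            SpeciesTree.from_newick("((A:0,B:1):2,C:3);")


class TestAncestralGenome:
    def test_gene_count_and_domain_blocks(self):
        cfg = EvolutionConfig(n_background_genes=50, n_chromosomes=1,
                              n_family_genes=1, seed=1)
        genome = build_ancestral_genome(cfg)
        assert genome.n_genes == 51
        fam = [g for g in genome.genes()
               if len(g.protein) == cfg.family_protein_length]
        assert len(fam) == 1

    def test_determinism(self):
        cfg = EvolutionConfig(n_background_genes=20, seed=7)
        g1 = build_ancestral_genome(cfg)
        g2 = build_ancestral_genome(cfg)
        assert {g.gene_id: g.protein for g in g1.genes()} == \
               {g.gene_id: g.protein for g in g2.genes()}
        assert [(g.chrom, g.start, g.end) for g in g1.genes()] == \
               [(g.chrom, g.start, g.end) for g in g2.genes()]

    def test_family_protein_length_is_sum_of_blocks(self):
        cfg = EvolutionConfig(len_flank_n=10, len_domain1=40, len_linker=5,
                              len_domain2=30, len_flank_c=15,
                              n_background_genes=5, seed=2)
        genome = build_ancestral_genome(cfg)
        lengths = {len(g.protein) for g in genome.genes()}
        assert 10 + 40 + 5 + 30 + 15 in lengths

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_background_genes"):
            build_ancestral_genome(EvolutionConfig(n_background_genes=0))

    def test_coordinates_strictly_increasing(self, small_cfg):
        genome = build_ancestral_genome(small_cfg)
        for chrom_genes in genome.chromosomes.values():
            starts = [g.start for g in chrom_genes]
            assert starts == sorted(starts)
            for a, b in zip(chrom_genes, chrom_genes[1:]):
                assert a.end <= b.start


class TestEvolve:
    def test_pure_vertical_descent(self, small_cfg):
        tree = SpeciesTree.from_newick("(A:0.05,B:0.05)root;")
        genomes, log = evolve(tree, small_cfg)
        assert len(genomes) == 2
        anc = build_ancestral_genome(small_cfg)
        for g in genomes:
            assert g.n_genes == anc.n_genes
            # same lengths: substitutions only, no indels
            assert sorted(len(x.protein) for x in g.genes()) == \
                   sorted(len(x.protein) for x in anc.genes())

    def test_wgd_doubles_gene_count_at_full_retention(self):
        cfg = EvolutionConfig(n_background_genes=10, seed=3,
                              wgd_events=[("root", 2)], wgd_retention=1.0)
        tree = SpeciesTree.from_newick("(A:0.01,B:0.01)root:0.01;")
        anc = build_ancestral_genome(cfg)
        genomes, _ = evolve(tree, cfg)
        for g in genomes:
            assert g.n_genes == 2 * anc.n_genes

    def test_wgt_triples_gene_count(self):
        cfg = EvolutionConfig(n_background_genes=8, seed=4,
                              wgd_events=[("root", 3)], wgd_retention=1.0)
        tree = SpeciesTree.from_newick("(A:0.01,B:0.01)root:0.01;")
        anc = build_ancestral_genome(cfg)
        genomes, _ = evolve(tree, cfg)
        for g in genomes:
            assert g.n_genes == 3 * anc.n_genes

    def test_count_conservation_from_log(self):
        cfg = EvolutionConfig(n_background_genes=10, seed=5, rate_tandem=20.0,
                              rate_transposed=10.0, rate_loss=5.0)
        tree = SpeciesTree.from_newick("(A:0.2,B:0.2)root:0.1;")
        anc = build_ancestral_genome(cfg)
        genomes, log = evolve(tree, cfg)
        for genome in genomes:
            # walk the branch path root -> leaf and sum event deltas
            path = {"root", genome.genome_id}
            delta = 0
            for ev in log.events:
                if ev.branch not in path:
                    continue
                if ev.kind in ("tandem_dup", "transposed_dup"):
                    delta += 1
                elif ev.kind == "loss":
                    delta -= 1
            assert genome.n_genes == anc.n_genes + delta

    def test_replay_oracle_reconstructs_leaf_gene_orders(self):
        cfg = EvolutionConfig(n_background_genes=12, n_chromosomes=2, seed=9,
                              rate_tandem=15.0, rate_transposed=8.0,
                              rate_loss=4.0, rate_fusion=3.0,
                              p_domain_loss=0.4, n_family_genes=2,
                              wgd_events=[("ab", 2)], wgd_retention=0.7)
        tree = SpeciesTree.from_newick(
            "((A:0.15,B:0.15)ab:0.1,(C:0.15,D:0.15)cd:0.1)root:0.05;")
        genomes, log = evolve(tree, cfg)
        anc = build_ancestral_genome(cfg)
        anc_orders = {c: [g.gene_id for g in genes]
                      for c, genes in anc.chromosomes.items()}
        replayed = replay_gene_orders(anc_orders, tree, log.events)
        for genome in genomes:
            actual = {c: [g.gene_id for g in genes]
                      for c, genes in genome.chromosomes.items()}
            expect = {c: g for c, g in replayed[genome.genome_id].items() if g}
            actual = {c: g for c, g in actual.items() if g}
            assert actual == expect, genome.genome_id

    def test_tandem_children_adjacent_at_birth(self):
        cfg = EvolutionConfig(n_background_genes=10, seed=13,
                              rate_tandem=30.0)
        tree = SpeciesTree.from_newick("(A:0.3,B:0.3)root:0.1;")
        genomes, log = evolve(tree, cfg)
        tandems = log.events_of_kind("tandem_dup")
        assert tandems, "scenario should contain tandem duplications"
        # at birth the child is inserted right after its parent; verify via
        # the recorded insertion index against the replay
        anc = build_ancestral_genome(cfg)
        anc_orders = {c: [g.gene_id for g in genes]
                      for c, genes in anc.chromosomes.items()}
        replayed = replay_gene_orders(anc_orders, tree, log.events)
        assert replayed  # replay must accept every tandem insertion index

    def test_determinism_of_evolve(self, four_leaf_tree):
        cfg = EvolutionConfig(n_background_genes=10, seed=21, rate_tandem=10.0,
                              rate_loss=2.0, wgd_events=[("root", 2)])
        g1, log1 = evolve(four_leaf_tree, cfg)
        g2, log2 = evolve(four_leaf_tree, cfg)
        for a, b in zip(g1, g2):
            assert {x.gene_id: x.protein for x in a.genes()} == \
                   {x.gene_id: x.protein for x in b.genes()}
        assert [e.kind for e in log1.events] == [e.kind for e in log2.events]

    def test_poisson_event_counts(self):
        # mean tandem count over replicates within 3 SE of rate * t
        rate, t, n_rep = 2.0, 1.0, 200
        tree = SpeciesTree.from_newick("(A:1.0,B:1.0)root;")
        counts = []
        for seed in range(n_rep):
            cfg = EvolutionConfig(n_background_genes=1, n_chromosomes=1,
                                  rate_tandem=rate, seed=seed)
            _, log = evolve(tree, cfg)
            counts.append(sum(1 for e in log.events
                              if e.kind == "tandem_dup" and e.branch == "A"))
        mean = np.mean(counts)
        se = np.sqrt(rate * t / n_rep)
        assert abs(mean - rate * t) < 3 * se


class TestMakeChimera:
    def test_simple_splice(self):
        assert make_chimera("AAAA", "BBBB", [2]) == "AABB"

    def test_no_breakpoints_is_identity(self):
        assert make_chimera("AAAA", "BBBB", []) == "AAAA"

    def test_unequal_lengths(self):
        # hand-spliced: prefix of a (2 aa) + suffix of b from position 2
        a, b = "ACDEF", "WYW"
        assert make_chimera(a, b, [2]) == "AC" + b[2:]

    def test_alternation(self):
        assert make_chimera("AAAA", "BBBB", [1, 3]) == "ABBA"

    def test_breakpoint_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            make_chimera("AAAA", "BB", [3])

    def test_non_increasing_breakpoints(self):
        with pytest.raises(ValueError, match="increasing"):
            make_chimera("AAAA", "BBBB", [3, 1])


class TestWriteDataset:
    def test_file_set(self, tmp_path, small_cfg):
        tree = SpeciesTree.from_newick("((A:0.05,B:0.05)ab:0.05,C:0.1)root;")
        genomes, log = evolve(tree, small_cfg)
        write_dataset(genomes, log, tmp_path)
        assert len(list(tmp_path.glob("*.faa"))) == 3
        assert len(list(tmp_path.glob("*.bed"))) == 3
        assert len(list(tmp_path.glob("*.tsv"))) == 1

    def test_round_trip_gene_counts(self, tmp_path, small_cfg):
        tree = SpeciesTree.from_newick("(A:0.05,B:0.05)root;")
        genomes, log = evolve(tree, small_cfg)
        write_dataset(genomes, log, tmp_path)
        for genome in genomes:
            back = seqio.load_genome(tmp_path / f"{genome.genome_id}.faa",
                                     tmp_path / f"{genome.genome_id}.bed",
                                     genome.genome_id)
            assert back.n_genes == genome.n_genes
            assert back.gene_map().keys() == genome.gene_map().keys()

    def test_bed_intervals_non_overlapping(self, tmp_path, small_cfg):
        tree = SpeciesTree.from_newick("(A:0.05,B:0.05)root;")
        genomes, log = evolve(tree, small_cfg)
        write_dataset(genomes, log, tmp_path)
        for genome in genomes:
            rows = seqio.read_bed6(tmp_path / f"{genome.genome_id}.bed")
            by_key = {}
            for chrom, start, end, name, strand in rows:
                by_key.setdefault((chrom, strand), []).append((start, end))
            for intervals in by_key.values():
                intervals.sort()
                for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                    assert e1 <= s2, "overlapping BED intervals"


class TestTruthHelpers:
    def test_domain_loss_truth_recorded(self, four_leaf_tree):
        cfg = EvolutionConfig(n_background_genes=10, seed=31,
                              rate_tandem=20.0, p_domain_loss=1.0)
        _, log = evolve(four_leaf_tree, cfg)
        assert log.events_of_kind("domain_loss")
        lost = [t for t in log.leaf_truth.values()
                if t.is_family and not t.has_domain2]
        assert lost
        assert all(t.architecture == "MAM-like" for t in lost)

    def test_mutate_protein_rate(self):
        rng = np.random.default_rng(0)
        seq = simgenomes.random_protein(2000, rng)
        out = simgenomes.mutate_protein(seq, 0.3, rng)
        frac = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert 0.25 < frac < 0.35

    def test_mutate_protein_zero_rate_identity(self):
        rng = np.random.default_rng(0)
        seq = simgenomes.random_protein(100, rng)
        assert simgenomes.mutate_protein(seq, 0.0, rng) == seq
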