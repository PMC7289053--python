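import numpy as np
import pytest

from syntegraph import fusion_dosage as fd
from syntegraph import simgenomes
from syntegraph.domains import DomainHit
from syntegraph.fusion_dosage import (SegmentTriplet, conservation_score,
                                      conservation_summary, dosage_deltas,
                                      dosage_profile, dosage_report,
                                      fusion_test, split_segments)
from syntegraph.network import CliqueCommunity
from syntegraph.phylo import MultipleAlignment
from syntegraph.seqio import AnnotatedGenome, GeneRecord
from syntegraph.simgenomes import make_chimera, mutate_protein, random_protein


def _gene(gene_id, protein, genome="G", chrom="chr1", start=0):
    return GeneRecord(gene_id=gene_id, genome_id=genome, chrom=chrom,
                      start=start, end=start + 3 * len(protein), strand="+",
                      protein=protein)


def _hit(start, end, name="HMGL-like"):
    return DomainHit("", name, start, end, 10.0, 0.001)


class TestSplitSegments:
    def test_partition_arithmetic(self):
        rng = np.random.default_rng(0)
        gene = _gene("g", random_protein(300, rng))
        trip = split_segments(gene, [_hit(100, 220)])
        assert (len(trip.before), len(trip.domain), len(trip.after)) == \
               (100, 120, 80)

    def test_full_length_hit_empty_flanks(self):
        rng = np.random.default_rng(1)
        gene = _gene("g", random_protein(80, rng))
        trip = split_segments(gene, [_hit(0, 80)])
        assert trip.before == "" and trip.after == ""

    def test_concatenation_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            protein = random_protein(int(rng.integers(50, 200)), rng)
            s = int(rng.integers(0, len(protein) - 10))
            e = int(rng.integers(s + 5, len(protein)))
            trip = split_segments(_gene("g", protein), [_hit(s, e)])
            assert trip.before + trip.domain + trip.after == protein

    def test_no_hit_is_error(self):
        with pytest.raises(ValueError, match="no domain hit"):
            split_segments(_gene("g", "MKTAYIAK"), [])

    def test_multi_hit_is_error(self):
        with pytest.raises(ValueError, match="multiple"):
            split_segments(_gene("g", "MKTAYIAKMKTAYIAK"),
                           [_hit(0, 5), _hit(8, 13)])


def _triplet_group(prefix, before, domain, after, n, divergence, rng):
    out = []
    for i in range(n):
        out.append(SegmentTriplet(
            gene_id=f"{prefix}{i}",
            before=mutate_protein(before, divergence, rng),
            domain=mutate_protein(domain, divergence, rng),
            after=mutate_protein(after, divergence, rng)))
    return out


class TestFusionTest:
    def _lineages(self, seed, inter_div=0.2):
        """Two diverged donor lineages plus segment material."""
        rng = np.random.default_rng(seed)
        before = random_protein(60, rng)
        domain = random_protein(80, rng)
        after = random_protein(40, rng)
        a = (mutate_protein(before, inter_div, rng),
             mutate_protein(domain, inter_div, rng),
             mutate_protein(after, inter_div, rng))
        b = (mutate_protein(before, inter_div, rng),
             mutate_protein(domain, inter_div, rng),
             mutate_protein(after, inter_div, rng))
        return rng, a, b

    def test_identical_to_donor_a(self):
        rng, a, b = self._lineages(0)
        focal = _triplet_group("f", *a, 4, 0.02, rng)
        donor_a = _triplet_group("a", *a, 4, 0.02, rng)
        donor_b = _triplet_group("b", *b, 4, 0.02, rng)
        res = fusion_test(focal, donor_a, donor_b)
        assert all(v.verdict == "donorA" for v in res.verdicts.values())
        assert not res.fusion_flagged

    def test_planted_chimera_flagged(self):
        rng, a, b = self._lineages(1)
        # focal: before from A, domain+after from B
        focal = [SegmentTriplet(f"f{i}",
                                before=mutate_protein(a[0], 0.02, rng),
                                domain=mutate_protein(b[1], 0.02, rng),
                                after=mutate_protein(b[2], 0.02, rng))
                 for i in range(4)]
        donor_a = _triplet_group("a", *a, 4, 0.02, rng)
        donor_b = _triplet_group("b", *b, 4, 0.02, rng)
        res = fusion_test(focal, donor_a, donor_b)
        assert res.fusion_flagged
        assert res.verdicts["before"].verdict == "donorA"
        assert res.verdicts["domain"].verdict == "donorB"
        assert res.verdicts["after"].verdict == "donorB"

    def test_indistinguishable_donors(self):
        # donorB = donorA pool under shuffled labels: no real signal
        rng, a, _ = self._lineages(2)
        focal = _triplet_group("f", *a, 4, 0.05, rng)
        pool = _triplet_group("d", *a, 8, 0.05, rng)
        order = rng.permutation(8)
        donor_a = [pool[i] for i in order[:4]]
        donor_b = [pool[i] for i in order[4:]]
        res = fusion_test(focal, donor_a, donor_b)
        assert all(v.verdict == "indistinguishable"
                   for v in res.verdicts.values())
        assert not res.fusion_flagged

    def test_label_swap_symmetry(self):
        rng, a, b = self._lineages(3)
        focal = _triplet_group("f", *a, 3, 0.02, rng)
        donor_a = _triplet_group("a", *a, 3, 0.02, rng)
        donor_b = _triplet_group("b", *b, 3, 0.02, rng)
        r1 = fusion_test(focal, donor_a, donor_b)
        r2 = fusion_test(focal, donor_b, donor_a)
        for seg in fd.SEGMENTS:
            assert r1.verdicts[seg].pvalue == pytest.approx(
                r2.verdicts[seg].pvalue)
            v1, v2 = r1.verdicts[seg].verdict, r2.verdicts[seg].verdict
            swap = {"donorA": "donorB", "donorB": "donorA",
                    "indistinguishable": "indistinguishable"}
            assert v2 == swap[v1]

    def test_empty_group_rejected(self):
        rng, a, b = self._lineages(4)
        donor_a = _triplet_group("a", *a, 3, 0.02, rng)
        with pytest.raises(ValueError, match="focal"):
            fusion_test([], donor_a, donor_a)

    def test_underpowered_warning(self):
        rng, a, b = self._lineages(5)
        focal = _triplet_group("f", *a, 1, 0.02, rng)
        donor_a = _triplet_group("a", *a, 1, 0.02, rng)
        donor_b = _triplet_group("b", *b, 1, 0.02, rng)
        with pytest.warns(UserWarning, match="underpowered"):
            fusion_test(focal, donor_a, donor_b)


class TestConservation:
    def test_identical_rows_score_one(self):
        score, classes, degenerate = conservation_score(
            {"a": "MKTA", "b": "MKTA", "c": "MKTA"})
        assert score == 1.0
        assert not degenerate

    def test_boundary_inclusive(self):
        rows = {f"s{i}": s for i, s in
                enumerate(["A", "A", "A", "A", "C"])}  # 4/5 = 0.8
        score, classes, _ = conservation_score(rows, threshold=0.8)
        assert score == 1.0
        rows["s4"] = "C"
        rows["s3"] = "C"  # 3/5 = 0.6 < 0.8
        score2, _, _ = conservation_score(rows, threshold=0.8)
        assert score2 == 0.0

    def test_single_row_degenerate(self):
        score, _, degenerate = conservation_score({"a": "MKTA"})
        assert score == 1.0 and degenerate

    def test_row_order_invariance(self):
        rows = {"a": "MKTA", "b": "MKTW", "c": "MKSA"}
        s1, _, _ = conservation_score(rows)
        s2, _, _ = conservation_score(dict(reversed(list(rows.items()))))
        assert s1 == s2

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        base = random_protein(60, rng)
        rows = {f"s{i}": mutate_protein(base, 0.2, rng) for i in range(8)}
        prev = 1.1
        for thr in (0.5, 0.7, 0.8, 0.9, 1.0):
            s, _, _ = conservation_score(rows, thr)
            assert s <= prev
            prev = s

    def test_low_rate_clade_scores_higher(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = random_protein(80, rng)
            rows = {}
            labels = {}
            for i in range(6):
                rows[f"lo{i}"] = mutate_protein(base, 0.03, rng)
                labels[f"lo{i}"] = "low"
                rows[f"hi{i}"] = mutate_protein(base, 0.35, rng)
                labels[f"hi{i}"] = "high"
            res = conservation_summary(MultipleAlignment(rows), labels)
            scores = {r["clade"]: r["score"] for r in res}
            assert scores["low"] > scores["high"]
            assert res[0]["clade"] == "low" and res[0]["rank"] == 1


class TestDosage:
    def _setup(self):
        genes = [
            _gene("A_i1", "M" * 50, "A"), _gene("A_i2", "M" * 50, "A",
                                                chrom="chr2"),
            _gene("A_m1", "M" * 30, "A", chrom="chr3"),
            _gene("B_i1", "M" * 50, "B"),
            _gene("B_m1", "M" * 30, "B", chrom="chr3"),
            _gene("B_m2", "M" * 30, "B", chrom="chr3", start=200),
        ]
        genomes = [
            AnnotatedGenome.from_records("A", [g for g in genes
                                               if g.genome_id == "A"]),
            AnnotatedGenome.from_records("B", [g for g in genes
                                               if g.genome_id == "B"]),
        ]
        communities = [
            CliqueCommunity("IPMS", frozenset({"A_i1", "A_i2", "B_i1"}), 3),
            CliqueCommunity("MAM", frozenset({"A_m1", "B_m1", "B_m2"}), 3),
        ]
        arch = {"A_i1": "IPMS-like", "A_i2": "IPMS-like",
                "A_m1": "MAM-like", "B_i1": "IPMS-like",
                "B_m1": "MAM-like", "B_m2": "MAM-like"}
        return genomes, genes, communities, arch

    def test_counts_sum_to_family_size(self):
        genomes, genes, communities, arch = self._setup()
        profiles = dosage_profile(genomes, genes, communities, arch)
        for genome in genomes:
            fam = [g for g in genes if g.genome_id == genome.genome_id]
            total = sum(p.gene_count for p in profiles
                        if p.genome_id == genome.genome_id)
            assert total == len(fam)

    def test_planted_compensatory_scenario(self):
        # genome A: WGT doubled IPMS (2) and lost one MAM (1);
        # genome B: 1 IPMS, 2 MAM -> deltas IPMS +1, MAM -1 on that branch
        genomes, genes, communities, arch = self._setup()
        profiles = dosage_profile(genomes, genes, communities, arch)
        deltas = dosage_deltas(profiles, "B", "A")
        assert deltas["IPMS"] == 1
        assert deltas["MAM"] == -1
        report = dosage_report(profiles, locus_pairs=[("IPMS", "MAM")],
                               genome_pairs=[("B", "A")])
        assert report["compensatory"], "opposite-sign deltas must be flagged"

    def test_no_events_zero_deltas(self):
        genomes, genes, communities, arch = self._setup()
        a_genes = [g for g in genes if g.genome_id == "A"]
        profiles = dosage_profile([genomes[0]], a_genes, communities, arch)
        deltas = dosage_deltas(profiles, "A", "A")
        assert all(v == 0 for v in deltas.values())

    def test_unknown_genome_rejected(self):
        genomes, genes, communities, arch = self._setup()
        bad = _gene("Z_g", "M" * 10, "Z")
        with pytest.raises(ValueError, match="unknown genome"):
            dosage_profile(genomes, genes + [bad], communities, arch)

    def test_power_of_two_flag(self):
        genomes, genes, communities, arch = self._setup()
        profiles = dosage_profile(genomes, genes, communities, arch)
        report = dosage_report(profiles, wgd_multiplier={"A": 2, "B": 2})
        flagged = {(r["genome"], r["locus"])
                   for r in report["non_power_of_two"]}
        assert ("B", "MAM") not in flagged   # 2 = 2^1
        assert ("B", "IPMS") not in flagged  # 1 = 2^0
        # 3 is not a power of two
        extra = _gene("B_m3", "M" * 30, "B", chrom="chr3", start=400)
        communities2 = [communities[0],
                        CliqueCommunity("MAM", communities[1].members
                                        | {"B_m3"}, 3)]
        genomes2 = [genomes[0], AnnotatedGenome.from_records(
            "B", [g for g in genes if g.genome_id == "B"] + [extra])]
        profiles2 = dosage_profile(genomes2, genes + [extra], communities2,
                                   arch | {"B_m3": "MAM-like"})
        report2 = dosage_report(profiles2, wgd_multiplier={"B": 2})
        assert ("B", "MAM") in {(r["genome"], r["locus"])
                                for r in report2["non_power_of_two"]}


class TestClassifyDuplicationsToy:
    def test_tandem_pair_called(self, default_run):
        from syntegraph import homology
        from syntegraph.collinearity import collinearity_scan
        from syntegraph.network import (build_network, clique_communities,
                                        extract_family_subnetwork)
        cfg, tree, genomes, log = default_run
        hits = homology.all_vs_all(genomes)
        blocks = collinearity_scan(genomes, hits)
        g = build_network(blocks, genomes)
        fam = {gid: t for gid, t in log.leaf_truth.items() if t.is_family}
        sub = extract_family_subnetwork(g, list(fam), window=25)
        coms = clique_communities(sub, k=3)
        gm = {x.gene_id: x for gmm in genomes for x in gmm.genes()}
        calls = fd.classify_duplications([gm[x] for x in fam], g, coms,
                                         genomes)
        assert len(calls) == len(fam)
        by_id = {c.gene_id: c for c in calls}
        # every simulated tandem child that stayed adjacent must be tandem
        for ev in log.events_of_kind("tandem_dup"):
            child = ev.child_genes[0]
            if child not in by_id:
                continue
            rec = gm[child]
            near = [o for o in genomes if o.genome_id == rec.genome_id]
            fam_same_chrom = [gm[x] for x in fam
                             if gm[x].genome_id == rec.genome_id
                             and gm[x].chrom == rec.chrom
                             and x != child]
            if any(abs(o.ordinal - rec.ordinal) <= 5
                   for o in fam_same_chrom):
                assert by_id[child].type == "tandem"
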