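"""Nos-gene-cluster reconstruction around nosZ anchors."""

import numpy as np
import pytest

from denitscan.errors import ClusterError
from denitscan.features import SignalCall, compute_features
from denitscan.noscluster import assign_clade, find_nos_clusters
from denitscan.profile_hmm import HmmHit, search_proteome
from denitscan.seqio import GeneRecord
from denitscan.synthetic import GenotypeSpec, generate_genome


def nosz_hit(model="nosZII", pid="p1"):
    return HmmHit(pid, model, 200.0, True, (1, 100), True)


class TestAssignClade:
    @pytest.mark.parametrize(
        "model, signal, expected",
        [
            ("nosZII", "sec_spi", "II"),
            ("nosZII", "none", "II"),
            ("nosZII", "tat", "ambiguous"),
            ("nosZI", "tat", "I"),
            ("nosZI", "none", "I"),
            ("nosZI", "sec_spi", "ambiguous"),
        ],
    )
    def test_model_signal_matrix(self, model, signal, expected):
        assert assign_clade(nosz_hit(model), SignalCall(signal)) == expected

    def test_non_nosz_hit_rejected(self):
        with pytest.raises(ClusterError):
            assign_clade(HmmHit("p", "qnor", 50.0, True, None, True), None)


@pytest.fixture(scope="module")
def complete_genome(registry):
    spec = GenotypeSpec(
        "g1",
        genes=("narG", "narH", "nirK", "qnor", "nosZII"),
        ngc_layout=("nosC", "nosZ", "nosB", "nosD", "nosY", "nosF"),
        seed=424242,
    )
    genome = generate_genome(spec, registry)
    hits = search_proteome(registry, list(genome.proteins))
    labels = {gid: lab for gid, lab in genome.truth["labels"]}
    return genome, hits, labels


class TestFindNosClusters:
    def test_layout_recovered_with_all_slots(self, complete_genome):
        genome, hits, labels = complete_genome
        clusters = find_nos_clusters(
            list(genome.genes), hits, proteins=list(genome.proteins),
            labels=labels,
        )
        assert len(clusters) == 1
        c = clusters[0]
        assert c.clade == "II"
        truth = genome.truth["ngc_slots"]
        for slot in ("nosC", "nosB", "nosD", "nosY", "nosF"):
            assert c.components[slot].gene_id == truth[slot]
        assert c.anchor.gene_id == truth["nosZ"]
        assert c.order_string() == "nosC>nosZ>nosB>nosD>nosY>nosF"

    def test_scattered_genes_leave_slots_empty(self, complete_genome, registry):
        """The same proteins shuffled across contigs: no neighborhood, so
        nosC/nosB stay unfilled."""
        genome, hits, labels = complete_genome
        rng = np.random.default_rng(99)
        scattered = []
        counters = {}
        for g in sorted(genome.genes, key=lambda g: g.gene_id):
            contig = f"c{rng.integers(0, 8)}"
            rank = counters.get(contig, 0) + 1
            counters[contig] = rank
            start = 1000 * rank + 1
            scattered.append(
                GeneRecord(g.gene_id, contig, start, start + 89, "+",
                           g.protein_id, rank)
            )
        clusters = find_nos_clusters(
            scattered, hits, proteins=list(genome.proteins), labels=labels
        )
        assert len(clusters) == 1
        assert "nosC" not in clusters[0].components
        assert "nosB" not in clusters[0].components

    def test_two_clusters_share_no_components(self, registry):
        """Two ngc copies on one genome yield two independent clusters."""
        spec = GenotypeSpec(
            "g2",
            genes=("nosZII",),
            ngc_layout=("nosC", "nosZ", "nosB"),
            seed=7,
            n_decoys=4,
        )
        g1 = generate_genome(spec, registry)
        # duplicate the cluster further along the same contig
        genes = list(g1.genes)
        proteins = list(g1.proteins)
        contig = g1.truth["ngc_slots"]["nosZ"]
        anchor_contig = next(
            g.contig_id for g in genes if g.gene_id == contig
        )
        tail_rank = max(g.rank for g in genes if g.contig_id == anchor_contig)
        tail_pos = max(g.end for g in genes if g.contig_id == anchor_contig)
        cluster_ids = [
            g1.truth["ngc_slots"][s] for s in ("nosC", "nosZ", "nosB")
        ]
        for i, gid in enumerate(cluster_ids, start=1):
            src = next(p for p in proteins if p.id == gid)
            new_id = f"{gid}_copy"
            proteins.append(type(src)(new_id, src.residues, src.description))
            start = tail_pos + 500 * i
            genes.append(
                GeneRecord(new_id, anchor_contig, start, start + 89, "+",
                           new_id, tail_rank + i)
            )
        hits = search_proteome(registry, proteins)
        clusters = find_nos_clusters(genes, hits, proteins=proteins)
        assert len(clusters) == 2
        comp_sets = [
            {c.anchor.gene_id} | {g.gene_id for g in c.components.values()}
            for c in clusters
        ]
        assert not (comp_sets[0] & comp_sets[1])
        for c in clusters:
            # components stay local to each anchor
            assert abs(c.components["nosB"].rank - c.anchor.rank) <= 2

    def test_output_independent_of_gene_order(self, complete_genome):
        genome, hits, labels = complete_genome
        genes = list(genome.genes)
        rng = np.random.default_rng(5)
        shuffled = [genes[i] for i in rng.permutation(len(genes))]
        a = find_nos_clusters(genes, hits, proteins=list(genome.proteins),
                              labels=labels)
        b = find_nos_clusters(shuffled, hits, proteins=list(genome.proteins),
                              labels=labels)
        assert [c.filled_slots() for c in a] == [c.filled_slots() for c in b]

    def test_window_enlargement_never_drops_slots(self, complete_genome):
        genome, hits, labels = complete_genome
        small = find_nos_clusters(
            list(genome.genes), hits, proteins=list(genome.proteins),
            labels=labels, window=6,
        )
        large = find_nos_clusters(
            list(genome.genes), hits, proteins=list(genome.proteins),
            labels=labels, window=10,
        )
        for cs, cl in zip(small, large):
            assert set(cs.filled_slots()) <= set(cl.filled_slots())

    def test_missing_gene_record_for_hit_rejected(self, complete_genome):
        genome, hits, labels = complete_genome
        anchor_gid = genome.truth["ngc_slots"]["nosZ"]
        genes = [g for g in genome.genes if g.gene_id != anchor_gid]
        with pytest.raises(ClusterError, match="no gene record"):
            find_nos_clusters(genes, hits, proteins=list(genome.proteins))

    def test_adjacent_nor_slot(self, registry):
        spec = GenotypeSpec(
            "g3",
            genes=("qnor", "nosZII"),
            ngc_layout=("nosC", "nosZ", "nosB", "nosD", "nosY", "nosF", "qnor"),
            seed=31,
        )
        genome = generate_genome(spec, registry)
        hits = search_proteome(registry, list(genome.proteins))
        labels = {gid: lab for gid, lab in genome.truth["labels"]}
        clusters = find_nos_clusters(
            list(genome.genes), hits, proteins=list(genome.proteins),
            labels=labels,
        )
        assert len(clusters) == 1
        c = clusters[0]
        assert c.adjacent_nor_gene == "qnor"
        assert c.components["adjacent_nor"].gene_id \
            == genome.truth["ngc_slots"]["adjacent_nor"]
        assert c.order_string().endswith(">qnor")

    def test_recovery_over_many_seeded_replicates(self, registry):
        """Noise-free synthetic genomes: slot precision and recall stay at
        1.0 across 50 seeded replicates."""
        n_exact = 0
        for rep in range(50):
            spec = GenotypeSpec(
                f"rep{rep}",
                genes=("nosZII",),
                ngc_layout=("nosC", "nosZ", "nosB", "nosD", "nosY", "nosF"),
                seed=50_000 + rep,
                n_decoys=6,
            )
            genome = generate_genome(spec, registry)
            hits = search_proteome(registry, list(genome.proteins))
            labels = {gid: lab for gid, lab in genome.truth["labels"]}
            clusters = find_nos_clusters(
                list(genome.genes), hits, proteins=list(genome.proteins),
                labels=labels,
            )
            truth = {
                (slot, gid)
                for slot, gid in genome.truth["ngc_slots"].items()
                if slot != "nosZ"
            }
            got = set()
            for c in clusters:
                got |= set(c.filled_slots().items())
            n_exact += got == truth
        assert n_exact == 50
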