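"""nosZ-anchored reconstruction of the Nos gene cluster (ngc).

Clade II nitrous oxide reducers carry their nosZ inside a conserved operon,
typically nosC-nosZ-nosB-nosD-nosY-nosF with an occasional copper
chaperone nosL or a quinol-dependent NO reductase immediately adjacent.
This module rebuilds that neighborhood around every nosZ hit on a contig:

* nosC — the nearest upstream gene (read in transcription direction, same
  strand) within the window that carries a C-x-x-C-H cytochrome-c motif;
* nosB — the nearest window gene not claimed by any registry model whose
  transmembrane-helix count is 4 or 6 (excluding model hits keeps the
  ~14-helix qNOR from capturing the slot);
* nosD/nosY/nosF/nosL — filled only from a user-supplied label table, since
  these accessory genes are identified by orthology annotation upstream of
  this tool;
* adjacent_nor — any NOR-step registry hit at gene-rank distance 1 from
  any cluster member.

Adjacency is measured in gene ranks (default window 6 each side), which is
robust to intergenic length; a gene occupies at most one slot and clusters
on the same contig never share components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ClusterError
from .features import ProteinFeatures, SignalCall, compute_features
from .profile_hmm import HmmHit
from .seqio import GeneRecord, SequenceRecord

NOSZ_MODELS = ("nosZI", "nosZII")
LABEL_SLOTS = ("nosD", "nosY", "nosF", "nosL")


@dataclass(frozen=True)
class NosCluster:
    """One nosZ-anchored gene neighborhood."""

    anchor: GeneRecord
    clade: str  # I | II | ambiguous
    components: Mapping[str, GeneRecord]
    adjacent_nor_gene: str | None  # registry model name of the adjacent Nor
    window: int
    contig_id: str

    def order_string(self) -> str:
        """Gene-order string along the contig, e.g.
        ``nosC>nosZ>nosB>nosD>nosY>nosF``."""
        members = [("nosZ", self.anchor)]
        for slot, gene in self.components.items():
            name = self.adjacent_nor_gene if slot == "adjacent_nor" else slot
            members.append((name, gene))
        members.sort(key=lambda m: m[1].rank)
        return ">".join(name for name, _ in members)

    def filled_slots(self) -> dict[str, str]:
        return {slot: g.gene_id for slot, g in self.components.items()}


def assign_clade(nosz_hit: HmmHit, signal_call: SignalCall | str | None) -> str:
    """Clade from model identity corroborated by the export signal.

    Clade II enzymes travel the Sec pathway, clade I the Tat pathway; a
    model/signal conflict is reported as ``ambiguous``, never silently
    overridden.
    """
    if nosz_hit.model_name not in NOSZ_MODELS:
        raise ClusterError(
            f"assign_clade needs a nosZ hit, got {nosz_hit.model_name!r}"
        )
    kind = signal_call.kind if isinstance(signal_call, SignalCall) else (
        signal_call or "none"
    )
    if nosz_hit.model_name == "nosZII":
        return "II" if kind in ("sec_spi", "none") else "ambiguous"
    return "I" if kind in ("tat", "none") else "ambiguous"


def _feature_table(
    proteins: Sequence[SequenceRecord] | None,
    features: Mapping[str, ProteinFeatures] | None,
) -> Mapping[str, ProteinFeatures]:
    if features is not None:
        return features
    if proteins is None:
        raise ClusterError("need either proteins or precomputed features")
    return {p.id: compute_features(p.residues) for p in proteins}


def find_nos_clusters(
    genes: Sequence[GeneRecord],
    hits: Sequence[HmmHit],
    proteins: Sequence[SequenceRecord] | None = None,
    features: Mapping[str, ProteinFeatures] | None = None,
    labels: Mapping[str, str] | None = None,
    window: int = 6,
    registry=None,
) -> list[NosCluster]:
    """Reconstruct one :class:`NosCluster` per passing nosZ hit.

    ``hits`` must include the genome's passing hits (primary assignments
    are used for anchors); ``labels`` optionally maps protein ids to
    nosD/nosY/nosF/nosL.  Output is independent of the input gene order.
    """
    feats = _feature_table(proteins, features)
    labels = labels or {}
    nor_models = (
        set(registry.genes_of_step("NOR")) if registry is not None
        else {"cnor", "qnor", "bnor", "snor"}
    )

    by_protein: dict[str, HmmHit] = {}
    hit_proteins: set[str] = set()
    for h in hits:
        if not h.passes_tc:
            continue
        hit_proteins.add(h.protein_id)
        if h.primary:
            by_protein[h.protein_id] = h

    gene_by_protein = {g.protein_id: g for g in genes}
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda g: (g.contig_id, g.rank)):
        by_contig.setdefault(g.contig_id, []).append(g)

    anchors = []
    for pid, h in by_protein.items():
        if h.model_name in NOSZ_MODELS:
            if pid not in gene_by_protein:
                raise ClusterError(
                    f"nosZ hit {pid!r} has no gene record on any contig"
                )
            anchors.append(gene_by_protein[pid])
    anchors.sort(key=lambda g: (g.contig_id, g.rank))

    clusters: list[NosCluster] = []
    claimed: dict[str, set[str]] = {}  # contig -> gene_ids already used

    for anchor in anchors:
        contig = by_contig[anchor.contig_id]
        used = claimed.setdefault(anchor.contig_id, set())
        used.add(anchor.gene_id)
        neighbors = [
            g for g in contig
            if g.gene_id != anchor.gene_id
            and abs(g.rank - anchor.rank) <= window
            and g.gene_id not in used
        ]
        components: dict[str, GeneRecord] = {}

        def _take(slot: str, gene: GeneRecord) -> None:
            components[slot] = gene
            used.add(gene.gene_id)

        # nosC: nearest upstream (transcription direction), same strand,
        # carrying a heme-binding motif
        upstream = [
            g for g in neighbors
            if g.strand == anchor.strand
            and ((anchor.strand == "+" and g.rank < anchor.rank)
                 or (anchor.strand == "-" and g.rank > anchor.rank))
            and feats.get(g.protein_id) is not None
            and feats[g.protein_id].cxxch >= 1
        ]
        if upstream:
            _take("nosC", min(upstream, key=lambda g: abs(g.rank - anchor.rank)))

        # nosB: nearest unclaimed, un-hit gene with 4 or 6 TM helices
        nosb = [
            g for g in neighbors
            if g.gene_id not in used
            and g.protein_id not in hit_proteins
            and feats.get(g.protein_id) is not None
            and feats[g.protein_id].tm.count in (4, 6)
        ]
        if nosb:
            _take("nosB", min(nosb, key=lambda g: abs(g.rank - anchor.rank)))

        # nosD/Y/F/L from the optional label table
        for slot in LABEL_SLOTS:
            cands = [
                g for g in neighbors
                if g.gene_id not in used and labels.get(g.protein_id) == slot
            ]
            if cands:
                _take(slot, min(cands, key=lambda g: abs(g.rank - anchor.rank)))

        # adjacent Nor: any NOR-step registry hit at rank distance 1 from
        # any cluster member
        member_ranks = {anchor.rank} | {g.rank for g in components.values()}
        adjacent_nor_gene = None
        nor_cands = []
        for g in contig:
            if g.gene_id in used:
                continue
            h = by_protein.get(g.protein_id)
            if h is None or h.model_name not in nor_models:
                continue
            if any(abs(g.rank - r) == 1 for r in member_ranks):
                nor_cands.append((g, h.model_name))
        if nor_cands:
            gene, model_name = min(
                nor_cands, key=lambda gm: abs(gm[0].rank - anchor.rank)
            )
            _take("adjacent_nor", gene)
            adjacent_nor_gene = model_name

        anchor_hit = by_protein[anchor.protein_id]
        signal = feats.get(anchor.protein_id)
        clusters.append(
            NosCluster(
                anchor=anchor,
                clade=assign_clade(
                    anchor_hit, signal.signal if signal else None
                ),
                components=components,
                adjacent_nor_gene=adjacent_nor_gene,
                window=window,
                contig_id=anchor.contig_id,
            )
        )
    return clusters


NGC_COLUMNS = (
    "genome", "contig", "anchor", "clade",
    "nosC", "nosB", "nosD", "nosY", "nosF", "nosL", "adjacent_nor",
    "gene_order",
)


def cluster_row(genome: str, cluster: NosCluster) -> dict:
    slots = cluster.filled_slots()
    return {
        "genome": genome,
        "contig": cluster.contig_id,
        "anchor": cluster.anchor.gene_id,
        "clade": cluster.clade,
        **{s: slots.get(s, "") for s in
           ("nosC", "nosB", "nosD", "nosY", "nosF", "nosL", "adjacent_nor")},
        "gene_order": cluster.order_string(),
    }
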