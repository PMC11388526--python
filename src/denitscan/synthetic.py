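"""Fully labeled synthetic inputs: seed alignments, proteomes, contigs.

Every stage of the scanner is testable offline because this module can
fabricate (i) reference alignments to build profiles from, (ii) whole
annotated genomes — protein FASTA plus GFF3 plus a truth table — whose
denitrification gene content, Nos-gene-cluster layout, signal peptides and
membrane proteins are implanted by construction, and (iii) multi-genome
benchmark panels with a manifest for one-command end-to-end evaluation.

Implants are fresh samples from the named registry models; decoys are
residue shuffles of implants (the hardest negatives that preserve length
and composition, which is exactly what trusted-cutoff calibration must
reject).  Noise knobs exist for robustness exploration but default to the
noise-free regime.  All outputs are pure functions of (spec, registry,
seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SimulationError
from .profile_hmm import sample_sequence, shuffle_residues
from .seqio import (
    AMINO_ACIDS,
    Alignment,
    GeneRecord,
    SequenceRecord,
    write_fasta,
    write_gff,
)

# --------------------------------------------------------------------------
# engineered building blocks

#: Sec/SPI-type export signal: charged n-region, leucine h-region, A-Q-A
#: cleavage motif (cut after the final A).
SEC_PEPTIDE = "MKR" + "L" * 10 + "AQA"

#: Tat-type export signal: twin-arginine then an h-region.
TAT_PEPTIDE = "MSRRQF" + "L" * 10 + "AQA"

_SEGMENT_CYCLE = "LIV"
_LINKER_CYCLE = "SGNQ"


def engineered_tm_protein(
    n_segments: int = 4, segment_len: int = 21, linker_len: int = 15
) -> str:
    """A membrane protein with exactly ``n_segments`` hydrophobic helices.

    Poly-LIV segments separated by polar SGNQ linkers, with polar leader and
    tail so every helix is interior.  The default four-segment form mimics
    the NosB membrane lipoprotein (4 or 6 transmembrane helices).
    """
    if n_segments < 1:
        raise SimulationError("need at least one segment")
    seg = (_SEGMENT_CYCLE * segment_len)[:segment_len]
    linker = (_LINKER_CYCLE * linker_len)[:linker_len]
    body = linker.join([seg] * n_segments)
    return "M" + linker + body + linker


def _random_protein(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list(AMINO_ACIDS))
    return "".join(rng.choice(letters, size=length))


def cxxch_protein(rng: np.random.Generator, length: int = 110) -> str:
    """A random protein carrying one C-x-x-C-H heme-binding motif, the
    cytochrome-c proxy used for nosC candidates."""
    body = list(_random_protein(rng, length))
    pos = int(rng.integers(20, max(21, length - 20)))
    body[pos:pos + 5] = list("CAACH")
    return "".join(body)


# --------------------------------------------------------------------------
# reference alignments


def generate_reference_msa(
    seed: int,
    length: int = 100,
    n_seqs: int = 12,
    substitution_rate: float = 0.15,
    indel_rate: float | None = None,
) -> Alignment:
    """A seed-alignment stand-in: ancestor plus substituted descendants.

    The ancestor is drawn from a Dirichlet-perturbed background
    composition; each descendant substitutes every site independently at
    ``substitution_rate`` and sparse indels add low-occupancy insert
    columns and short deletions.  ``indel_rate`` defaults to a tenth of the
    substitution rate, so a rate of 0 reproduces the ancestor exactly in
    every row.  Deterministic per seed.
    """
    if n_seqs < 4:
        raise SimulationError("n_seqs must be >= 4")
    if length < 30:
        raise SimulationError("length must be >= 30")
    if not 0.0 <= substitution_rate < 1.0:
        raise SimulationError("substitution_rate must be in [0, 1)")
    if indel_rate is None:
        indel_rate = substitution_rate / 10.0
    rng = np.random.default_rng(seed)
    K = len(AMINO_ACIDS)
    letters = np.array(list(AMINO_ACIDS))
    composition = rng.dirichlet(np.full(K, 20.0 / K) * K)
    ancestor = rng.choice(letters, size=length, p=composition)

    rows = []
    for _ in range(n_seqs):
        row = ancestor.copy()
        if substitution_rate > 0:
            mask = rng.random(length) < substitution_rate
            row[mask] = rng.choice(letters, size=int(mask.sum()), p=composition)
        if indel_rate > 0:
            n_del = rng.poisson(indel_rate * length / 2)
            for _ in range(n_del):
                start = int(rng.integers(0, length))
                run = int(rng.integers(1, 4))
                row[start:start + run] = "-"
        rows.append(row)

    # sparse insertion columns: one row carries a residue, the rest gaps
    matrix = np.array(rows)
    if indel_rate > 0:
        n_ins = rng.poisson(indel_rate * length / 2)
        for _ in range(n_ins):
            col = np.full(n_seqs, "-")
            owner = int(rng.integers(0, n_seqs))
            col[owner] = rng.choice(letters, p=composition)
            at = int(rng.integers(0, matrix.shape[1] + 1))
            matrix = np.insert(matrix, at, col, axis=1)

    records = tuple(
        SequenceRecord(f"seq{i + 1}", "".join(matrix[i]))
        for i in range(n_seqs)
    )
    return Alignment(records)


# --------------------------------------------------------------------------
# genome generation

#: layout slot names accepted in ``ngc_layout``
NGC_SLOTS = ("nosC", "nosZ", "nosB", "nosD", "nosY", "nosF", "nosL", "qnor")

DEFAULT_NGC_LAYOUT = ("nosC", "nosZ", "nosB", "nosD", "nosY", "nosF")


@dataclass(frozen=True)
class GenotypeSpec:
    """Recipe for one synthetic genome."""

    genome_id: str
    genes: tuple[str, ...] = ()
    ngc_layout: tuple[str, ...] | None = None
    n_decoys: int = 10
    n_contigs: int = 2
    dnra: tuple[str, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class SyntheticGenome:
    """One generated genome plus its intended truth labels."""

    genome_id: str
    proteins: tuple[SequenceRecord, ...]
    genes: tuple[GeneRecord, ...]
    truth: dict


def _intended_steps(genes: set[str], registry) -> dict[str, bool]:
    step_of = registry.step_map()
    present = {s: False for s in ("NAR", "NIR", "NOR", "NOS")}
    if {"narG", "narH"} <= genes or "napA" in genes:
        present["NAR"] = True
    for g in genes:
        step = step_of.get(g)
        if step in ("NIR", "NOR", "NOS"):
            present[step] = True
    return present


def _intended_fine_label(genes: set[str], registry) -> str:
    p = _intended_steps(genes, registry)
    nar, nir, nor, nos = p["NAR"], p["NIR"], p["NOR"], p["NOS"]
    if nar and nir and nor and nos:
        return "complete"
    if nar and nir and nor:
        return "truncated"
    if nor and not (nar or nir or nos):
        return "nor_only"
    if nos and not (nar or nir or nor):
        return "nos_only"
    if not (nar or nir or nor or nos):
        return "non_denitrifying"
    return "modular"


_COARSE = {"complete": "C", "truncated": "T", "nor_only": "M",
           "nos_only": "M", "modular": "M", "non_denitrifying": "N"}


def generate_genome(spec: GenotypeSpec, registry) -> SyntheticGenome:
    """Realize a :class:`GenotypeSpec` as proteins + gene coordinates + truth.

    Implanted registry genes are fresh model samples; clade II nosZ gets an
    engineered Sec peptide prepended (clade I a Tat peptide); layout slots
    nosC/nosB are an engineered heme-motif protein and a 4-TM membrane
    protein; nosD/Y/F/L are labeled placeholder proteins; decoys are
    shuffles of the implants.  The ngc layout occupies consecutive ranks on
    the first contig, all on the plus strand.
    """
    rng = np.random.default_rng(spec.seed)
    layout = tuple(spec.ngc_layout) if spec.ngc_layout else None
    if layout:
        bad = [s for s in layout if s not in NGC_SLOTS]
        if bad:
            raise SimulationError(f"unknown ngc layout slots: {bad}")
    for g in spec.genes:
        if g not in registry:
            raise SimulationError(f"gene {g!r} not in registry")

    nosz_gene = next(
        (g for g in spec.genes if g in ("nosZI", "nosZII")), None
    )
    if layout and "nosZ" in layout and nosz_gene is None:
        raise SimulationError(
            "ngc_layout includes nosZ but spec.genes has no nosZI/nosZII"
        )

    # role -> residues; roles keep implant identity for the truth table
    proteins: list[tuple[str, str]] = []  # (role, residues)

    def implant(gene: str) -> str:
        rec = sample_sequence(registry[gene].model, rng)
        res = rec.residues
        if gene == "nosZII":
            res = SEC_PEPTIDE + res
        elif gene == "nosZI":
            res = TAT_PEPTIDE + res
        return res

    cluster_roles: list[str] = []
    placed_in_cluster: set[str] = set()
    if layout:
        for slot in layout:
            if slot == "nosZ":
                cluster_roles.append(f"gene:{nosz_gene}")
                placed_in_cluster.add(nosz_gene)
            elif slot == "qnor":
                cluster_roles.append("gene:qnor")
                placed_in_cluster.add("qnor")
            else:
                cluster_roles.append(f"slot:{slot}")

    free_genes = [g for g in spec.genes if g not in placed_in_cluster]
    free_roles = [f"gene:{g}" for g in free_genes]

    role_residues: dict[str, str] = {}
    for role in cluster_roles + free_roles:
        kind, _, name = role.partition(":")
        if kind == "gene":
            role_residues[role] = implant(name)
        elif name == "nosC":
            role_residues[role] = cxxch_protein(rng)
        elif name == "nosB":
            role_residues[role] = engineered_tm_protein(4)
        else:  # nosD / nosY / nosF / nosL placeholders
            role_residues[role] = _random_protein(rng, 90)

    implant_residues = [
        role_residues[r] for r in free_roles + cluster_roles
    ] or [_random_protein(rng, 120)]
    decoys = []
    for i in range(spec.n_decoys):
        src = implant_residues[i % len(implant_residues)]
        decoys.append(
            shuffle_residues(SequenceRecord("decoy", src), rng).residues
        )

    # --- assemble contigs: the cluster occupies consecutive ranks on the
    # first contig, padded by decoys; free gene implants go to the other
    # contigs so no unintended gene ends up adjacent to the cluster
    n_contigs = max(1, spec.n_contigs)
    gene_items = [(r, role_residues[r]) for r in free_roles]
    decoy_items = [(f"decoy:{i + 1}", d) for i, d in enumerate(decoys)]
    order = rng.permutation(len(decoy_items))
    decoy_items = [decoy_items[i] for i in order]

    contigs: list[list[tuple[str, str]]] = [[] for _ in range(n_contigs)]
    if cluster_roles and n_contigs >= 2:
        half = len(decoy_items) // 2
        cluster_items = [(r, role_residues[r]) for r in cluster_roles]
        pad = decoy_items[:half]
        contigs[0] = pad[: len(pad) // 2] + cluster_items + pad[len(pad) // 2:]
        rest = decoy_items[half:] + gene_items
        for idx, item in enumerate(rest):
            contigs[1 + idx % (n_contigs - 1)].append(item)
    else:
        loose = decoy_items + gene_items
        for idx, item in enumerate(loose):
            contigs[idx % n_contigs].append(item)
        if cluster_roles:
            insert_at = min(1, len(contigs[0]))
            cluster_items = [(r, role_residues[r]) for r in cluster_roles]
            contigs[0][insert_at:insert_at] = cluster_items

    cluster_role_set = set(cluster_roles)
    proteins_out: list[SequenceRecord] = []
    genes_out: list[GeneRecord] = []
    truth_slots: dict[str, str] = {}
    labels: list[tuple[str, str]] = []  # (gene_id, nosD/Y/F/L label)
    role_of_gene: dict[str, str] = {}
    counter = 0
    for c_idx, items in enumerate(contigs):
        contig_id = f"{spec.genome_id}_c{c_idx + 1}"
        pos = 1
        for rank, (role, residues) in enumerate(items, start=1):
            counter += 1
            gid = f"{spec.genome_id}_g{counter:03d}"
            length_nt = 3 * len(residues)
            start = pos
            end = pos + length_nt - 1
            pos = end + int(rng.integers(20, 200))
            strand = "+" if role in cluster_role_set else \
                str(rng.choice(["+", "-"]))
            proteins_out.append(SequenceRecord(gid, residues, role))
            genes_out.append(
                GeneRecord(gid, contig_id, start, end, strand, gid, rank)
            )
            role_of_gene[gid] = role
            if role in cluster_role_set:
                kind, _, name = role.partition(":")
                slot = "nosZ" if name in ("nosZI", "nosZII") else name
                if kind == "gene" and name == "qnor":
                    slot = "adjacent_nor"
                truth_slots[slot] = gid
                if name in ("nosD", "nosY", "nosF", "nosL"):
                    labels.append((gid, name))

    intended_genes = set(spec.genes)
    fine = _intended_fine_label(intended_genes, registry)
    truth = {
        "genome_id": spec.genome_id,
        "fine_label": fine,
        "coarse_label": _COARSE[fine],
        "genes": tuple(sorted(intended_genes)),
        "dnra": tuple(sorted(spec.dnra)),
        "nosz_clade": (
            "II" if nosz_gene == "nosZII"
            else "I" if nosz_gene == "nosZI" else "none"
        ),
        "ngc_slots": truth_slots,
        "labels": tuple(labels),
        "roles": role_of_gene,
    }
    return SyntheticGenome(
        genome_id=spec.genome_id,
        proteins=tuple(proteins_out),
        genes=tuple(genes_out),
        truth=truth,
    )


# --------------------------------------------------------------------------
# benchmark panels


def default_panel(seed: int = 0) -> tuple[GenotypeSpec, ...]:
    """A 12-genome panel mirroring the enrichment study's composition:
    5 complete, 1 truncated, 4 modular (one of them a pure NO reducer) and
    2 non-denitrifying genomes."""
    base = int(seed) % (2 ** 31 - 100)
    s = lambda i: base + i
    return (
        GenotypeSpec(
            "complete_1",
            genes=("narG", "narH", "nirK", "nirS", "qnor", "bnor", "nosZII"),
            ngc_layout=("nosC", "nosZ", "nosB", "nosD", "nosY", "nosF", "nosL"),
            seed=s(1),
        ),
        GenotypeSpec(
            "complete_2",
            genes=("narG", "narH", "nirK", "qnor", "bnor", "snor", "nosZII"),
            ngc_layout=DEFAULT_NGC_LAYOUT,
            seed=s(2),
        ),
        GenotypeSpec(
            "complete_3",
            genes=("narG", "narH", "nirK", "qnor", "bnor", "snor", "nosZII"),
            ngc_layout=DEFAULT_NGC_LAYOUT,
            dnra=("nirBD",),
            seed=s(3),
        ),
        GenotypeSpec(
            "complete_4",
            genes=("narG", "narH", "nirS", "qnor", "nosZII"),
            ngc_layout=("nosC", "nosZ", "nosB", "nosD", "nosY", "nosF", "qnor"),
            seed=s(4),
        ),
        GenotypeSpec(
            "complete_5",
            genes=("narG", "narH", "nirK", "nirS", "qnor", "bnor", "nosZII"),
            ngc_layout=DEFAULT_NGC_LAYOUT,
            seed=s(5),
        ),
        GenotypeSpec(
            "truncated_1",
            genes=("narG", "narH", "napA", "nirK", "qnor"),
            dnra=("nrfAH",),
            seed=s(6),
        ),
        GenotypeSpec("modular_1", genes=("narG", "narH", "qnor"), seed=s(7)),
        GenotypeSpec("modular_2", genes=("qnor",), dnra=("nirBD",), seed=s(8)),
        GenotypeSpec("modular_3", genes=("narG", "narH", "nirK"), seed=s(9)),
        GenotypeSpec("modular_4", genes=("narG", "narH"), seed=s(10)),
        GenotypeSpec("nondenit_1", seed=s(11)),
        GenotypeSpec("nondenit_2", seed=s(12)),
    )


TRUTH_COLUMNS = (
    "genome", "fine_label", "coarse_label", "genes", "dnra", "nosz_clade",
    "ngc_slots",
)


def generate_benchmark(panel, registry, out_dir) -> Path:
    """Write a benchmark dataset directory and return the manifest path.

    Per genome: ``<id>.faa`` + ``<id>.gff3``.  Shared: ``truth.tsv`` (the
    intended labels), ``labels.tsv`` (nosD/Y/F/L placeholder labels for the
    cluster stage) and ``manifest.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seen = set()
    truth_rows = []
    label_rows = []
    manifest_rows = []
    for spec in panel:
        if spec.genome_id in seen:
            raise SimulationError(f"duplicate genome_id {spec.genome_id!r}")
        seen.add(spec.genome_id)
        genome = generate_genome(spec, registry)
        faa = out_dir / f"{spec.genome_id}.faa"
        gff = out_dir / f"{spec.genome_id}.gff3"
        write_fasta(genome.proteins, faa)
        write_gff(genome.genes, gff)
        t = genome.truth
        truth_rows.append(
            {
                "genome": t["genome_id"],
                "fine_label": t["fine_label"],
                "coarse_label": t["coarse_label"],
                "genes": ";".join(t["genes"]),
                "dnra": ";".join(t["dnra"]),
                "nosz_clade": t["nosz_clade"],
                "ngc_slots": ";".join(
                    f"{slot}={gid}" for slot, gid in sorted(t["ngc_slots"].items())
                ),
            }
        )
        for gid, label in t["labels"]:
            label_rows.append({"genome": t["genome_id"],
                               "protein_id": gid, "label": label})
        manifest_rows.append(
            {"genome": spec.genome_id, "proteome": faa.name, "gff": gff.name}
        )

    def _write_tsv(path, columns, rows):
        with open(path, "w") as fh:
            fh.write("# " + "\t".join(columns) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in columns) + "\n")

    _write_tsv(out_dir / "truth.tsv", TRUTH_COLUMNS, truth_rows)
    _write_tsv(out_dir / "labels.tsv", ("genome", "protein_id", "label"),
               label_rows)
    manifest = out_dir / "manifest.tsv"
    _write_tsv(manifest, ("genome", "proteome", "gff"), manifest_rows)
    return manifest
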