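"""Collapse per-protein hits into per-genome denitrification genotypes.

The pathway is the stepwise reduction NO3- -> NO2- -> NO -> N2O -> N2; each
arrow is one step (NAR, NIR, NOR, NOS).  Step presence follows fixed
backing rules — NAR needs (narG AND narH) or monomeric napA; NIR needs nirK
or nirS; NOR any of the heme-copper oxidase family reductases
(cNOR/qNOR/bNOR/sNOR); NOS either nosZ clade — and the fine genotype label
is a pure function of which steps are present:

    complete          all four steps
    truncated         NAR, NIR, NOR but no NOS (end product N2O)
    nor_only          NOR and nothing else
    nos_only          NOS and nothing else (non-denitrifying N2O reducer)
    non_denitrifying  no step at all
    modular           anything else

Coarse labels fold the fine vocabulary onto four letters: complete -> C,
truncated -> T, nor_only/nos_only/modular -> M, non_denitrifying -> N.

DNRA genes (nirBD, nrfAH) are accepted as externally supplied annotation
flags, not as shipped models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import SearchError
from .profile_hmm import HmmHit

STEPS = ("NAR", "NIR", "NOR", "NOS")
DNRA_FLAGS = frozenset({"nirBD", "nrfAH"})

FINE_TO_COARSE = {
    "complete": "C",
    "truncated": "T",
    "nor_only": "M",
    "nos_only": "M",
    "modular": "M",
    "non_denitrifying": "N",
}


@dataclass(frozen=True)
class StepPresence:
    """Which steps are backed, with full per-step evidence retained.

    ``steps`` holds only genes that actually back the step under the rules
    (an unpaired narG backs nothing); ``evidence`` retains every passing
    gene assigned to the step regardless.
    """

    steps: Mapping[str, frozenset[str]]
    evidence: Mapping[str, frozenset[str]]
    accessory: frozenset[str] = frozenset()
    dnra: frozenset[str] = frozenset()

    def present(self, step: str) -> bool:
        return bool(self.steps.get(step))

    @property
    def present_steps(self) -> tuple[str, ...]:
        return tuple(s for s in STEPS if self.present(s))


@dataclass(frozen=True)
class GenotypeCall:
    fine_label: str
    coarse_label: str
    evidence: StepPresence
    nosz_clade: str  # I | II | none | ambiguous


def summarize_steps(
    hits: Iterable[HmmHit],
    registry,
    dnra_annotations: Iterable[str] | None = None,
) -> StepPresence:
    """Build per-step gene sets from one genome's hits.

    Only passing primary hits contribute gene presence.  narG without narH
    (or vice versa) contributes nothing to NAR but stays in the evidence.
    """
    step_of = registry.step_map()
    genes: set[str] = set()
    for h in hits:
        if h.model_name not in step_of:
            raise SearchError(f"hit references unknown model {h.model_name!r}")
        if h.passes_tc and h.primary:
            genes.add(h.model_name)

    evidence: dict[str, set[str]] = {s: set() for s in STEPS}
    accessory: set[str] = set()
    for g in genes:
        step = step_of[g]
        if step == "ACCESSORY":
            accessory.add(g)
        else:
            evidence[step].add(g)

    steps: dict[str, frozenset[str]] = {}
    nar = set()
    if {"narG", "narH"} <= genes:
        nar |= {"narG", "narH"}
    if "napA" in genes:
        nar.add("napA")
    # user-registered extra NAR genes back the step directly
    nar |= {g for g in evidence["NAR"] if g not in ("narG", "narH", "napA")}
    steps["NAR"] = frozenset(nar)
    for step in ("NIR", "NOR", "NOS"):
        steps[step] = frozenset(evidence[step])

    dnra = frozenset(dnra_annotations or ())
    unknown = dnra - DNRA_FLAGS
    if unknown:
        raise SearchError(f"unknown DNRA flags: {sorted(unknown)}")
    return StepPresence(
        steps={s: frozenset(v) for s, v in steps.items()},
        evidence={s: frozenset(v) for s, v in evidence.items()},
        accessory=frozenset(accessory),
        dnra=dnra,
    )


def classify(sp: StepPresence, nosz_signal: str | None = None) -> GenotypeCall:
    """Assign the fine and coarse genotype label for one genome.

    ``nosz_signal`` optionally carries the signal-peptide kind detected on
    the genome's nosZ protein; it corroborates the clade call and a
    model/signal conflict yields clade ``ambiguous`` rather than a silent
    override.
    """
    nar, nir, nor, nos = (sp.present(s) for s in STEPS)
    if nar and nir and nor and nos:
        fine = "complete"
    elif nar and nir and nor:
        fine = "truncated"
    elif nor and not (nar or nir or nos):
        fine = "nor_only"
    elif nos and not (nar or nir or nor):
        fine = "nos_only"
    elif not (nar or nir or nor or nos):
        fine = "non_denitrifying"
    else:
        fine = "modular"

    nos_genes = sp.steps.get("NOS", frozenset())
    if not nos_genes:
        clade = "none"
    elif nos_genes == {"nosZI"}:
        clade = "I"
        if nosz_signal == "sec_spi":
            clade = "ambiguous"
    elif nos_genes == {"nosZII"}:
        clade = "II"
        if nosz_signal == "tat":
            clade = "ambiguous"
    else:
        clade = "ambiguous"

    return GenotypeCall(
        fine_label=fine,
        coarse_label=FINE_TO_COARSE[fine],
        evidence=sp,
        nosz_clade=clade,
    )


GENOTYPE_COLUMNS = (
    "genome", "fine_label", "coarse_label",
    "NAR", "NIR", "NOR", "NOS", "accessory", "nosz_clade", "dnra_flags",
)


def genotype_row(genome: str, call: GenotypeCall) -> dict:
    sp = call.evidence
    return {
        "genome": genome,
        "fine_label": call.fine_label,
        "coarse_label": call.coarse_label,
        **{s: ";".join(sorted(sp.steps.get(s, ()))) for s in STEPS},
        "accessory": ";".join(sorted(sp.accessory)),
        "nosz_clade": call.nosz_clade,
        "dnra_flags": ";".join(sorted(sp.dnra)),
    }
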