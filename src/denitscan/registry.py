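"""The denitrification gene-model registry.

The shipped default registry carries twelve gene models spanning the four
reduction steps plus the clade II accessory lipoprotein nosB:

    NAR  narG, narH (jointly required), napA (monomeric, no napH anywhere)
    NIR  nirK, nirS
    NOR  cnor, qnor, bnor, snor
    NOS  nosZI, nosZII
    ACC  nosB

Six models (nirK, nirS, qnor, bnor, snor, nosB) are of custom-MSA origin;
the rest are seeded the way per-subunit TIGRFAM profiles would be.  The
shipped seed alignments are synthetic stand-ins generated by
:mod:`denitscan.synthetic` (the curated alignments behind the original
profiles are not redistributable); users drop in their own seed MSAs via
the same config schema.  Trusted cutoffs are re-derived at load time by
:func:`~denitscan.profile_hmm.calibrate_tc` on model samples versus their
residue shuffles, with per-gene seeds recorded in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .profile_hmm import (
    ProfileHMM,
    build_profile,
    calibrate_tc,
    read_model,
    sample_sequence,
    shuffle_residues,
    write_model,
)
from .seqio import read_alignment

VALID_STEPS = frozenset({"NAR", "NIR", "NOR", "NOS", "ACCESSORY"})
VALID_ORIGINS = frozenset({"custom-msa", "tigrfam-seeded"})

DEFAULT_GENES = (
    "narG", "narH", "napA", "nirK", "nirS",
    "cnor", "qnor", "bnor", "snor", "nosZI", "nosZII", "nosB",
)


@dataclass(frozen=True)
class GeneModel:
    """One registry entry: a calibrated profile mapped to a pathway step."""

    gene: str
    step: str
    model: ProfileHMM
    origin: str = "custom-msa"
    active_site: dict[int, frozenset[str]] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self):
        if self.step not in VALID_STEPS:
            raise ConfigError(
                f"gene {self.gene!r}: unknown step {self.step!r} "
                f"(valid: {sorted(VALID_STEPS)})"
            )
        if self.origin not in VALID_ORIGINS:
            raise ConfigError(
                f"gene {self.gene!r}: unknown origin {self.origin!r}"
            )


class GeneModelRegistry:
    """Ordered collection of gene models; iteration order is config order."""

    def __init__(self, entries: list[GeneModel] | None = None):
        self._entries: dict[str, GeneModel] = {}
        for e in entries or []:
            self.register(e)

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self._entries

    def __getitem__(self, gene: str) -> GeneModel:
        return self._entries[gene]

    def register(self, entry: GeneModel, replace: bool = False) -> None:
        """Add or (with ``replace``) overwrite an entry."""
        if entry.gene in self._entries and not replace:
            raise ConfigError(
                f"gene {entry.gene!r} already registered (use replace=True)"
            )
        self._entries[entry.gene] = entry

    def step_map(self) -> dict[str, str]:
        return {e.gene: e.step for e in self}

    def genes_of_step(self, step: str) -> tuple[str, ...]:
        return tuple(e.gene for e in self if e.step == step)

    def save(self, out_dir) -> Path:
        """Serialize to a directory: one model file per gene plus a config
        with explicit trusted cutoffs.  Round-trips through ``load``."""
        out_dir = Path(out_dir)
        (out_dir / "models").mkdir(parents=True, exist_ok=True)
        entries = []
        for e in self:
            model_path = out_dir / "models" / f"{e.gene}.hmm"
            write_model(e.model, model_path)
            entry = {
                "gene": e.gene,
                "step": e.step,
                "origin": e.origin,
                "model": f"models/{e.gene}.hmm",
            }
            if e.model.tc_bits is not None:
                entry["tc_bits"] = float(e.model.tc_bits)
            if e.active_site:
                entry["active_site"] = {
                    int(k): "".join(sorted(v)) for k, v in e.active_site.items()
                }
            if e.notes:
                entry["notes"] = e.notes
            entries.append(entry)
        config_path = out_dir / "registry.yaml"
        with open(config_path, "w") as fh:
            yaml.safe_dump({"genes": entries}, fh, sort_keys=False)
        return config_path


def _parse_active_site(raw) -> dict[int, frozenset[str]]:
    if not raw:
        return {}
    return {int(k): frozenset(str(v)) for k, v in raw.items()}


def load_registry(config_path) -> GeneModelRegistry:
    """Load a registry from a YAML config.

    Each entry names a gene, its step, and either a serialized ``model``
    file or a seed ``msa`` to build from.  A trusted cutoff must come from
    ``tc_bits`` or a ``calibration`` block (n samples vs their shuffles at
    a recorded seed); entries with neither are rejected.
    """
    config_path = Path(config_path)
    base = config_path.parent
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "genes" not in cfg:
        raise ConfigError(f"{config_path}: config must have a 'genes' list")
    defaults = cfg.get("defaults", {})
    occupancy = float(defaults.get("match_occupancy", 0.5))
    pseudo = float(defaults.get("pseudocount_weight", 1.0))

    registry = GeneModelRegistry()
    for raw in cfg["genes"]:
        gene = raw.get("gene")
        if not gene:
            raise ConfigError(f"{config_path}: entry without a gene name")
        if gene in registry:
            raise ConfigError(f"{config_path}: duplicate gene {gene!r}")
        step = raw.get("step", "")
        if "model" in raw:
            model = read_model(base / raw["model"])
        elif "msa" in raw:
            msa = read_alignment(base / raw["msa"], dialect="aligned-fasta")
            model = build_profile(
                msa,
                match_occupancy=occupancy,
                pseudocount_weight=pseudo,
                name=gene,
            )
        else:
            raise ConfigError(
                f"{config_path}: gene {gene!r} needs a 'model' or 'msa'"
            )
        if "tc_bits" in raw:
            model.tc_bits = float(raw["tc_bits"])
        elif "calibration" in raw:
            cal = raw["calibration"]
            n = int(cal.get("n", 30))
            seed = int(cal["seed"])
            rng = np.random.default_rng(seed)
            positives = [sample_sequence(model, rng) for _ in range(n)]
            negatives = [shuffle_residues(p, rng) for p in positives]
            calibrate_tc(model, positives, negatives)
        if model.tc_bits is None:
            raise ConfigError(
                f"{config_path}: gene {gene!r} lacks a trusted cutoff "
                "(provide tc_bits or a calibration block)"
            )
        registry.register(
            GeneModel(
                gene=gene,
                step=step,
                model=model,
                origin=raw.get("origin", "custom-msa"),
                active_site=_parse_active_site(raw.get("active_site")),
                notes=raw.get("notes", ""),
            )
        )
    return registry


def default_config_path() -> Path:
    """Path to the packaged default registry config."""
    return Path(resources.files("denitscan").joinpath("data", "registry.yaml"))


_DEFAULT_CACHE: dict[str, GeneModelRegistry] = {}


def default_registry(refresh: bool = False) -> GeneModelRegistry:
    """The shipped 12-gene registry, built and calibrated on first use."""
    if refresh or "default" not in _DEFAULT_CACHE:
        _DEFAULT_CACHE["default"] = load_registry(default_config_path())
    return _DEFAULT_CACHE["default"]
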