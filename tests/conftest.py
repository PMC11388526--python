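import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from denitscan.profile_hmm import ProfileHMM, build_profile
from denitscan.registry import GeneModel, GeneModelRegistry, default_registry
from denitscan.seqio import Alignment, SequenceRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_alignment(rows, ids=None):
    ids = ids or [f"s{i + 1}" for i in range(len(rows))]
    return Alignment(tuple(SequenceRecord(i, r) for i, r in zip(ids, rows)))


@pytest.fixture
def toy_msa():
    """The two-row hand-computed alignment: one column is gapped in one row."""
    return make_alignment(["AC-E", "ACDE"])


@pytest.fixture
def toy_model(toy_msa):
    return build_profile(toy_msa, pseudocount_weight=1.0, name="toy")


@pytest.fixture(scope="session")
def registry():
    """The shipped 12-gene registry, built and calibrated once per session."""
    return default_registry()


def reduced_models(max_M=4, alphabet="AB", seed0=100):
    """Small profiles over a reduced alphabet for oracle comparisons."""
    models = []
    for M in range(1, max_M + 1):
        r = np.random.default_rng(seed0 + M)
        rows = ["".join(r.choice(list(alphabet), size=M)) for _ in range(4)]
        if M > 1:  # put one gap in so delete transitions get real counts
            rows[-1] = "-" + rows[-1][1:]
        msa = make_alignment(rows)
        models.append(build_profile(msa, alphabet=alphabet, name=f"m{M}"))
    return models


def single_gene_registry(model: ProfileHMM, gene: str, step: str):
    reg = GeneModelRegistry()
    reg.register(GeneModel(gene=gene, step=step, model=model))
    return reg


@pytest.fixture(scope="session")
def step_registry():
    """A lightweight 12-gene registry (one shared tiny model) for genotype
    logic tests that never score sequences."""
    msa = make_alignment(["ACDE", "ACDE", "ACDE"])
    model = build_profile(msa, name="tiny")
    model.tc_bits = 0.0
    entries = [
        ("narG", "NAR"), ("narH", "NAR"), ("napA", "NAR"),
        ("nirK", "NIR"), ("nirS", "NIR"),
        ("cnor", "NOR"), ("qnor", "NOR"), ("bnor", "NOR"), ("snor", "NOR"),
        ("nosZI", "NOS"), ("nosZII", "NOS"), ("nosB", "ACCESSORY"),
    ]
    reg = GeneModelRegistry()
    for gene, step in entries:
        reg.register(GeneModel(gene=gene, step=step, model=model))
    return reg
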