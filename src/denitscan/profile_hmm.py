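"""Profile hidden Markov models: build, score, sample, calibrate.

The profile follows the classic match/insert/delete architecture with a
*glocal* alignment mode: the model is always traversed begin-to-end (global
in the model) while any amount of flanking sequence is consumed by free
null-emitting flank states (local in the sequence).  Because flank states
emit at the background distribution, their contribution cancels against the
null model exactly, so the reported bit score is

    bit = log2 [ P(seq, best/all paths | model) / P(seq | background) ]

with no length correction and no E-value machinery: the only decision rule
is the per-model trusted cutoff (TC) in bits, mirroring how curated HMM
collections gate family membership.

State lattice (M = number of match states; node 0 is *begin*):

    begin -> {M1, I0, D1}
    Mk    -> {Mk+1, Ik, Dk+1}      (MM -> {end, IM})
    Ik    -> {Ik, Mk+1}            (IM -> {IM, end})
    Dk    -> {Dk+1, Mk+1}          (DM -> end)

Transitions out of node ``k`` are stored at index ``k`` of seven arrays
(``t_mm`` at ``k = 0`` is begin->M1, at ``k = M`` it is MM->end, and so on);
``t_md[M]`` and ``t_dd[M]`` are structurally zero.  D->I and I->D moves do
not exist in this lattice.

Viterbi traceback ties break deterministically as M > D > I.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import BuildError, CalibrationError, SearchError
from .seqio import AMINO_ACIDS, GAP_CHARS, Alignment, SequenceRecord

NEG_INF = float("-inf")
#: finite stand-in for log2(0) inside the DP tables (see _score_tables)
IMPOSSIBLE = -1.0e30


# ---------------------------------------------------------------------------
# model container


@dataclass
class ProfileHMM:
    """A built profile with optional trusted cutoff.

    All emission and transition rows are probability distributions (sum to 1
    within 1e-9); after pseudocounting every *legal* move and letter has
    strictly positive probability.
    """

    name: str
    alphabet: str
    match_emissions: np.ndarray  # (M+1, K); row 0 unused
    insert_emissions: np.ndarray  # (K,) shared across insert states
    background: np.ndarray  # (K,)
    t_mm: np.ndarray  # each (M+1,)
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    tc_bits: float | None = None

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0] - 1

    @property
    def K(self) -> int:
        return len(self.alphabet)

    def __post_init__(self):
        self._index = {a: i for i, a in enumerate(self.alphabet)}
        self._tables = None
        self.validate()

    def validate(self) -> None:
        M, K = self.M, self.K
        if M < 1:
            raise BuildError("profile needs at least one match state")
        atol = 1e-9
        if not np.allclose(self.match_emissions[1:].sum(axis=1), 1.0, atol=atol):
            raise BuildError("match emission rows must sum to 1")
        for vec in (self.insert_emissions, self.background):
            if not math.isclose(vec.sum(), 1.0, abs_tol=atol):
                raise BuildError("insert/background distributions must sum to 1")
        # transition rows: out of M, I and D states at each node
        m_out = self.t_mm + self.t_mi + self.t_md
        i_out = self.t_im + self.t_ii
        d_out = self.t_dm + self.t_dd
        if not np.allclose(m_out, 1.0, atol=atol):
            raise BuildError("match-state transition rows must sum to 1")
        if not np.allclose(i_out, 1.0, atol=atol):
            raise BuildError("insert-state transition rows must sum to 1")
        if not np.allclose(d_out[1:], 1.0, atol=atol):
            raise BuildError("delete-state transition rows must sum to 1")
        if self.t_md[M] != 0.0 or self.t_dd[M] != 0.0:
            raise BuildError("t_md[M] and t_dd[M] are structurally zero")

    # -- cached log-space score tables -------------------------------------

    def _score_tables(self):
        """log2 emission odds (incl. an X column) and log2 transitions."""
        if self._tables is None:
            with np.errstate(divide="ignore"):
                lo = np.log2(self.match_emissions[1:] / self.background)
                # X: background-weighted average emission over background norm
                x_num = self.match_emissions[1:] @ self.background
                x_den = float(self.background @ self.background)
                lo_x = np.log2(x_num / x_den)
                lo = np.concatenate([lo, lo_x[:, None]], axis=1)  # (M, K+1)
                lt = {
                    name: np.log2(getattr(self, name))
                    for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
                }
            # impossible moves get a huge finite penalty instead of -inf so
            # the prefix-scan arithmetic (which subtracts chain costs) never
            # produces NaN; 2**IMPOSSIBLE underflows to exactly 0
            for arr in (lo, *lt.values()):
                np.copyto(arr, IMPOSSIBLE, where=np.isneginf(arr))
            self._tables = (lo, lt)
        return self._tables

    def encode(self, residues: str) -> np.ndarray:
        """Map residues to alphabet indices; X (or any unknown) -> index K."""
        K = self.K
        return np.array(
            [self._index.get(ch, K) for ch in residues], dtype=np.intp
        )


# ---------------------------------------------------------------------------
# building from an alignment


def build_profile(
    msa: Alignment,
    match_occupancy: float = 0.5,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    name: str = "profile",
    alphabet: str = AMINO_ACIDS,
) -> ProfileHMM:
    """Estimate a profile from an alignment.

    Columns whose non-gap fraction is >= ``match_occupancy`` become match
    states in order; every other column feeds insert states.  Emissions and
    transitions are observed counts plus ``pseudocount_weight`` spread over
    the background (emissions) or uniformly over the legal moves
    (transitions), then normalized.
    """
    if pseudocount_weight <= 0:
        raise BuildError("pseudocount_weight must be positive")
    K = len(alphabet)
    index = {a: i for i, a in enumerate(alphabet)}
    if background is None:
        background = np.full(K, 1.0 / K)
    background = np.asarray(background, dtype=float)

    rows = [r.residues for r in msa.records]
    ncols = msa.ncols
    gaps = set(GAP_CHARS)
    occ = [
        sum(1 for row in rows if row[j] not in gaps) / len(rows)
        for j in range(ncols)
    ]
    is_match = [occ[j] >= match_occupancy for j in range(ncols)]
    M = sum(is_match)
    if M == 0:
        raise BuildError("no column passes the match occupancy threshold")

    e_counts = np.zeros((M + 1, K))
    t_counts = {k: np.zeros(M + 1) for k in
                ("mm", "mi", "md", "im", "ii", "dm", "dd")}

    for row in rows:
        # implied state path through the M/I/D labeling of this row
        path: list[tuple[str, int]] = [("M", 0)]  # begin behaves as M0
        node = 0
        for j in range(ncols):
            ch = row[j]
            if is_match[j]:
                node += 1
                if ch in gaps:
                    path.append(("D", node))
                else:
                    path.append(("M", node))
                    if ch in index:  # X contributes no emission count
                        e_counts[node, index[ch]] += 1
            elif ch not in gaps:
                path.append(("I", node))
        path.append(("M", M + 1))  # end behaves as M_{M+1}
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            move = s1.lower() + s2.lower()
            if move in ("di", "id"):
                # illegal in this lattice; drop the pair, pseudocounts keep
                # the distributions proper
                continue
            key = {"mm": "mm", "mi": "mi", "md": "md",
                   "im": "im", "ii": "ii", "dm": "dm", "dd": "dd"}[move]
            t_counts[key][k1] += 1

    w = pseudocount_weight
    e = e_counts + w * background
    e[0] = 0.0
    match_emissions = np.zeros_like(e)
    match_emissions[1:] = e[1:] / e[1:].sum(axis=1, keepdims=True)

    t = {k: v.copy() for k, v in t_counts.items()}

    def _normalize(keys: Sequence[str], node: int) -> None:
        total = sum(t[k][node] for k in keys) + w
        for k in keys:
            t[k][node] = (t_counts[k][node] + w / len(keys)) / total

    for k in range(M + 1):
        _normalize(("mm", "mi", "md") if k < M else ("mm", "mi"), k)
        _normalize(("im", "ii"), k)
        if 1 <= k < M:
            _normalize(("dm", "dd"), k)
    t["dm"][M] = 1.0
    t["dd"][M] = 0.0
    t["md"][M] = 0.0
    t["dm"][0] = t["dd"][0] = 0.0  # no delete state at the begin node

    return ProfileHMM(
        name=name,
        alphabet=alphabet,
        match_emissions=match_emissions,
        insert_emissions=background.copy(),
        background=background,
        t_mm=t["mm"], t_mi=t["mi"], t_md=t["md"],
        t_im=t["im"], t_ii=t["ii"], t_dm=t["dm"], t_dd=t["dd"],
        tc_bits=None,
    )


# ---------------------------------------------------------------------------
# scoring


def _check_seq(residues: str) -> None:
    if not residues:
        raise SearchError("cannot score an empty sequence")


def score_sequence(
    model: ProfileHMM,
    residues: str,
    algorithm: str = "viterbi",
    local_flanks: bool = True,
) -> float:
    """Fast bit score (no traceback).

    ``algorithm`` is ``"viterbi"`` (max over paths) or ``"forward"``
    (log-sum-exp over paths).  With ``local_flanks`` (the default, the
    public glocal contract) the core may start and end anywhere in the
    sequence, flanking residues being consumed by free null flank states;
    without it the core traversal must account for the whole sequence.
    The delete-state chain within a column is resolved with a prefix scan
    so each position costs O(M) vector work.
    """
    if local_flanks:
        _check_seq(residues)
    if algorithm == "viterbi":
        reduce2, accumulate = np.maximum, np.maximum.accumulate
    elif algorithm == "forward":
        reduce2, accumulate = np.logaddexp2, np.logaddexp2.accumulate
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    lo, lt = model._score_tables()
    M = model.M
    xs = model.encode(residues)
    ltmm, ltmi, ltmd = lt["t_mm"], lt["t_mi"], lt["t_md"]
    ltim, ltii = lt["t_im"], lt["t_ii"]
    ltdm, ltdd = lt["t_dm"], lt["t_dd"]

    # chain-cost prefix for the delete column scan: S[m] = sum_{k<m} ln2 t_dd[k]
    if M > 1:
        S = np.concatenate(([0.0], np.cumsum(ltdd[1:M])))
    else:
        S = np.zeros(1)

    def d_chain(m_vals: np.ndarray, begin_open: bool) -> np.ndarray:
        """Delete values D_1..D_M at the current position given match values."""
        entry = np.empty(M)
        entry[0] = ltmd[0] if begin_open else NEG_INF  # begin (score 0) -> D1
        if M > 1:
            entry[1:] = m_vals[1:M] + ltmd[1:M]
        return accumulate(entry - S) + S

    m_prev = np.full(M + 1, NEG_INF)  # index j = 1..M
    i_prev = np.full(M + 1, NEG_INF)  # index j = 0..M
    d_prev = np.full(M + 1, NEG_INF)
    d_prev[1:] = d_chain(m_prev, begin_open=True)

    def end_score(mv, iv, dv):
        return reduce2(
            reduce2(mv[M] + ltmm[M], dv[M] + ltdm[M]), iv[M] + ltim[M]
        )

    best = end_score(m_prev, i_prev, d_prev) if local_flanks else None
    for pos, x in enumerate(xs, start=1):
        begin_open = local_flanks or pos == 1
        m_new = np.full(M + 1, NEG_INF)
        src_m = np.empty(M)
        src_m[0] = ltmm[0] if begin_open else NEG_INF  # begin (0) -> M1
        if M > 1:
            src_m[1:] = m_prev[1:M] + ltmm[1:M]
        src_i = i_prev[:M] + ltim[:M]
        src_d = np.full(M, NEG_INF)
        if M > 1:
            src_d[1:] = d_prev[1:M] + ltdm[1:M]
        m_new[1:] = lo[:, x] + reduce2(reduce2(src_m, src_d), src_i)

        i_new = np.empty(M + 1)
        src_a = np.full(M + 1, NEG_INF)
        if begin_open:
            src_a[0] = ltmi[0]  # begin (0) -> I0
        src_a[1:] = m_prev[1:] + ltmi[1:]
        i_new[:] = reduce2(src_a, i_prev + ltii)

        d_new = np.full(M + 1, NEG_INF)
        d_new[1:] = d_chain(m_new, begin_open=local_flanks)

        if local_flanks:
            best = reduce2(best, end_score(m_new, i_new, d_new))
        m_prev, i_prev, d_prev = m_new, i_new, d_new
    if not local_flanks:
        best = end_score(m_prev, i_prev, d_prev)
    return float(best)


def forward(model: ProfileHMM, residues: str) -> float:
    """Glocal forward bit score: log-sum-exp over all paths and flank splits."""
    return score_sequence(model, residues, algorithm="forward")


def sequence_probability(model: ProfileHMM, residues: str) -> float:
    """P(residues | model) for a full begin-to-end core traversal.

    No flank states and no null normalization: this is the plain emission
    probability of the sequence under the profile, which sums to 1 over all
    sequences (the empty string, emitted by the all-delete path, included).
    Only meaningful for sequences without X.
    """
    bits = score_sequence(
        model, residues, algorithm="forward", local_flanks=False
    )
    null = float(np.prod(model.background[model.encode(residues)])) \
        if residues else 1.0
    return (2.0 ** bits) * null


def viterbi(model: ProfileHMM, residues: str):
    """Optimal glocal alignment with traceback.

    Returns ``(bit_score, state_path, aligned_span)`` where ``state_path``
    is a list of ``(kind, node, seq_pos)`` tuples for the core states in
    order (``seq_pos`` is the 1-based residue consumed, or ``None`` for
    deletes) and ``aligned_span`` is the 1-based first/last residue consumed
    by match or insert states (``None`` if the optimal path consumes no
    residue).  Ties break M > D > I at every cell.
    """
    _check_seq(residues)
    lo, lt = model._score_tables()
    M = model.M
    xs = model.encode(residues)
    n = len(xs)
    ltmm, ltmi, ltmd = lt["t_mm"], lt["t_mi"], lt["t_md"]
    ltim, ltii = lt["t_im"], lt["t_ii"]
    ltdm, ltdd = lt["t_dm"], lt["t_dd"]

    # V[s][i][j]: best score having consumed i residues, last state s_j.
    VM = np.full((n + 1, M + 1), NEG_INF)
    VI = np.full((n + 1, M + 1), NEG_INF)
    VD = np.full((n + 1, M + 1), NEG_INF)
    # pointers: which previous state kind fed this cell ('B','M','I','D')
    PM = np.zeros((n + 1, M + 1), dtype="U1")
    PI = np.zeros((n + 1, M + 1), dtype="U1")
    PD = np.zeros((n + 1, M + 1), dtype="U1")

    prio = {"M": 0, "D": 1, "I": 2, "B": 3}

    def _pick_tie(cands):
        cands = sorted(cands, key=lambda c: (-c[0], prio[c[1]]))
        return cands[0]

    for i in range(n + 1):
        for j in range(1, M + 1):
            if i >= 1:
                cands = []
                if j == 1:
                    cands.append((ltmm[0], "B"))  # begin at i-1, score 0
                else:
                    cands.append((VM[i - 1, j - 1] + ltmm[j - 1], "M"))
                    cands.append((VD[i - 1, j - 1] + ltdm[j - 1], "D"))
                cands.append((VI[i - 1, j - 1] + ltim[j - 1], "I"))
                s, k = _pick_tie(cands)
                VM[i, j] = lo[j - 1, xs[i - 1]] + s
                PM[i, j] = k
            # delete chain at same i
            cands = []
            if j == 1:
                cands.append((ltmd[0], "B"))
            else:
                cands.append((VM[i, j - 1] + ltmd[j - 1], "M"))
                cands.append((VD[i, j - 1] + ltdd[j - 1], "D"))
            s, k = _pick_tie(cands)
            VD[i, j] = s
            PD[i, j] = k
        if i >= 1:
            for j in range(M + 1):
                cands = [(VI[i - 1, j] + ltii[j], "I")]
                if j == 0:
                    cands.append((ltmi[0], "B"))
                else:
                    cands.append((VM[i - 1, j] + ltmi[j], "M"))
                s, k = _pick_tie(cands)
                VI[i, j] = s  # insert emission log-odds is 0
                PI[i, j] = k

    best = (NEG_INF, "B", 0)
    for i in range(n + 1):
        s, k = _pick_tie(
            [
                (VM[i, M] + ltmm[M], "M"),
                (VD[i, M] + ltdm[M], "D"),
                (VI[i, M] + ltim[M], "I"),
            ]
        )
        if s > best[0]:
            best = (s, k, i)
    bit, kind, i = best

    # traceback
    path: list[tuple[str, int | None, int | None]] = []
    j = M
    while kind != "B":
        if kind == "M":
            path.append(("M", j, i))
            kind = PM[i, j]
            i, j = i - 1, j - 1
        elif kind == "D":
            path.append(("D", j, None))
            kind = PD[i, j]
            j = j - 1
        else:  # insert at node j (entered from M_j or I_j); node index is j
            # I states sit between nodes: coming *into* M_{j+1}/end from I_j
            path.append(("I", j, i))
            kind = PI[i, j]
            i = i - 1
    path.reverse()
    consumed = [p[2] for p in path if p[0] in ("M", "I") and p[2] is not None]
    span = (min(consumed), max(consumed)) if consumed else None
    return float(bit), path, span


# ---------------------------------------------------------------------------
# sampling, calibration, active sites


def sample_sequence(model: ProfileHMM, rng) -> SequenceRecord:
    """Draw one sequence by stochastic begin-to-end traversal of the core.

    ``rng`` is an integer seed or a :class:`numpy.random.Generator`.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    M, K = model.M, model.K
    letters = np.frombuffer(model.alphabet.encode(), dtype="S1").astype("U1")
    out: list[str] = []
    kind, node = "M", 0  # begin
    while True:
        if kind == "M":
            if node > 0:
                out.append(str(rng.choice(letters, p=model.match_emissions[node])))
            if node == M:
                probs = [model.t_mm[M], model.t_mi[M]]
                nxt = rng.choice(["E", "I"], p=probs)
            else:
                nxt = rng.choice(
                    ["M", "I", "D"],
                    p=[model.t_mm[node], model.t_mi[node], model.t_md[node]],
                )
        elif kind == "I":
            out.append(str(rng.choice(letters, p=model.insert_emissions)))
            nxt = rng.choice(
                ["M" if node < M else "E", "I"],
                p=[model.t_im[node], model.t_ii[node]],
            )
        else:  # D
            if node == M:
                nxt = "E"
            else:
                nxt = rng.choice(["M", "D"], p=[model.t_dm[node], model.t_dd[node]])
        if nxt == "E":
            break
        if nxt == "I":
            kind = "I"  # stays at current node
        else:
            kind, node = nxt, node + 1
    return SequenceRecord(f"{model.name}_sample", "".join(out))


def shuffle_residues(record: SequenceRecord, rng) -> SequenceRecord:
    """Residue-shuffled decoy preserving composition and length."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    chars = list(record.residues)
    rng.shuffle(chars)
    return SequenceRecord(f"{record.id}_shuffled", "".join(chars))


def calibrate_tc_from_scores(
    positive_scores: Mapping[str, float], negative_scores: Mapping[str, float]
) -> float:
    """Midpoint trusted cutoff between separable positive/negative scores.

    Raises :class:`CalibrationError` listing every overlapping sequence when
    the sets are not separable — the signal, as in manual curation loops,
    that the seed alignment needs re-inspection.
    """
    if not positive_scores or not negative_scores:
        raise CalibrationError("both positive and negative sets must be non-empty")
    min_pos = min(positive_scores.values())
    max_neg = max(negative_scores.values())
    if min_pos <= max_neg:
        overlaps = [
            ("positive", sid, s)
            for sid, s in positive_scores.items()
            if s <= max_neg
        ] + [
            ("negative", sid, s)
            for sid, s in negative_scores.items()
            if s >= min_pos
        ]
        raise CalibrationError(
            "positive and negative scores overlap; offending sequences: "
            + "; ".join(f"{role} {sid}={s:.2f}" for role, sid, s in overlaps),
            overlaps=overlaps,
        )
    return (min_pos + max_neg) / 2.0


def calibrate_tc(
    model: ProfileHMM,
    positives: Sequence[SequenceRecord],
    negatives: Sequence[SequenceRecord],
) -> float:
    """Score both sets, set the midpoint TC on the model and return it."""
    pos = {r.id if r.id else str(i): score_sequence(model, r.residues)
           for i, r in enumerate(positives)}
    neg = {r.id if r.id else str(i): score_sequence(model, r.residues)
           for i, r in enumerate(negatives)}
    tc = calibrate_tc_from_scores(pos, neg)
    model.tc_bits = tc
    return tc


@dataclass(frozen=True)
class ActiveSiteReport:
    ok: bool
    violations: tuple[str, ...]


def verify_active_site(
    model: ProfileHMM, residues: str, residue_spec: Mapping[int, Iterable[str]]
) -> ActiveSiteReport:
    """Check conserved residues on the optimal alignment.

    ``residue_spec`` maps 1-based match-state indices to the set of allowed
    letters.  The check passes iff every specified match state is occupied
    (not deleted) on the Viterbi path and emits an allowed letter.
    """
    for idx in residue_spec:
        if not 1 <= idx <= model.M:
            raise ValueError(f"match-state index {idx} outside 1..{model.M}")
    _, path, _ = viterbi(model, residues)
    emitted = {node: pos for kind, node, pos in path if kind == "M"}
    deleted = {node for kind, node, _ in path if kind == "D"}
    violations = []
    for idx, allowed in sorted(residue_spec.items()):
        allowed = set(allowed)
        if idx in deleted or idx not in emitted:
            violations.append(f"match {idx}: deleted")
            continue
        letter = residues[emitted[idx] - 1]
        if letter not in allowed:
            violations.append(
                f"match {idx}: saw {letter!r}, allowed {sorted(allowed)}"
            )
    return ActiveSiteReport(ok=not violations, violations=tuple(violations))


# ---------------------------------------------------------------------------
# proteome search


@dataclass(frozen=True)
class HmmHit:
    """One protein-vs-model score with TC pass/fail."""

    protein_id: str
    model_name: str
    bit_score: float
    passes_tc: bool
    aligned_span: tuple[int, int] | None
    primary: bool = False


def search_proteome(
    registry, proteins: Sequence[SequenceRecord], keep_subthreshold: bool = False
) -> list[HmmHit]:
    """Score every protein against every registry model.

    Hits below TC are dropped unless ``keep_subthreshold``; each protein's
    *primary* model is its highest-bit passing hit (ties resolved by
    registry order).  Requires every model to be calibrated.
    """
    entries = list(registry)
    for entry in entries:
        if entry.model.tc_bits is None:
            raise SearchError(f"model {entry.gene!r} has no trusted cutoff")
    hits: list[HmmHit] = []
    for prot in proteins:
        scored = []
        for order, entry in enumerate(entries):
            bit = score_sequence(entry.model, prot.residues)
            passes = bit >= entry.model.tc_bits
            if passes or keep_subthreshold:
                scored.append((order, entry, bit, passes))
        passing = [s for s in scored if s[3]]
        primary_order = None
        if passing:
            primary_order = min(passing, key=lambda s: (-s[2], s[0]))[0]
        for order, entry, bit, passes in scored:
            span = None
            if passes:
                _, _, span = viterbi(entry.model, prot.residues)
            hits.append(
                HmmHit(
                    protein_id=prot.id,
                    model_name=entry.gene,
                    bit_score=bit,
                    passes_tc=passes,
                    aligned_span=span,
                    primary=(order == primary_order),
                )
            )
    return hits


HIT_COLUMNS = (
    "protein_id", "model", "bit_score", "passes_tc",
    "primary", "span_start", "span_end",
)


def hits_to_rows(hits: Iterable[HmmHit]) -> list[dict]:
    rows = []
    for h in hits:
        rows.append(
            {
                "protein_id": h.protein_id,
                "model": h.model_name,
                "bit_score": f"{h.bit_score:.4f}",
                "passes_tc": int(h.passes_tc),
                "primary": int(h.primary),
                "span_start": h.aligned_span[0] if h.aligned_span else "",
                "span_end": h.aligned_span[1] if h.aligned_span else "",
            }
        )
    return rows


def write_hits_tsv(hits: Iterable[HmmHit], path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# " + "\t".join(HIT_COLUMNS) + "\n")
        for row in hits_to_rows(hits):
            fh.write(
                "\t".join(
                    str(row[c]) for c in
                    ("protein_id", "model", "bit_score", "passes_tc",
                     "primary", "span_start", "span_end")
                ) + "\n"
            )


def read_hits_tsv(path) -> list[HmmHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "protein_id":
                continue
            pid, model, bit, passes, primary, s0, s1 = parts
            span = (int(s0), int(s1)) if s0 and s1 else None
            hits.append(
                HmmHit(pid, model, float(bit), bool(int(passes)), span,
                       bool(int(primary)))
            )
    return hits


# ---------------------------------------------------------------------------
# text serialization


def write_model(model: ProfileHMM, path) -> None:
    """Write the documented text format (natural-log probability rows)."""

    def fmt(values) -> str:
        return " ".join(f"{v:.17g}" for v in values)

    def ln(p: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(p)

    with open(path, "w") as fh:
        fh.write("DENITSCAN-HMM 1\n")
        fh.write(f"NAME {model.name}\n")
        fh.write(f"ALPHABET {model.alphabet}\n")
        fh.write(f"LENG {model.M}\n")
        tc = "NONE" if model.tc_bits is None else f"{model.tc_bits:.17g}"
        fh.write(f"TC {tc}\n")
        fh.write(f"BACKGROUND {fmt(ln(model.background))}\n")
        fh.write(f"INSERT {fmt(ln(model.insert_emissions))}\n")
        for k in range(model.M + 1):
            trans = [model.t_mm[k], model.t_mi[k], model.t_md[k],
                     model.t_im[k], model.t_ii[k], model.t_dm[k], model.t_dd[k]]
            fh.write(f"NODE {k}\n")
            fh.write(f"TRANS {fmt(ln(np.array(trans)))}\n")
            if k >= 1:
                fh.write(f"MATCH {fmt(ln(model.match_emissions[k]))}\n")
        fh.write("END\n")


def read_model(path) -> ProfileHMM:
    """Read the text format written by :func:`write_model`."""
    header: dict[str, str] = {}
    nodes: dict[int, dict[str, np.ndarray]] = {}
    current = None
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("DENITSCAN-HMM"):
            raise BuildError(f"{path}: not a denitscan model file")
        for line in fh:
            line = line.strip()
            if not line or line == "END":
                continue
            tag, _, rest = line.partition(" ")
            if tag == "NODE":
                current = int(rest)
                nodes[current] = {}
            elif tag in ("TRANS", "MATCH"):
                nodes[current][tag] = np.exp(
                    np.array([float(v) for v in rest.split()])
                )
            else:
                header[tag] = rest
    M = int(header["LENG"])
    alphabet = header["ALPHABET"]
    K = len(alphabet)
    match_emissions = np.zeros((M + 1, K))
    arrays = {k: np.zeros(M + 1) for k in
              ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")}
    order = ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
    for k in range(M + 1):
        trans = nodes[k]["TRANS"]
        for name, v in zip(order, trans):
            arrays[name][k] = v
        if k >= 1:
            match_emissions[k] = nodes[k]["MATCH"]
    tc = None if header["TC"] == "NONE" else float(header["TC"])
    return ProfileHMM(
        name=header["NAME"],
        alphabet=alphabet,
        match_emissions=match_emissions,
        insert_emissions=np.exp(
            np.array([float(v) for v in header["INSERT"].split()])
        ),
        background=np.exp(
            np.array([float(v) for v in header["BACKGROUND"].split()])
        ),
        tc_bits=tc,
        **arrays,
    )
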