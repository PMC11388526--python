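"""Sequence-feature heuristics: transmembrane helices, signal peptides,
heme-binding motifs.

These are explicit, parameterized approximations of the neural predictors
commonly used for the same calls (DeepTMHMM-style helix counting, SignalP-
style Sec/Tat discrimination).  Downstream logic consumes only categorical
outcomes — a helix *count* of 4 or 6 for NosB candidates, the *presence* of
a Sec versus Tat peptide on NosZ, and >= 1 C-x-x-C-H motif as the
cytochrome-c proxy for NosC — so simple windowed-hydropathy and motif rules
are sufficient and fully testable.  All three operations are pure and
deterministic, and signal decisions depend only on the N-terminal 45
residues.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

# Kyte-Doolittle hydropathy; X is treated as neutral.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

#: decisions below never look past this many N-terminal residues
SIGNAL_NTERM = 45


@dataclass(frozen=True)
class TmPrediction:
    """Predicted transmembrane helices as sorted, non-overlapping spans."""

    helix_spans: tuple[tuple[int, int], ...]

    @property
    def count(self) -> int:
        return len(self.helix_spans)


@dataclass(frozen=True)
class SignalFlags:
    n_charge: bool = False
    h_region: bool = False
    c_motif: bool = False
    twin_arginine: bool = False


@dataclass(frozen=True)
class SignalCall:
    """Sec/SPI vs Tat vs no signal peptide, with component evidence."""

    kind: str  # none | sec_spi | tat
    cleavage_pos: int | None = None
    evidence: SignalFlags = field(default_factory=SignalFlags)


def _hydropathy(seq: str) -> list[float]:
    return [KYTE_DOOLITTLE.get(ch, 0.0) for ch in seq]


def count_tm_helices(
    seq: str, window: int = 19, threshold: float = 1.6, min_gap: int = 5
) -> TmPrediction:
    """Count transmembrane helices by sliding Kyte-Doolittle hydropathy.

    Every window of ``window`` residues whose mean hydropathy exceeds
    ``threshold`` flags its start position as helix core; maximal runs of
    flagged positions are merged, runs closer than ``min_gap`` are merged,
    and each surviving run counts as one helix.  Spans are reported 1-based
    over the flagged core runs.  Sequences shorter than the window yield a
    count of 0 with a warning.
    """
    n = len(seq)
    if n < window:
        warnings.warn(
            f"sequence of length {n} shorter than TM window {window}; "
            "returning zero helices",
            stacklevel=2,
        )
        return TmPrediction(())
    kd = _hydropathy(seq)
    prefix = [0.0]
    for v in kd:
        prefix.append(prefix[-1] + v)
    flagged = [
        i for i in range(n - window + 1)
        if (prefix[i + window] - prefix[i]) / window > threshold
    ]
    if not flagged:
        return TmPrediction(())
    runs: list[list[int]] = [[flagged[0], flagged[0]]]
    for i in flagged[1:]:
        if i - runs[-1][1] == 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    merged = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] - 1 < min_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    spans = tuple((s + 1, e + 1) for s, e in merged)
    return TmPrediction(spans)


def _best_h_window(kd: list[float], lo: int, hi: int, width: int = 7) -> bool:
    """True if some ``width`` window entirely within [lo, hi) (0-based,
    half-open) has mean hydropathy > 1.5."""
    hi = min(hi, len(kd))
    for q in range(lo, hi - width + 1):
        if sum(kd[q:q + width]) / width > 1.5:
            return True
    return False


_C_MOTIF = re.compile(r"[AGS].[AGS]")


def _c_motif_pos(s: str) -> int | None:
    """1-based position of the third residue of the first [AGS]-X-[AGS]
    motif whose third residue falls in positions 15-40."""
    for m in _C_MOTIF.finditer(s):
        third = m.start() + 3  # 1-based position of motif's third residue
        if 15 <= third <= 40:
            return third
    return None


def detect_signal(seq: str) -> SignalCall:
    """Classify the N-terminus as Tat, Sec/SPI, or no signal peptide.

    Tat (checked first): a consecutive ``RR`` within residues 1-35 followed
    by a hydrophobic h-region (a 7-residue window of mean Kyte-Doolittle
    > 1.5 shortly after the twin-arginine).  Sec/SPI: >= 1 K/R within
    residues 1-7, an h-region within residues 5-25, and an [AGS]-X-[AGS]
    cleavage motif whose third residue lies in positions 15-40 (cleavage
    after that residue).  Sequences shorter than 30 residues are ``none``.
    Only the first 45 residues are ever examined.
    """
    if len(seq) < 30:
        return SignalCall("none")
    s = seq[:SIGNAL_NTERM]
    kd = _hydropathy(s)

    # --- Tat: twin-arginine then h-region
    for m in re.finditer("RR", s[:35]):
        p0 = m.start()
        if _best_h_window(kd, p0 + 2, p0 + 2 + 15 + 7):
            pos = _c_motif_pos(s)
            return SignalCall(
                "tat",
                cleavage_pos=pos,
                evidence=SignalFlags(
                    n_charge=any(ch in "KR" for ch in s[:7]),
                    h_region=True,
                    c_motif=pos is not None,
                    twin_arginine=True,
                ),
            )

    # --- Sec/SPI: charged n-region, h-region in 5-25, cleavage motif
    n_charge = any(ch in "KR" for ch in s[:7])
    h_region = _best_h_window(kd, 4, 25)  # residues 5-25, 0-based [4, 25)
    pos = _c_motif_pos(s)
    flags = SignalFlags(n_charge=n_charge, h_region=h_region,
                        c_motif=pos is not None, twin_arginine=False)
    if n_charge and h_region and pos is not None:
        return SignalCall("sec_spi", cleavage_pos=pos, evidence=flags)
    return SignalCall("none", evidence=flags)


def count_cxxch(seq: str) -> int:
    """Number of non-overlapping C-x-x-C-H heme-binding motifs."""
    return len(re.findall(r"C..CH", seq))


@dataclass(frozen=True)
class ProteinFeatures:
    """Bundle of the three feature calls for one protein."""

    tm: TmPrediction
    signal: SignalCall
    cxxch: int


def compute_features(
    residues: str, tm_window: int = 19, tm_threshold: float = 1.6
) -> ProteinFeatures:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tm = count_tm_helices(residues, window=tm_window, threshold=tm_threshold)
    return ProteinFeatures(
        tm=tm, signal=detect_signal(residues), cxxch=count_cxxch(residues)
    )
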