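"""Rule-based miRNA target prediction on ungapped antiparallel duplexes.

A miRNA is slid along every window of a transcript; within a window, miRNA
position i (1-based, counted from the miRNA 5' end) pairs with window
position L+1-i.  Pair states are Watson-Crick (A:U, U:A, G:C, C:G), G-U
wobble (G:U, U:G), or mismatch, and the mismatch score counts a wobble as
half a mismatch.  A window is reported as a target site when all six rules
hold.  Two rule variants exist:

ruleset A
  (1) total mismatch score <= 4;
  (2) no more than two adjacent mismatches (no run of three);
  (3) no adjacent mismatch pair entirely within positions 2-12;
  (4) no mismatch at positions 10-11;
  (5) mismatch score over positions 1-12 <= 2.5;
  (6) duplex energy >= 74% of the perfect-complement energy.

ruleset B
  as A, except (2) no two consecutive mismatches anywhere, (3) no mismatch
  at positions 2-12 at all, and (6) a 60% energy threshold.

Whether a wobble counts as a mismatch *event* for the positional rules
(2)-(4) is the ``gu_is_positional_mismatch`` switch (default True); it always
contributes 0.5 to the scored rules (1) and (5).

The energy model is a simple additive per-pair model (GC -3, AU -2, GU -1,
mismatch 0, arbitrary units) applied identically to the duplex and to the
miRNA bound to its perfect complement, so the ratio in rule (6) is
model-consistent; the constants are configurable and a richer model can be
plugged in behind the same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import SeqRecord, logger

_BASES = "ACGU"
_LUT = np.full(256, 4, dtype=np.int8)  # 4 = N / unknown
for _i, _b in enumerate(_BASES):
    _LUT[ord(_b)] = _i

WC, GU, MM = 0, 1, 2

# pair state indexed by (mirna base, target base), codes A C G U N
PAIR_STATE = np.full((5, 5), MM, dtype=np.int8)
for _a, _b in ((0, 3), (3, 0), (2, 1), (1, 2)):  # A:U U:A G:C C:G
    PAIR_STATE[_a, _b] = WC
for _a, _b in ((2, 3), (3, 2)):  # G:U U:G
    PAIR_STATE[_a, _b] = GU

_STATE_SCORE = np.array([0.0, 0.5, 1.0])
_STATE_NAME = ("WC", "GU", "MM")


def encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(rna: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}
    return "".join(comp[b] for b in reversed(rna))


@dataclass(frozen=True)
class EnergyModel:
    """Additive per-pair duplex energies (all <= 0; mismatch contributes 0)."""

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    mm: float = 0.0

    def __post_init__(self) -> None:
        if any(e > 0 for e in (self.gc, self.au, self.gu)) or self.mm != 0.0:
            raise ValueError("pair energies must be <= 0 with mismatch = 0")

    def pair_table(self) -> np.ndarray:
        table = np.full((5, 5), self.mm)
        for a, b, e in (
            (2, 1, self.gc), (1, 2, self.gc),
            (0, 3, self.au), (3, 0, self.au),
            (2, 3, self.gu), (3, 2, self.gu),
        ):
            table[a, b] = e
        return table

    def perfect_per_base(self) -> np.ndarray:
        # energy of each miRNA base paired with its Watson-Crick complement
        return np.array([self.au, self.gc, self.gc, self.au, 0.0])


DEFAULT_MODEL = EnergyModel()
MFE_THRESHOLDS = {"A": 0.74, "B": 0.60}


@dataclass(frozen=True)
class DuplexAlignment:
    """One miRNA-vs-window pairing with per-position states and energies."""

    mirna_id: str
    transcript_id: str
    window_start: int
    states: tuple[str, ...]  # indexed by miRNA position 1..L from the 5' end
    mismatch_score: float
    duplex_energy: float
    perfect_energy: float

    @property
    def mfe_ratio(self) -> float:
        if self.perfect_energy == 0:
            return 0.0
        return abs(self.duplex_energy) / abs(self.perfect_energy)


@dataclass(frozen=True)
class RuleVerdict:
    r1: bool
    r2: bool
    r3: bool
    r4: bool
    r5: bool
    r6: bool

    @property
    def passed(self) -> bool:
        return self.r1 and self.r2 and self.r3 and self.r4 and self.r5 and self.r6

    def violated(self) -> tuple[str, ...]:
        return tuple(
            name for name in ("r1", "r2", "r3", "r4", "r5", "r6")
            if not getattr(self, name)
        )


@dataclass(frozen=True)
class TargetHit:
    alignment: DuplexAlignment
    verdict: RuleVerdict

    @property
    def mfe_ratio(self) -> float:
        return self.alignment.mfe_ratio


def _validate_rna(seq: str, what: str) -> None:
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"{what} is not RNA (found {sorted(bad)}); convert T to U")


def duplex_align(
    mirna: str,
    window: str,
    model: EnergyModel = DEFAULT_MODEL,
    mirna_id: str = "mirna",
    transcript_id: str = "window",
    window_start: int = 0,
) -> DuplexAlignment:
    """Align a miRNA against an equal-length transcript window (no gaps)."""
    _validate_rna(mirna, "miRNA")
    _validate_rna(window, "window")
    if len(mirna) != len(window):
        raise ValueError(
            f"length mismatch: miRNA {len(mirna)} vs window {len(window)}"
        )
    mi = encode(mirna)
    win = encode(window)
    paired = win[::-1]  # miRNA index i0 pairs window index L-1-i0
    states = PAIR_STATE[mi, paired]
    score = float(_STATE_SCORE[states].sum())
    energy = float(model.pair_table()[mi, paired].sum())
    perfect = float(model.perfect_per_base()[mi].sum())
    return DuplexAlignment(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        window_start=window_start,
        states=tuple(_STATE_NAME[s] for s in states),
        mismatch_score=score,
        duplex_energy=energy,
        perfect_energy=perfect,
    )


def perfect_energy(mirna: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Energy of the miRNA bound to its exact Watson-Crick complement."""
    _validate_rna(mirna, "miRNA")
    return float(model.perfect_per_base()[encode(mirna)].sum())


def duplex_energy(aln: DuplexAlignment) -> float:
    return aln.duplex_energy


def evaluate_rules(
    aln: DuplexAlignment,
    ruleset: str = "A",
    mfe_threshold: float | None = None,
    gu_is_positional_mismatch: bool = True,
) -> RuleVerdict:
    """Apply the six target rules (variant A or B) to an alignment."""
    if ruleset not in ("A", "B"):
        raise ValueError(f"unknown ruleset {ruleset!r}")
    threshold = MFE_THRESHOLDS[ruleset] if mfe_threshold is None else mfe_threshold
    L = len(aln.states)
    codes = np.array([_STATE_NAME.index(s) for s in aln.states])
    score = _STATE_SCORE[codes]
    event = codes != WC if gu_is_positional_mismatch else codes == MM

    r1 = float(score.sum()) <= 4.0 + 1e-12

    max_run = run = 0
    for e in event:
        run = run + 1 if e else 0
        max_run = max(max_run, run)
    r2 = max_run <= (2 if ruleset == "A" else 1)

    # positions 2..12 are 0-based indices 1..11
    hi = min(12, L)
    if ruleset == "A":
        window = event[1:hi]
        r3 = not np.any(window[:-1] & window[1:]) if window.size > 1 else True
    else:
        r3 = not np.any(event[1:hi])

    r4 = all(codes[i] == WC for i in (9, 10) if i < L)
    r5 = float(score[: min(12, L)].sum()) <= 2.5 + 1e-12
    r6 = aln.mfe_ratio >= threshold - 1e-12
    return RuleVerdict(bool(r1), r2, bool(r3), bool(r4), bool(r5), bool(r6))


# ---------------------------------------------------------------------------
# Window scanning
# ---------------------------------------------------------------------------


def _window_state_matrix(mi: np.ndarray, tr: np.ndarray) -> np.ndarray:
    """Pair states for every window: shape (n_windows, L)."""
    L = mi.size
    wins = np.lib.stride_tricks.sliding_window_view(tr, L)
    return PAIR_STATE[mi[None, :], np.flip(wins, axis=1)]


def scan_transcript(
    mirna: SeqRecord,
    transcript: SeqRecord,
    ruleset: str = "A",
    model: EnergyModel = DEFAULT_MODEL,
    mfe_threshold: float | None = None,
    gu_is_positional_mismatch: bool = True,
) -> list[TargetHit]:
    """Evaluate every window of the transcript; return rule-passing hits.

    Hits are sorted by window start; overlapping hits are all reported.  The
    scan first screens windows on the mismatch-score bound of rule (1) (a
    cheap vectorized pass), then applies the full rule set to survivors.
    """
    mi_seq = mirna.sequence.replace("T", "U")
    tr_seq = transcript.sequence.replace("T", "U")
    L = len(mi_seq)
    if len(tr_seq) < L:
        warnings.warn(
            f"transcript {transcript.id} shorter than miRNA {mirna.id}; no scan"
        )
        return []
    mi = encode(mi_seq)
    tr = encode(tr_seq)
    states = _window_state_matrix(mi, tr)
    scores = _STATE_SCORE[states].sum(axis=1)
    hits: list[TargetHit] = []
    for pos in np.nonzero(scores <= 4.0 + 1e-12)[0]:
        aln = duplex_align(
            mi_seq, tr_seq[pos : pos + L], model=model,
            mirna_id=mirna.id, transcript_id=transcript.id, window_start=int(pos),
        )
        verdict = evaluate_rules(
            aln, ruleset=ruleset, mfe_threshold=mfe_threshold,
            gu_is_positional_mismatch=gu_is_positional_mismatch,
        )
        if verdict.passed:
            hits.append(TargetHit(alignment=aln, verdict=verdict))
    return hits


def best_window_verdict(
    mirna: SeqRecord,
    transcript: SeqRecord,
    ruleset: str = "A",
    model: EnergyModel = DEFAULT_MODEL,
    gu_is_positional_mismatch: bool = True,
) -> tuple[DuplexAlignment, RuleVerdict]:
    """Diagnostics for the lowest-mismatch-score window of a transcript.

    Useful for asking *why* a near-site failed: the verdict names the
    violated rules even when no window passes.
    """
    mi_seq = mirna.sequence.replace("T", "U")
    tr_seq = transcript.sequence.replace("T", "U")
    L = len(mi_seq)
    if len(tr_seq) < L:
        raise ValueError("transcript shorter than miRNA")
    states = _window_state_matrix(encode(mi_seq), encode(tr_seq))
    pos = int(np.argmin(_STATE_SCORE[states].sum(axis=1)))
    aln = duplex_align(
        mi_seq, tr_seq[pos : pos + L], model=model,
        mirna_id=mirna.id, transcript_id=transcript.id, window_start=pos,
    )
    return aln, evaluate_rules(
        aln, ruleset=ruleset, gu_is_positional_mismatch=gu_is_positional_mismatch
    )


def scan_many(
    mirnas: Iterable[SeqRecord],
    transcripts: Iterable[SeqRecord],
    ruleset: str = "A",
    model: EnergyModel = DEFAULT_MODEL,
    mfe_threshold: float | None = None,
) -> pd.DataFrame:
    """Hit table over all miRNA x transcript pairs.

    Columns: mirna, transcript, position, mismatch_score, mfe_ratio and the
    six per-rule flags.
    """
    transcripts = list(transcripts)
    rows = []
    for mirna in mirnas:
        for tr in transcripts:
            if len(tr.sequence) < len(mirna.sequence):
                continue
            for hit in scan_transcript(
                mirna, tr, ruleset=ruleset, model=model, mfe_threshold=mfe_threshold
            ):
                a, v = hit.alignment, hit.verdict
                rows.append(
                    {
                        "mirna": a.mirna_id,
                        "transcript": a.transcript_id,
                        "position": a.window_start,
                        "mismatch_score": a.mismatch_score,
                        "mfe_ratio": a.mfe_ratio,
                        **{r: getattr(v, r) for r in ("r1", "r2", "r3", "r4", "r5", "r6")},
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "mirna", "transcript", "position", "mismatch_score", "mfe_ratio",
            "r1", "r2", "r3", "r4", "r5", "r6",
        ],
    )
    logger.info("scan_many: %d hits (ruleset %s)", len(table), ruleset)
    return table
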