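"""Dinucleotide DNA strength parameters.

The duplex stability score of a sequence is built from two ingredients
assigned per dinucleotide step (an ordered pair of adjacent bases read
5'->3' on one strand):

* a *stacking* value determined by the purine/pyrimidine class of the
  step — RY steps stack strongest (5), RR and YY intermediate (3), YR
  weakest (2);
* a Watson–Crick *hydrogen-bond* value per base — 4 for G/C (triple
  H-bond pair), 1 for A/T (double H-bond pair) — counted once for each
  of the two bases in the step.

Their sum gives an integer step score between 4 (TA) and 13 (GC).  The
cumulative strength of a sequence is the sum over its n-1 overlapping
steps; the per-base strength parameter E divides that sum by the number
of bases n (not steps).  Because each step score equals that of its
reverse complement, every strength quantity is strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PURINES",
    "PYRIMIDINES",
    "STACKING_VALUES",
    "HBOND_BASE_VALUES",
    "STEP_VALUES",
    "SequenceError",
    "StrengthResult",
    "normalize_sequence",
    "classify_stack_group",
    "step_strength",
    "cumulative_strength",
    "strength_per_base",
    "strength_result",
    "strength_table_records",
    "encode_sequence",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: Stacking value per purine/pyrimidine step class.
STACKING_VALUES: dict[str, int] = {"RY": 5, "RR": 3, "YY": 3, "YR": 2}

#: Hydrogen-bond value per base: triple-bonded G·C pairs score 4, double-bonded A·T pairs 1.
HBOND_BASE_VALUES: dict[str, int] = {"G": 4, "C": 4, "A": 1, "T": 1}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Raised for sequences outside the A/C/G/T alphabet or too short to score."""


def classify_stack_group(step: str) -> str:
    """Return the stacking class (RR, RY, YR or YY) of a dinucleotide step."""
    if len(step) != 2:
        raise SequenceError(f"a dinucleotide step has exactly 2 bases, got {step!r}")
    a, b = step[0].upper(), step[1].upper()
    for base in (a, b):
        if base not in PURINES and base not in PYRIMIDINES:
            raise SequenceError(f"invalid base {base!r} in step {step!r}")
    return ("R" if a in PURINES else "Y") + ("R" if b in PURINES else "Y")


def step_strength(step: str) -> int:
    """Strength score of one dinucleotide step: stacking class value plus both base H-bond values."""
    cls = classify_stack_group(step)
    a, b = step[0].upper(), step[1].upper()
    return STACKING_VALUES[cls] + HBOND_BASE_VALUES[a] + HBOND_BASE_VALUES[b]


#: All 16 step scores, generated from the stacking and H-bond maps.
STEP_VALUES: dict[str, int] = {
    a + b: step_strength(a + b) for a in "ACGT" for b in "ACGT"
}


def normalize_sequence(raw: str, min_length: int = 1) -> str:
    """Uppercase *raw* and validate it against the A/C/G/T alphabet.

    Parameters
    ----------
    raw : str
        Input sequence, any case.  Whitespace is not tolerated: the caller
        strips formatting (FASTA readers do this already).
    min_length : int
        Shortest acceptable sequence; strength computations need 2.

    Raises
    ------
    SequenceError
        If empty, shorter than *min_length*, or containing a non-ACGT
        character (reported with its 1-based position).
    """
    if not raw:
        raise SequenceError("empty sequence")
    seq = raw.upper()
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise SequenceError(
                f"invalid character {ch!r} at position {i + 1}: only A/C/G/T are scorable"
            )
    if len(seq) < min_length:
        raise SequenceError(
            f"sequence of length {len(seq)} is too short (need >= {min_length})"
        )
    return seq


_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
    _ENCODE_LUT[_b + 32] = _i  # lowercase

#: step score indexed by 4*first + second (A,C,G,T -> 0..3)
_STEP_LUT = np.array(
    [STEP_VALUES["ACGT"[i] + "ACGT"[j]] for i in range(4) for j in range(4)],
    dtype=np.int64,
)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes 0–3 (A,C,G,T); 255 marks any other character."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _step_scores(seq: str) -> np.ndarray:
    codes = encode_sequence(seq)
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        i = int(bad[0])
        raise SequenceError(
            f"invalid character {seq[i]!r} at position {i + 1}: only A/C/G/T are scorable"
        )
    if codes.size < 2:
        raise SequenceError(
            f"sequence of length {codes.size} is too short (need >= 2 for a dinucleotide step)"
        )
    idx = codes[:-1].astype(np.intp) * 4 + codes[1:]
    return _STEP_LUT[idx]


def cumulative_strength(seq: str) -> int:
    """Sum of step scores over the n-1 overlapping dinucleotide steps, 5'->3'."""
    return int(_step_scores(seq).sum())


def strength_per_base(seq: str, round_2dp: bool = False) -> float:
    """Per-base strength parameter E = cumulative strength / n bases.

    ``round_2dp`` reproduces hand-calculation convention of carrying E at
    two decimals before the temperature equation (e.g. 128/15 -> 8.53).
    """
    e = cumulative_strength(seq) / len(seq)
    return round(e, 2) if round_2dp else e


@dataclass(frozen=True)
class StrengthResult:
    """Cumulative strength and per-base E of one sequence."""

    cumulative: int
    length: int

    @property
    def per_base_e(self) -> float:
        return self.cumulative / self.length

    @property
    def per_base_e_2dp(self) -> float:
        return round(self.per_base_e, 2)


def strength_result(seq: str) -> StrengthResult:
    """Score a sequence and return both the cumulative sum and per-base E."""
    return StrengthResult(cumulative=cumulative_strength(seq), length=len(seq))


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T alphabet (case-preserving complement table)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def strength_table_records() -> list[dict[str, int | str]]:
    """The 16-entry strength table as records: dinucleotide, stack class, components, total."""
    out = []
    for a in "ACGT":
        for b in "ACGT":
            step = a + b
            cls = classify_stack_group(step)
            out.append(
                {
                    "dinucleotide": step,
                    "stack_class": cls,
                    "stacking_value": STACKING_VALUES[cls],
                    "hbond_value": HBOND_BASE_VALUES[a] + HBOND_BASE_VALUES[b],
                    "total": STEP_VALUES[step],
                }
            )
    return out
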