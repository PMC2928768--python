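"""Synthetic sequences and Tm datasets with known generating truth.

Every other part of the package is testable offline through these
generators: random oligonucleotides with controlled GC content (i.i.d.
bases, optionally first-order Markov), synthetic chromosomes, and
datasets of (sequence, conditions, Tm) records in which the "experimental"
Tm is drawn from the log-linear model under known coefficients plus
Gaussian noise.  Defaults mirror a typical oligonucleotide melting
compilation: 123 records, lengths 15–100 nt, Na+ 0.01–1 M, strand
concentration 1e-7–1e-4 M, noise 1.36 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    MeltingConditions,
    ModelCoefficients,
    TmDatasetRecord,
    predict_tm_for_sequence,
    published_coefficients,
)

__all__ = [
    "SequenceGeneratorSpec",
    "SyntheticDatasetSpec",
    "random_sequence",
    "random_sequences",
    "markov_sequence",
    "synthetic_tm_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SequenceGeneratorSpec:
    """i.i.d. sequence generator: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""

    length: int
    gc_fraction: float = 0.5
    seed: int = 0
    count: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gc_fraction must be in [0,1] (got {self.gc_fraction})")
        if self.length < 2:
            raise ValueError(f"length must be >= 2 (got {self.length})")


def random_sequence(
    length: int,
    gc_fraction: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> str:
    """One i.i.d. random sequence with expected GC content ``gc_fraction``."""
    spec = SequenceGeneratorSpec(length=length, gc_fraction=gc_fraction)
    rng = np.random.default_rng(rng)
    p = np.array(
        [
            (1 - spec.gc_fraction) / 2,
            spec.gc_fraction / 2,
            spec.gc_fraction / 2,
            (1 - spec.gc_fraction) / 2,
        ]
    )
    return "".join(rng.choice(_BASES, size=length, p=p))


def random_sequences(spec: SequenceGeneratorSpec) -> list[str]:
    """``spec.count`` sequences from one seeded stream (reproducible)."""
    rng = np.random.default_rng(spec.seed)
    return [random_sequence(spec.length, spec.gc_fraction, rng) for _ in range(spec.count)]


def markov_sequence(
    length: int,
    transition: np.ndarray,
    rng: np.random.Generator | int | None = None,
) -> str:
    """First-order Markov sequence for dinucleotide-correlated stress tests.

    ``transition`` is a 4x4 row-stochastic matrix over (A, C, G, T);
    the initial base is drawn from its stationary distribution.
    """
    t = np.asarray(transition, dtype=float)
    if t.shape != (4, 4) or not np.allclose(t.sum(axis=1), 1.0):
        raise ValueError("transition must be a 4x4 row-stochastic matrix")
    rng = np.random.default_rng(rng)
    evals, evecs = np.linalg.eig(t.T)
    stat = np.real(evecs[:, np.argmin(np.abs(evals - 1))])
    stat = np.abs(stat) / np.abs(stat).sum()
    out = np.empty(length, dtype=np.intp)
    out[0] = rng.choice(4, p=stat)
    for i in range(1, length):
        out[i] = rng.choice(4, p=t[out[i - 1]])
    return "".join(_BASES[out])


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Design space and generating truth of a synthetic Tm dataset.

    Conditions are sampled log-uniformly over the stated ranges; with
    ``noise_sd`` = 0 the recorded Tm equals the model output exactly.
    """

    n_records: int = 123
    length_range: tuple[int, int] = (15, 100)
    na_range: tuple[float, float] = (0.01, 1.0)
    dna_range: tuple[float, float] = (1e-7, 1e-4)
    gc_range: tuple[float, float] = (0.2, 0.8)
    generating_coefficients: ModelCoefficients = field(
        default_factory=published_coefficients
    )
    noise_sd: float = 1.36
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("length_range", self.length_range),
            ("na_range", self.na_range),
            ("dna_range", self.dna_range),
            ("gc_range", self.gc_range),
        ):
            if lo > hi:
                raise ValueError(f"{name} lower bound exceeds upper bound")
        if self.length_range[0] < 2:
            raise ValueError("minimum length must be >= 2")
        if self.na_range[0] <= 0 or self.dna_range[0] <= 0:
            raise ValueError("concentration ranges must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def synthetic_tm_dataset(spec: SyntheticDatasetSpec) -> list[TmDatasetRecord]:
    """Sample a dataset whose exp_tm follows the model under known coefficients."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_records):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        gc = float(rng.uniform(*spec.gc_range))
        seq = random_sequence(length, gc, rng)
        cond = MeltingConditions(
            na_molar=float(np.exp(rng.uniform(*np.log(spec.na_range)))),
            strand_conc=float(np.exp(rng.uniform(*np.log(spec.dna_range)))),
            strand_conc_units="molar",
        )
        tm = predict_tm_for_sequence(seq, cond, spec.generating_coefficients)
        if spec.noise_sd > 0:
            tm += float(rng.normal(0.0, spec.noise_sd))
        records.append(
            TmDatasetRecord(id=f"syn{i:04d}", sequence=seq, conditions=cond, exp_tm=tm)
        )
    return records
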