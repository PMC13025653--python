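"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here with its true
underlying quantity returned alongside, so parameter recovery can be
tested end to end: saturating kinetic traces with a known initial rate,
Box-Behnken response tables drawn from a known quadratic surface, and
peptide identification tables with a planted set of funnel survivors.

All generators are pure functions of their arguments and the seed; the
PRNG is NumPy's PCG64 (``numpy.random.default_rng``), so a fixed seed
reproduces outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assays import KineticTrace
from .errors import DomainError
from .pepscreen import AMINO_ACIDS, PeptideRecord, ScreenConfig
from .rsm import DesignTable, FactorSpec, generate_bbd, model_matrix

__all__ = [
    "TraceSpec",
    "gen_kinetic_trace",
    "gen_bbd_responses",
    "gen_peptide_table",
]


@dataclass(frozen=True)
class TraceSpec:
    """Ground truth for a synthetic progress curve.

    The trace follows A(t) = baseline + rate * t + curvature * t^2 with t
    in minutes (curvature negative for a saturating curve), sampled every
    ``interval_s`` seconds for ``duration_min`` minutes, plus i.i.d.
    Gaussian noise of standard deviation ``noise_sd`` AU.  Defaults mirror
    a plate-reader ADH assay: one reading every 10 s for 10 min.
    """

    initial_rate: float = 0.02  # AU/min
    curvature: float = -0.0005  # AU/min^2
    baseline: float = 0.1  # AU
    duration_min: float = 10.0
    interval_s: float = 10.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.duration_min <= 0 or self.interval_s <= 0:
            raise DomainError("duration and sampling interval must be positive")


def gen_kinetic_trace(spec: TraceSpec = TraceSpec(), seed: int = 0) -> tuple[KineticTrace, float]:
    """Generate a noisy quadratic progress curve; returns (trace, true initial rate)."""
    rng = np.random.default_rng(seed)
    t_s = np.arange(0.0, spec.duration_min * 60.0 + 0.5 * spec.interval_s, spec.interval_s)
    t_min = t_s / 60.0
    clean = spec.baseline + spec.initial_rate * t_min + spec.curvature * t_min**2
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=t_s.shape)
    return KineticTrace(t_s, noisy, time_unit="s"), spec.initial_rate


def gen_bbd_responses(
    factors: tuple[FactorSpec, FactorSpec, FactorSpec],
    true_coefficients: dict[str, np.ndarray],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_center: int = 5,
) -> DesignTable:
    """Box-Behnken design with responses drawn from known quadratic surfaces.

    ``true_coefficients`` maps each response name to its ten coded-unit
    coefficients (intercept, A, B, C, AB, AC, BC, A^2, B^2, C^2); each
    response is the surface evaluated at the design runs plus
    N(0, noise_sd^2) noise.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    design = generate_bbd(factors, n_center=n_center)
    X = model_matrix(design.coded)
    for name, beta in true_coefficients.items():
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (10,):
            raise DomainError(f"response {name!r}: expected 10 coefficients, got {beta.shape}")
        design.responses[name] = X @ beta + rng.normal(0.0, noise_sd, size=design.n_runs)
    return design


def _random_sequence(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def gen_peptide_table(
    n: int = 100,
    n_planted: int = 5,
    seed: int = 0,
    length_range: tuple[int, int] = (4, 12),
    config: ScreenConfig = ScreenConfig(),
) -> tuple[list[PeptideRecord], set[str]]:
    """Peptide ID table with a planted set of funnel survivors.

    Planted records satisfy every stage of ``config`` with margin; every
    other record is forced to fail at least one randomly chosen stage
    (its remaining fields are drawn from the passing distributions, so
    decoys are not trivially bad everywhere).  Returns the records in a
    shuffled order together with the planted sequences.
    """
    if n_planted > n:
        raise DomainError(f"cannot plant {n_planted} survivors in {n} records")
    rng = np.random.default_rng(seed)

    sequences: list[str] = []
    seen: set[str] = set()
    while len(sequences) < n:
        s = _random_sequence(rng, length_range)
        if s not in seen:
            seen.add(s)
            sequences.append(s)

    def passing_fields() -> dict:
        return {
            "observed_mass": float(rng.uniform(400.0, 0.99 * config.max_mass)),
            "alc": float(rng.uniform(config.min_alc + 5.0, 99.0)),
            "peak_area": float(rng.uniform(2.0 * config.min_area, 100.0 * config.min_area)),
            "bioactivity": float(rng.uniform(config.min_bioactivity_score + 0.1, 0.99)),
            "toxicity": "Non-Toxin",
            "solubility": "good",
        }

    failure_modes = ("mass", "alc", "area", "bioactivity", "toxicity", "solubility")
    records: list[PeptideRecord] = []
    planted = set(sequences[:n_planted])
    for i, seq in enumerate(sequences):
        f = passing_fields()
        if i >= n_planted:
            mode = failure_modes[int(rng.integers(len(failure_modes)))]
            if mode == "mass":
                f["observed_mass"] = float(rng.uniform(1.01 * config.max_mass, 3.0 * config.max_mass))
            elif mode == "alc":
                f["alc"] = float(rng.uniform(20.0, 0.99 * config.min_alc))
            elif mode == "area":
                f["peak_area"] = float(rng.uniform(0.0, 0.99 * config.min_area))
            elif mode == "bioactivity":
                f["bioactivity"] = float(rng.uniform(0.0, 0.99 * config.min_bioactivity_score))
            elif mode == "toxicity":
                f["toxicity"] = "Toxin"
            else:
                f["solubility"] = "poor"
        records.append(
            PeptideRecord(
                sequence=seq,
                observed_mass=f["observed_mass"],
                alc=f["alc"],
                retention_time=float(rng.uniform(1.0, 30.0)),
                peak_area=f["peak_area"],
                external_scores={
                    "bioactivity": f["bioactivity"],
                    "toxicity": f["toxicity"],
                    "solubility": f["solubility"],
                },
            )
        )
    order = rng.permutation(n)
    return [records[i] for i in order], planted
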