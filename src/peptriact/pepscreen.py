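"""Peptide physicochemical properties and the virtual-screening funnel.

Sequence-based average/monoisotopic mass, Henderson-Hasselbalch net
charge, isoelectric point by bisection, and a staged threshold funnel
that reduces a de-novo MS peptide list (sequence, ALC, peak area, plus
external bioactivity/toxicity/solubility predictions) to candidate
bioactive peptides.

External predictors (bioactivity ranking, toxicity, solubility) are
third-party tools; this module treats their outputs as pluggable scores
carried on each record, never re-implementing the predictors themselves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

from pyteomics import mass as _pt_mass
from scipy.optimize import bisect

from .errors import DataError, DomainError, SequenceError

__all__ = [
    "AMINO_ACIDS",
    "ResidueTable",
    "DEFAULT_RESIDUE_TABLE",
    "PeptideRecord",
    "ScreenConfig",
    "StageResult",
    "FunnelReport",
    "average_mass",
    "monoisotopic_mass",
    "net_charge",
    "isoelectric_point",
    "screen",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Side-chain pKa values (standard biochemistry-textbook set) and termini.
_SIDE_CHAIN_PKA = {
    "D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07,  # acidic when deprotonated
    "H": 6.00, "K": 10.53, "R": 12.48,            # basic when protonated
}
_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


def _residue_masses() -> tuple[dict[str, float], dict[str, float], float, float]:
    avg, mono = {}, {}
    for aa in AMINO_ACIDS:
        comp = _pt_mass.std_aa_comp[aa]
        avg[aa] = _pt_mass.calculate_mass(composition=comp, average=True)
        mono[aa] = _pt_mass.calculate_mass(composition=comp)
    water = _pt_mass.Composition({"H": 2, "O": 1})
    return (avg, mono,
            _pt_mass.calculate_mass(composition=water, average=True),
            _pt_mass.calculate_mass(composition=water))


@dataclass(frozen=True)
class ResidueTable:
    """Per-residue masses and ionizable-group pKas used by all property functions.

    Masses are *residue* masses (amino acid minus water); a peptide's mass
    is the residue sum plus one water.  The pKa set covers the seven
    ionizable side chains (D, E, C, Y, H, K, R) and the two termini;
    individual entries can be overridden via :meth:`with_pka`.
    """

    average: Mapping[str, float]
    monoisotopic: Mapping[str, float]
    water_average: float
    water_monoisotopic: float
    pka: Mapping[str, float]
    pka_nterm: float = 9.0
    pka_cterm: float = 3.55

    def __post_init__(self) -> None:
        missing = sorted(set(AMINO_ACIDS) - set(self.average) | set(AMINO_ACIDS) - set(self.monoisotopic))
        if missing:
            raise DomainError(f"residue table missing masses for {missing}")
        for aa in AMINO_ACIDS:
            if self.average[aa] <= 0 or self.monoisotopic[aa] <= 0:
                raise DomainError(f"residue {aa} has a non-positive mass")
        for name, val in list(self.pka.items()) + [("N-term", self.pka_nterm), ("C-term", self.pka_cterm)]:
            if not 0.0 < val < 14.0:
                raise DomainError(f"pKa for {name} must lie in (0, 14), got {val}")

    def with_pka(self, **overrides: float) -> "ResidueTable":
        """New table with some pKa entries replaced (keys: residue letters, 'nterm', 'cterm')."""
        pka = dict(self.pka)
        kwargs: dict = {}
        for key, val in overrides.items():
            if key == "nterm":
                kwargs["pka_nterm"] = val
            elif key == "cterm":
                kwargs["pka_cterm"] = val
            elif key in pka:
                pka[key] = val
            else:
                raise DomainError(f"unknown pKa key {key!r}")
        return replace(self, pka=pka, **kwargs)


_avg, _mono, _w_avg, _w_mono = _residue_masses()
DEFAULT_RESIDUE_TABLE = ResidueTable(_avg, _mono, _w_avg, _w_mono, dict(_SIDE_CHAIN_PKA))


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise SequenceError("empty peptide sequence")
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise SequenceError(
                f"invalid residue {ch!r} at position {i + 1} of {sequence!r}"
            )
    return seq


def average_mass(sequence: str, table: ResidueTable = DEFAULT_RESIDUE_TABLE) -> float:
    """Average molecular mass (Da): sum of residue masses plus one water."""
    seq = _check_sequence(sequence)
    return sum(table.average[ch] for ch in seq) + table.water_average


def monoisotopic_mass(sequence: str, table: ResidueTable = DEFAULT_RESIDUE_TABLE) -> float:
    """Monoisotopic molecular mass (Da)."""
    seq = _check_sequence(sequence)
    return sum(table.monoisotopic[ch] for ch in seq) + table.water_monoisotopic


def net_charge(sequence: str, pH: float, table: ResidueTable = DEFAULT_RESIDUE_TABLE) -> float:
    """Henderson-Hasselbalch net charge at the given pH (fractional, signed).

    Positive groups (N-terminus, K, R, H) contribute
    ``10**pKa / (10**pKa + 10**pH)`` each; negative groups (C-terminus,
    D, E, C, Y) contribute ``-10**pH / (10**pKa + 10**pH)``.  Strictly
    decreasing in pH.
    """
    seq = _check_sequence(sequence)
    if not 0.0 <= pH <= 14.0:
        raise DomainError(f"pH must lie in [0, 14], got {pH}")

    def pos(pka: float) -> float:
        return 10.0 ** pka / (10.0 ** pka + 10.0 ** pH)

    def neg(pka: float) -> float:
        return 10.0 ** pH / (10.0 ** pka + 10.0 ** pH)

    q = pos(table.pka_nterm) - neg(table.pka_cterm)
    for ch in seq:
        if ch in _POSITIVE:
            q += pos(table.pka[ch])
        elif ch in _NEGATIVE:
            q -= neg(table.pka[ch])
    return q


def isoelectric_point(
    sequence: str,
    table: ResidueTable = DEFAULT_RESIDUE_TABLE,
    xtol: float = 1e-4,
) -> float:
    """pH at which the net charge is zero, found by bisection on [0, 14].

    With both termini present the charge is positive at pH 0 and negative
    at pH 14, so a root always exists and is unique (the charge is
    strictly decreasing).
    """
    seq = _check_sequence(sequence)
    q0, q14 = net_charge(seq, 0.0, table), net_charge(seq, 14.0, table)
    if not (q0 > 0 > q14):
        raise DomainError(
            f"net charge does not change sign on [0, 14] for {sequence!r} "
            f"(q(0)={q0:.3g}, q(14)={q14:.3g})"
        )
    return float(bisect(lambda p: net_charge(seq, p, table), 0.0, 14.0, xtol=xtol))


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide with optional MS metadata and external scores.

    ``external_scores`` may carry ``"bioactivity"`` (fraction in [0, 1]),
    ``"toxicity"`` (label, non-toxic when it normalises to "non-toxin")
    and ``"solubility"`` (label, soluble when "good").
    """

    sequence: str
    observed_mass: float | None = None  # Da, from MS
    alc: float | None = None  # percent
    retention_time: float | None = None  # min
    peak_area: float | None = None
    external_scores: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence))
        object.__setattr__(self, "external_scores", dict(self.external_scores))


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the screening funnel.

    All comparisons are strict inequalities.  ``mass_source`` selects the
    observed MS mass when present ("observed", falling back to the
    computed average mass) or always the computed mass
    ("computed-average").  ``missing_policy`` is "strict" (a record
    lacking a field needed by a stage is an error) or "lenient" (the
    stage passes that record through, with a warning).
    """

    max_mass: float = 1000.0  # Da
    min_alc: float = 80.0  # percent
    min_area: float = 1e5
    min_bioactivity_score: float = 0.5
    require_nontoxic: bool = True
    require_soluble: bool = True
    mass_source: str = "observed"
    missing_policy: str = "strict"

    def __post_init__(self) -> None:
        for name in ("max_mass", "min_alc", "min_area", "min_bioactivity_score"):
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"{name} must be finite")
        if self.mass_source not in ("observed", "computed-average"):
            raise DomainError(f"unknown mass_source {self.mass_source!r}")
        if self.missing_policy not in ("strict", "lenient"):
            raise DomainError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass(frozen=True)
class StageResult:
    name: str
    n_in: int
    n_out: int
    survivors: tuple[str, ...]


@dataclass(frozen=True)
class FunnelReport:
    """Per-stage attrition of the screening funnel."""

    stages: tuple[StageResult, ...]
    survivors: tuple[PeptideRecord, ...]

    def to_rows(self) -> list[dict]:
        return [
            {"stage": s.name, "entering": s.n_in, "surviving": s.n_out,
             "survivor_ids": ";".join(s.survivors)}
            for s in self.stages
        ]


def _default_score_provider(record: PeptideRecord) -> Mapping[str, object]:
    return record.external_scores


def _is_nontoxic(label: object) -> bool:
    return str(label).strip().lower().replace("_", "-") in ("non-toxin", "nontoxin", "non-toxic", "nontoxic")


def _is_soluble(label: object) -> bool:
    return str(label).strip().lower() == "good"


def screen(
    records: Sequence[PeptideRecord],
    config: ScreenConfig = ScreenConfig(),
    score_provider: Callable[[PeptideRecord], Mapping[str, object]] = _default_score_provider,
) -> FunnelReport:
    """Run the staged screening funnel over a peptide list.

    Stages, in order: molecular mass < ``max_mass``; ALC > ``min_alc``;
    peak area > ``min_area``; bioactivity score > ``min_bioactivity_score``;
    toxicity prediction non-toxic; solubility prediction good.  Because
    every stage is an independent per-record predicate, the final
    survivor set does not depend on stage order or record order.
    """
    if not records:
        raise DataError("no peptide records to screen")

    def mass_of(r: PeptideRecord) -> float:
        if config.mass_source == "observed" and r.observed_mass is not None:
            return r.observed_mass
        return average_mass(r.sequence)

    def need(r: PeptideRecord, value, stage: str):
        if value is None:
            if config.missing_policy == "strict":
                raise DataError(f"record {r.sequence!r} is missing the field required by stage {stage!r}")
            warnings.warn(
                f"record {r.sequence!r} missing data for stage {stage!r}; passed through (lenient)",
                stacklevel=3,
            )
        return value

    def stage_mass(r: PeptideRecord) -> bool | None:
        return mass_of(r) < config.max_mass

    def stage_alc(r: PeptideRecord) -> bool | None:
        v = need(r, r.alc, "alc")
        return None if v is None else v > config.min_alc

    def stage_area(r: PeptideRecord) -> bool | None:
        v = need(r, r.peak_area, "peak_area")
        return None if v is None else v > config.min_area

    def stage_bioactivity(r: PeptideRecord) -> bool | None:
        v = need(r, score_provider(r).get("bioactivity"), "bioactivity")
        return None if v is None else float(v) > config.min_bioactivity_score

    def stage_toxicity(r: PeptideRecord) -> bool | None:
        v = need(r, score_provider(r).get("toxicity"), "toxicity")
        return None if v is None else _is_nontoxic(v)

    def stage_solubility(r: PeptideRecord) -> bool | None:
        v = need(r, score_provider(r).get("solubility"), "solubility")
        return None if v is None else _is_soluble(v)

    stages: list[tuple[str, Callable[[PeptideRecord], bool | None]]] = [
        (f"mass < {config.max_mass:g} Da", stage_mass),
        (f"ALC > {config.min_alc:g}%", stage_alc),
        (f"peak area > {config.min_area:g}", stage_area),
        (f"bioactivity > {config.min_bioactivity_score:g}", stage_bioactivity),
    ]
    if config.require_nontoxic:
        stages.append(("non-toxic", stage_toxicity))
    if config.require_soluble:
        stages.append(("soluble", stage_solubility))

    current = list(records)
    results = []
    for name, predicate in stages:
        n_in = len(current)
        kept = [r for r in current if predicate(r) is not False]
        results.append(StageResult(name, n_in, len(kept), tuple(r.sequence for r in kept)))
        current = kept
    return FunnelReport(tuple(results), tuple(current))
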