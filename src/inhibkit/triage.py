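"""Hit-to-lead decision layer: free-energy conversions, candidate
enumeration, potency triage, and pesticide-likeness filtering.

Sign convention: dG = RT*ln(Ki) with Ki in molar, so tighter binding is more
negative and a binding free-energy shift ddG = RT*ln(Ki_new/Ki_ref) below
zero means an improvement.  A 10-fold potency gain at 300 K corresponds to
ddG = -RT*ln(10) = -1.37 kcal/mol, the default triage threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError
from .models import ThermoContext

#: Substitution groups scanned at each ring position.
GROUPS: dict[str, str] = {
    "a": "-F", "b": "-Cl", "c": "-Br", "d": "-NO2", "e": "-CH3",
    "f": "-CF3", "g": "-OCH3", "h": "-OH", "i": "-NH2", "j": "-COOH",
}

#: Ring positions (benzothiazole carbons) scanned.
SITES: tuple[int, ...] = (4, 5, 6, 7)

#: Scaffold series: 1 = CH scaffold, 2 = its nitrogen analogue.
SERIES: tuple[int, ...] = (1, 2)

#: Default pesticide-likeness limits (all inequalities are <=).
LIKENESS_LIMITS: dict[str, float] = {
    "MW": 435.0, "ClogP": 6.0, "HBA": 6, "HBD": 2, "ROB": 9, "ARB": 17,
}

#: Default triage threshold, kcal/mol: RT*ln(1/10) at 300 K to 2 decimals.
DDG_THRESHOLD = -1.37


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical descriptors consumed (not computed) by the filter."""

    MW: float
    ClogP: float
    HBA: int
    HBD: int
    ROB: int
    ARB: int

    def __post_init__(self) -> None:
        if self.MW <= 0:
            raise InvalidInputError("MW must be positive")
        for name in ("HBA", "HBD", "ROB", "ARB"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise InvalidInputError(f"{name} must be a non-negative integer")


@dataclass(frozen=True)
class CandidateID:
    """Identity of one enumerated substitution candidate.

    Candidates are numbered 2..81: series-major, then site 4->7, then group
    a->j, so compound 2 is (series 1, site 4, group a) and compound 81 is
    (series 2, site 7, group j).
    """

    series: int
    site: int
    group: str
    compound_number: int

    def __post_init__(self) -> None:
        if self.series not in SERIES or self.site not in SITES or self.group not in GROUPS:
            raise InvalidInputError("invalid series/site/group")

    @property
    def name(self) -> str:
        """Series-site-group label, e.g. '1-4a'."""
        return f"{self.series}-{self.site}{self.group}"

    @property
    def substituent(self) -> str:
        return GROUPS[self.group]


@dataclass
class PotencyRecord:
    """Potency summary of one compound relative to a reference."""

    Ki: float
    dG: float
    ddG: float
    fold_change: float
    LE: float = math.nan
    n_heavy: int = 0


@dataclass
class CandidateRecord:
    """One candidate row: identity, energies, potency, descriptors, verdicts."""

    id: CandidateID | None = None
    label: str = ""
    ddG_cal: float | None = None
    Ki_exp: float | None = None
    ddG_exp: float | None = None
    descriptors: DescriptorSet | None = None
    synthesizable: bool | None = None
    verdicts: dict[str, bool] = field(default_factory=dict)


def ddG_from_ki(ki_new: float, ki_ref: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Binding free-energy shift RT*ln(ki_new/ki_ref), kcal/mol.

    Antisymmetric in its arguments and additive along substitution chains.
    """
    if ki_new <= 0 or ki_ref <= 0:
        raise InvalidInputError("Ki values must be positive")
    return ctx.RT * math.log(ki_new / ki_ref)


def dG_from_ki(ki: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Binding free energy RT*ln(Ki), kcal/mol (Ki molar; negative for Ki < 1 M)."""
    if ki <= 0:
        raise InvalidInputError("Ki must be positive")
    return ctx.RT * math.log(ki)


def fold_improvement(ki_ref: float, ki_new: float) -> float:
    """Potency fold change ki_ref/ki_new (> 1 means the new compound is tighter)."""
    if ki_ref <= 0 or ki_new <= 0:
        raise InvalidInputError("Ki values must be positive")
    return ki_ref / ki_new


def ligand_efficiency(ki: float, n_heavy: int, ctx: ThermoContext = ThermoContext()) -> float:
    """Ligand efficiency -RT*ln(Ki)/n_heavy, kcal/mol per non-hydrogen atom."""
    if ki <= 0:
        raise InvalidInputError("Ki must be positive")
    if n_heavy < 1:
        raise InvalidInputError("n_heavy must be >= 1")
    if ki >= 1.0:
        warnings.warn("Ki >= 1 M gives non-positive ligand efficiency", stacklevel=2)
    return -dG_from_ki(ki, ctx) / n_heavy


def potency_record(ki: float, ki_ref: float, n_heavy: int | None = None,
                   ctx: ThermoContext = ThermoContext()) -> PotencyRecord:
    """Bundle dG/ddG/fold (and LE when n_heavy is given) for one compound."""
    rec = PotencyRecord(
        Ki=ki, dG=dG_from_ki(ki, ctx), ddG=ddG_from_ki(ki, ki_ref, ctx),
        fold_change=fold_improvement(ki_ref, ki),
    )
    if n_heavy:
        rec.LE = ligand_efficiency(ki, n_heavy, ctx)
        rec.n_heavy = n_heavy
    return rec


def enumerate_candidates(
    sites: Sequence[int] = SITES,
    groups: Sequence[str] = tuple(GROUPS),
    series: Sequence[int] = SERIES,
    first_number: int = 2,
) -> list[CandidateID]:
    """Enumerate all substitution candidates in the documented order.

    Numbering is series-major, then site in the given order, then group, and
    starts at ``first_number`` (the parent hit is compound 1).  With the
    defaults this yields the 80 candidates 2..81.
    """
    if len(set(sites)) != len(sites) or len(set(groups)) != len(groups) \
            or len(set(series)) != len(series):
        raise InvalidInputError("duplicate site, group, or series labels")
    out = []
    n = first_number
    for sr in series:
        for site in sites:
            for g in groups:
                out.append(CandidateID(series=sr, site=site, group=g, compound_number=n))
                n += 1
    return out


@dataclass
class TriageResult:
    selected: list[CandidateRecord]
    n_selected: int
    n_missing: int
    threshold: float


def triage_by_ddG(candidates: Iterable[CandidateRecord],
                  threshold: float = DDG_THRESHOLD) -> TriageResult:
    """Select candidates with ddG_cal strictly below ``threshold``.

    A shift of exactly the threshold is excluded ("lower than").  Candidates
    without a calculated shift are skipped and counted in ``n_missing``.
    The selection is sorted ascending by ddG_cal (best first).
    """
    with_ddg, missing = [], 0
    for c in candidates:
        if c.ddG_cal is None or (isinstance(c.ddG_cal, float) and math.isnan(c.ddG_cal)):
            missing += 1
        else:
            with_ddg.append(c)
    if missing:
        warnings.warn(f"{missing} candidate(s) lack ddG_cal and were excluded", stacklevel=2)
    selected = sorted((c for c in with_ddg if c.ddG_cal < threshold),
                      key=lambda c: c.ddG_cal)
    return TriageResult(selected, len(selected), missing, threshold)


@dataclass
class LikenessVerdict:
    passed: bool
    flags: dict[str, bool]


def pesticide_likeness(d: DescriptorSet,
                       limits: Mapping[str, float] = LIKENESS_LIMITS) -> LikenessVerdict:
    """Six-rule physicochemical filter for agrochemical candidates.

    Passes iff MW <= 435 Da, ClogP <= 6, HBA <= 6, HBD <= 2, ROB <= 9 and
    ARB <= 17 (boundary values pass).  Per-rule booleans are returned.
    """
    if d is None:
        raise InvalidInputError("descriptor set required")
    flags = {}
    for name, limit in limits.items():
        value = getattr(d, name, None)
        if value is None:
            raise InvalidInputError(f"missing descriptor {name!r}")
        flags[name] = value <= limit
    return LikenessVerdict(all(flags.values()), flags)


def ddG_correlation(ddg_cal: Sequence[float], ddg_exp: Sequence[float]):
    """Squared Pearson correlation and OLS line of experimental on calculated shifts.

    Returns (r_squared, slope, intercept); needs >= 3 pairs with variance on
    both axes.
    """
    x = np.asarray(ddg_cal, dtype=float)
    y = np.asarray(ddg_exp, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidInputError("need >= 3 paired shifts")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError("zero variance on one axis")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.slope), float(res.intercept)
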