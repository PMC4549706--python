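"""Domain types and forward kinetic equations.

Everything downstream (simulation, fitting, triage) is built on the three
forward models defined here:

* the Michaelis-Menten inhibition family (``mm_rate``) for fast-binding
  inhibitors, in its competitive / noncompetitive / uncompetitive / mixed
  forms;
* the one-step slow-binding integrated progress-curve equation
  (``slow_binding_progress``), P(t) = vs*t + (v0 - vs)*(1 - exp(-kobs*t))/kobs;
* the linear law for the observed first-order rate constant
  (``kobs_law``), kobs = k-0 + k+0*[I]/(1 + [S]/Km) for a competitive
  slow-binding inhibitor and kobs = k-0 + k+0*[I] for a noncompetitive one.

Unit convention: concentrations in molar, time in seconds, rates in molar/s
(or absorbance-equivalents/s; the equations are scale-free in the signal).
I/O layers convert from the uM/nM columns used in assay tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Default absolute temperature (K); RT*ln(10) = 1.373 kcal/mol at this T.
T_DEFAULT = 300.0

MODALITIES = ("competitive", "noncompetitive", "uncompetitive", "mixed", "undetermined")

FAST_MODALITIES = ("competitive", "noncompetitive", "uncompetitive", "mixed")


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic context for free-energy conversions.

    Attributes
    ----------
    R : float
        Gas constant, kcal mol^-1 K^-1.
    T : float
        Absolute temperature, K.
    """

    R: float = R_KCAL
    T: float = T_DEFAULT

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0:
            raise InvalidInputError("R and T must both be positive")

    @property
    def RT(self) -> float:
        """R*T in kcal/mol."""
        return self.R * self.T


@dataclass(frozen=True)
class AssayDesign:
    """Concentration grid and sampling scheme of one inhibition assay.

    ``substrate_concs`` and ``inhibitor_concs`` are in molar.  When
    ``per_substrate_inhibitors`` is given it lists one inhibitor grid per
    substrate level (used for slow-binding studies where the inhibitor
    titration is scaled with the substrate level); otherwise the full
    Cartesian product of the two grids is used.
    """

    assay_id: str
    varied_substrate: str
    substrate_concs: tuple[float, ...]
    inhibitor_concs: tuple[float, ...] = ()
    duration: float = 600.0
    n_timepoints: int = 60
    per_substrate_inhibitors: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrate_concs", tuple(float(s) for s in self.substrate_concs))
        object.__setattr__(self, "inhibitor_concs", tuple(float(i) for i in self.inhibitor_concs))
        if self.per_substrate_inhibitors is not None:
            object.__setattr__(
                self,
                "per_substrate_inhibitors",
                tuple(tuple(float(i) for i in grid) for grid in self.per_substrate_inhibitors),
            )
            if len(self.per_substrate_inhibitors) != len(self.substrate_concs):
                raise InvalidInputError(
                    "per_substrate_inhibitors must carry one grid per substrate level"
                )
        if any(s < 0 for s in self.substrate_concs):
            raise InvalidInputError("substrate concentrations must be >= 0")
        for grid in self.inhibitor_grids():
            if any(i < 0 for i in grid):
                raise InvalidInputError("inhibitor concentrations must be >= 0")
        if self.n_timepoints < 4:
            raise InvalidInputError("need at least 4 time points")
        if self.duration <= 0:
            raise InvalidInputError("duration must be positive")

    def inhibitor_grids(self) -> tuple[tuple[float, ...], ...]:
        """Inhibitor grid for each substrate level, in order."""
        if self.per_substrate_inhibitors is not None:
            return self.per_substrate_inhibitors
        return tuple(self.inhibitor_concs for _ in self.substrate_concs)

    def grid(self) -> list[tuple[float, float]]:
        """All (S, I) pairs of the design, molar."""
        return [
            (s, i)
            for s, grid in zip(self.substrate_concs, self.inhibitor_grids())
            for i in grid
        ]


@dataclass
class ProgressCurve:
    """A single timed product-formation trace at fixed [S] and [I].

    times are seconds (strictly increasing, starting at >= 0); signal is the
    accumulated product in molar or absorbance-equivalent units; S and I are
    molar.
    """

    times: np.ndarray
    signal: np.ndarray
    S: float
    I: float
    assay_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.signal.shape:
            raise InvalidInputError("times and signal must be 1-d arrays of equal length")
        if self.times.size and self.times[0] < 0:
            raise InvalidInputError("times must start at >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.S < 0 or self.I < 0:
            raise InvalidInputError("concentrations must be >= 0")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class SlowBindingCurveFit:
    """(v0, vs, kobs) estimates for one progress curve.

    ``slow_binding`` is False when the trace is statistically linear, in which
    case v0 == vs == the fitted straight-line slope and kobs is NaN.
    """

    v0: float
    vs: float
    kobs: float
    se_v0: float = math.nan
    se_vs: float = math.nan
    se_kobs: float = math.nan
    sse: float = math.nan
    converged: bool = True
    slow_binding: bool = True
    n_points: int = 0
    f_pvalue: float = math.nan


@dataclass
class KobsRegression:
    """OLS line kobs = B + A*[I] at one substrate level.

    A (slope) is the apparent association constant in s^-1 M^-1; B
    (intercept) is the apparent dissociation constant in s^-1.
    """

    A: float
    B: float
    se_A: float
    se_B: float
    r_squared: float
    n: int
    S: float = math.nan


@dataclass
class MicroscopicConstants:
    """True association/dissociation rate constants and the derived Ki.

    k_plus0 in s^-1 M^-1, k_minus0 in s^-1, Ki = k_minus0/k_plus0 in molar.
    """

    k_plus0: float
    k_minus0: float
    modality: str
    se_k_plus0: float = math.nan
    se_k_minus0: float = math.nan
    Ki: float = field(init=False)

    def __post_init__(self) -> None:
        if self.k_plus0 <= 0 or self.k_minus0 <= 0:
            raise InvalidInputError("rate constants must be positive")
        if self.modality not in MODALITIES:
            raise InvalidInputError(f"unknown modality {self.modality!r}")
        self.Ki = self.k_minus0 / self.k_plus0

    @property
    def Ki_nM(self) -> float:
        return self.Ki * 1e9

    @property
    def k_plus0_per_nM(self) -> float:
        """k+0 in s^-1 nM^-1, the unit assay reports are printed in."""
        return self.k_plus0 * 1e-9


def _as_nonneg(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError(f"{name} must be >= 0")
    return arr


def mm_rate(
    S,
    I,
    modality: str,
    Vmax: float,
    Km: float,
    Ki: float | None = None,
    Kic: float | None = None,
    Kiu: float | None = None,
):
    """Michaelis-Menten initial rate under one of the four inhibition laws.

    Parameters are molar (Km, Ki, Kic, Kiu) and rate units/s (Vmax).  S and I
    broadcast like numpy arrays.  The mixed law uses Kic for the competitive
    component and Kiu for the uncompetitive one; the other three laws take a
    single Ki.

    Returns the rate v >= 0, monotone increasing in S and non-increasing in I.
    """
    S = _as_nonneg(S, "S")
    I = _as_nonneg(I, "I")
    if Vmax <= 0 or Km <= 0:
        raise InvalidInputError("Vmax and Km must be positive")
    if modality == "mixed":
        if Kic is None or Kiu is None or Kic <= 0 or Kiu <= 0:
            raise InvalidInputError("mixed law requires positive Kic and Kiu")
        v = Vmax * S / (Km * (1.0 + I / Kic) + S * (1.0 + I / Kiu))
    elif modality in ("competitive", "noncompetitive", "uncompetitive"):
        if Ki is None or Ki <= 0:
            raise InvalidInputError(f"{modality} law requires positive Ki")
        if modality == "competitive":
            v = Vmax * S / (Km * (1.0 + I / Ki) + S)
        elif modality == "noncompetitive":
            v = Vmax * S / ((Km + S) * (1.0 + I / Ki))
        else:  # uncompetitive
            v = Vmax * S / (Km + S * (1.0 + I / Ki))
    else:
        raise InvalidInputError(f"unknown modality {modality!r}")
    return v


def slow_binding_progress(t, v0: float, vs: float, kobs: float):
    """Integrated product trace of a one-step slow-binding inhibitor.

    P(t) = vs*t + (v0 - vs)*(1 - exp(-kobs*t))/kobs

    with P(0) = 0, initial slope v0 and asymptotic slope vs.  Requires
    kobs > 0; for a curve with no slow phase use ``linear_progress``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("t must be >= 0")
    if kobs <= 0:
        raise InvalidInputError("kobs must be positive; use linear_progress for kobs -> 0")
    # -expm1(-k t)/k is the numerically stable form of (1 - exp(-k t))/k
    return vs * t + (v0 - vs) * (-np.expm1(-kobs * t)) / kobs


def linear_progress(t, v: float):
    """Straight-line trace P(t) = v*t, the kobs -> 0 (or [I]=0) limit."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("t must be >= 0")
    return v * t


def kobs_law(
    I,
    k_plus0: float,
    k_minus0: float,
    modality: str,
    S=0.0,
    Km: float | None = None,
):
    """Observed first-order rate constant for a one-step slow-binding inhibitor.

    competitive:    kobs = k-0 + k+0*[I] / (1 + [S]/Km)
    noncompetitive: kobs = k-0 + k+0*[I]

    All concentrations molar; k_plus0 in s^-1 M^-1, k_minus0 in s^-1.  At
    S = 0 the two laws coincide; for a competitive inhibitor kobs decreases
    with S at fixed I > 0, while for a noncompetitive one it is independent
    of S.
    """
    I = _as_nonneg(I, "I")
    if k_plus0 <= 0 or k_minus0 < 0:
        raise InvalidInputError("k_plus0 must be > 0 and k_minus0 >= 0")
    if modality == "noncompetitive":
        return k_minus0 + k_plus0 * I + 0.0 * np.asarray(S, dtype=float)
    if modality == "competitive":
        S = _as_nonneg(S, "S")
        if Km is None or Km <= 0:
            raise InvalidInputError("competitive kobs law requires positive Km")
        return k_minus0 + k_plus0 * I / (1.0 + S / Km)
    raise InvalidInputError(f"unknown slow-binding modality {modality!r}")


def apparent_ki(Ki: float, modality: str, S: float = 0.0, Km: float | None = None) -> float:
    """Apparent inhibition constant at substrate level S.

    Ki_app = Ki*(1 + S/Km) for a competitive inhibitor; Ki otherwise.  The
    steady-state rate of a slow-binding trace obeys vs = v0/(1 + I/Ki_app).
    """
    if Ki <= 0:
        raise InvalidInputError("Ki must be positive")
    if modality == "competitive":
        if Km is None or Km <= 0:
            raise InvalidInputError("competitive Ki_app requires positive Km")
        return Ki * (1.0 + S / Km)
    return Ki
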