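"""Slow-binding progress-curve inference.

The analysis chain mirrors how slow-binding inhibition assays are worked up:

1. each product trace at fixed ([S], [I]) is fitted to the one-step
   integrated equation to extract (v0, vs, kobs);
2. at each substrate level, kobs is regressed on [I] to give the apparent
   association constant A (slope) and dissociation constant B (intercept);
3. the substrate-dependence of A and B diagnoses the binding modality:
   A falling with [S] while B stays flat is the competitive signature, no
   [S]-dependence at all is the noncompetitive one;
4. the true microscopic constants k+0 and k-0, and Ki = k-0/k+0, are
   derived from the A/B values (for the competitive case through the linear
   1/A-versus-[S] relation 1/A = (1/k+0)*(1 + [S]/Km)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .errors import InconsistentDataError, InsufficientDesignError, InvalidInputError
from .models import (
    KobsRegression,
    MicroscopicConstants,
    ProgressCurve,
    SlowBindingCurveFit,
    slow_binding_progress,
)

_KOBS_START_FACTORS = (0.5, 1.0, 2.0, 5.0, 10.0)


class ProgressCurveFitter(BaseEstimator):
    """Nonlinear least-squares fitter for one slow-binding progress curve.

    Fits P(t) = vs*t + (v0 - vs)*(1 - exp(-kobs*t))/kobs by multistart
    least squares (five deterministic starts with kobs in
    {0.5, 1, 2, 5, 10}/T_end; v0 seeded from the first-decile secant slope
    and vs from the last-quintile secant slope; best SSE wins, ties broken
    toward smaller kobs).  A curve whose slow phase is not statistically
    detectable (F-test of the three-parameter model against a straight line
    through the origin, p > ``alpha``) is reported with
    ``slow_binding_ = False`` and v0 = vs = the straight-line slope.

    Parameters
    ----------
    alpha : float
        Significance level of the linearity F-test.
    max_nfev : int
        Iteration budget per start.
    ftol, xtol : float
        Convergence tolerances passed to ``scipy.optimize.least_squares``.
    """

    def __init__(self, alpha: float = 0.05, max_nfev: int = 500,
                 ftol: float = 1e-10, xtol: float = 1e-8):
        self.alpha = alpha
        self.max_nfev = max_nfev
        self.ftol = ftol
        self.xtol = xtol

    # -- internal pieces -------------------------------------------------
    @staticmethod
    def _secant_slope(t: np.ndarray, y: np.ndarray) -> float:
        dt = t[-1] - t[0]
        return (y[-1] - y[0]) / dt if dt > 0 else 0.0

    def _starts(self, t: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        n = t.size
        k0 = max(2, n // 10)
        v0_init = self._secant_slope(t[:k0], y[:k0])
        tail = max(2, n // 5)
        vs_init = self._secant_slope(t[-tail:], y[-tail:])
        t_end = t[-1] if t[-1] > 0 else 1.0
        scale = max(abs(v0_init), abs(vs_init), 1e-300)
        v0_init = max(v0_init, 1e-6 * scale)
        vs_init = max(vs_init, 1e-6 * scale)
        return [np.array([v0_init, vs_init, f / t_end]) for f in _KOBS_START_FACTORS]

    def fit(self, t, y):
        """Fit the curve; ``t`` seconds, ``y`` accumulated signal."""
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise InvalidInputError("t and y must be 1-d arrays of equal length")
        if t.size < 6:
            raise InvalidInputError("need at least 6 time points")
        if np.ptp(y) == 0:
            raise InvalidInputError("signal is constant; nothing to fit")
        n = t.size

        # straight line through the origin, the no-slow-phase null model
        stt = float(np.dot(t, t))
        v_lin = float(np.dot(t, y) / stt)
        sse_lin = float(np.sum((y - v_lin * t) ** 2))

        # fit in normalized units: rates in y-range per T_end, kobs in 1/T_end
        y_scale = float(np.max(np.abs(y)))
        t_end = float(t[-1]) if t[-1] > 0 else 1.0
        v_unit = y_scale / t_end
        yn, tn = y / y_scale, t / t_end

        def residuals(p):
            v0, vs, kobs = p
            return slow_binding_progress(tn, v0, vs, kobs) - yn

        best = None
        for p0 in self._starts(t, y):
            p0n = np.array([p0[0] / v_unit, p0[1] / v_unit, p0[2] * t_end])
            try:
                sol = optimize.least_squares(
                    residuals, p0n,
                    bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
                    max_nfev=self.max_nfev, ftol=self.ftol, xtol=self.xtol,
                )
            except Exception:
                continue
            sse = float(2.0 * sol.cost) * y_scale**2
            if best is None or sse < best[0] * (1 - 1e-12) or (
                abs(sse - best[0]) <= 1e-12 * max(best[0], 1e-300)
                and sol.x[2] < best[1].x[2]
            ):
                best = (sse, sol)
        if best is None:
            self.v0_, self.vs_, self.kobs_ = math.nan, math.nan, math.nan
            self.se_v0_ = self.se_vs_ = self.se_kobs_ = math.nan
            self.sse_, self.converged_, self.slow_binding_ = math.nan, False, True
            self.f_pvalue_, self.n_ = math.nan, n
            return self
        sse, sol = best

        # F-test: does the slow-binding model beat the straight line?
        dof = n - 3
        if sse <= 0 or dof <= 0:
            f_p = 0.0 if sse_lin > sse else 1.0
        else:
            f = max(sse_lin - sse, 0.0) / 2.0 / (sse / dof)
            f_p = float(stats.f.sf(f, 2, dof))
        # a numerically exact straight line (SSE at float-noise level) is
        # linear regardless of the F statistic
        exact_line = sse_lin <= n * (1e-10 * y_scale) ** 2
        if f_p > self.alpha or sse_lin <= sse * (1 + 1e-12) or exact_line:
            se_v = math.sqrt(sse_lin / max(n - 1, 1) / stt)
            self.v0_ = self.vs_ = v_lin
            self.kobs_ = math.nan
            self.se_v0_ = self.se_vs_ = se_v
            self.se_kobs_ = math.nan
            self.sse_ = sse_lin
            self.converged_ = True
            self.slow_binding_ = False
            self.f_pvalue_ = f_p
            self.n_ = n
            return self

        se = np.full(3, math.nan)
        if dof > 0:
            jtj = sol.jac.T @ sol.jac
            try:
                cov = np.linalg.pinv(jtj) * (2.0 * sol.cost / dof)
                se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            except np.linalg.LinAlgError:
                pass
        unit = np.array([v_unit, v_unit, 1.0 / t_end])
        self.v0_, self.vs_, self.kobs_ = (float(v) for v in sol.x * unit)
        self.se_v0_, self.se_vs_, self.se_kobs_ = (float(s) for s in se * unit)
        self.sse_ = sse
        self.converged_ = bool(sol.status > 0)
        self.slow_binding_ = True
        self.f_pvalue_ = f_p
        self.n_ = n
        return self

    def predict(self, t):
        """Fitted trace at the requested times."""
        t = np.asarray(t, dtype=float)
        if not self.slow_binding_:
            return self.v0_ * t
        return slow_binding_progress(t, self.v0_, self.vs_, self.kobs_)


def fit_progress_curve(curve: ProgressCurve, **options) -> SlowBindingCurveFit:
    """Fit one :class:`ProgressCurve`; thin wrapper over ProgressCurveFitter."""
    fitter = ProgressCurveFitter(**options).fit(curve.times, curve.signal)
    return SlowBindingCurveFit(
        v0=fitter.v0_, vs=fitter.vs_, kobs=fitter.kobs_,
        se_v0=fitter.se_v0_, se_vs=fitter.se_vs_, se_kobs=fitter.se_kobs_,
        sse=fitter.sse_, converged=fitter.converged_,
        slow_binding=fitter.slow_binding_, n_points=fitter.n_,
        f_pvalue=fitter.f_pvalue_,
    )


def regress_kobs_vs_inhibitor(
    inhibitor_concs: Sequence[float],
    kobs_values: Sequence[float],
    S: float = math.nan,
) -> KobsRegression:
    """OLS regression kobs = B + A*[I] at one substrate level.

    ``inhibitor_concs`` molar; at least three distinct levels are required.
    Unweighted, matching how the apparent constants are usually read off a
    straight-line titration.
    """
    I = np.asarray(inhibitor_concs, dtype=float)
    k = np.asarray(kobs_values, dtype=float)
    if I.shape != k.shape or I.ndim != 1:
        raise InvalidInputError("inhibitor_concs and kobs_values must match in shape")
    if np.unique(I).size < 3:
        raise InsufficientDesignError(
            "kobs regression needs >= 3 distinct inhibitor levels"
        )
    res = stats.linregress(I, k)
    return KobsRegression(
        A=float(res.slope), B=float(res.intercept),
        se_A=float(res.stderr), se_B=float(res.intercept_stderr),
        r_squared=float(res.rvalue**2), n=int(I.size), S=float(S),
    )


@dataclass
class ModalityEvidence:
    """Evidence table behind a slow-binding modality call."""

    modality: str
    reason: str
    inv_A_slope: float = math.nan
    inv_A_slope_p: float = math.nan
    B_slope_p: float = math.nan
    B_rel_range: float = math.nan
    n_substrate_levels: int = 0


def classify_slow_binding_modality(
    regressions: Mapping[float, KobsRegression],
    alpha: float = 0.05,
    equivalence_band: float = 0.20,
) -> ModalityEvidence:
    """Diagnose competitive vs noncompetitive binding from A/B-vs-[S] trends.

    Competitive: the slope of 1/A against [S] is significantly positive
    (one-sided t-test at ``alpha``) AND B shows no significant trend in [S]
    (two-sided p > alpha) with relative range below ``equivalence_band``.
    Noncompetitive: no significant [S]-dependence of A.  Anything else (or
    fewer than three substrate levels) is undetermined.
    """
    S = np.array(sorted(regressions), dtype=float)
    if S.size < 3:
        return ModalityEvidence(
            "undetermined",
            f"only {S.size} substrate level(s); need >= 3 for the A/B trend test",
            n_substrate_levels=int(S.size),
        )
    A = np.array([regressions[s].A for s in S])
    B = np.array([regressions[s].B for s in S])
    if np.any(A <= 0):
        return ModalityEvidence("undetermined", "non-positive apparent association constant",
                                n_substrate_levels=int(S.size))
    res_a = stats.linregress(S, 1.0 / A)
    p_a_onesided = res_a.pvalue / 2.0 if res_a.slope > 0 else 1.0 - res_a.pvalue / 2.0
    res_b = stats.linregress(S, B)
    b_rel_range = float(np.ptp(B) / abs(np.mean(B))) if np.mean(B) != 0 else math.inf
    # an exactly constant B gives an undefined trend p-value: clearly invariant
    b_pvalue = 1.0 if math.isnan(res_b.pvalue) else float(res_b.pvalue)
    b_invariant = (b_pvalue > alpha) and (b_rel_range < equivalence_band)
    a_depends_on_S = p_a_onesided < alpha

    if a_depends_on_S and b_invariant:
        modality, reason = "competitive", "A decreases with [S] (1/A linear in [S]); B invariant"
    elif not a_depends_on_S:
        modality, reason = "noncompetitive", "no significant [S]-dependence of the kobs line"
    else:
        modality, reason = "undetermined", "A depends on [S] but B is not invariant"
    return ModalityEvidence(
        modality, reason,
        inv_A_slope=float(res_a.slope), inv_A_slope_p=float(p_a_onesided),
        B_slope_p=b_pvalue, B_rel_range=b_rel_range,
        n_substrate_levels=int(S.size),
    )


def _weighted_mean(values: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """Inverse-variance weighted mean; falls back to the plain mean when any
    standard error is missing or zero."""
    ok = np.isfinite(ses) & (ses > 0)
    if not np.all(ok):
        return float(np.mean(values)), float("nan")
    w = 1.0 / ses**2
    m = float(np.sum(w * values) / np.sum(w))
    return m, float(math.sqrt(1.0 / np.sum(w)))


def derive_microscopic_constants(
    regressions: Mapping[float, KobsRegression],
    modality: str,
    Km: float | None = None,
) -> MicroscopicConstants:
    """Derive (k+0, k-0, Ki) from the apparent constants.

    Noncompetitive: k+0 and k-0 are the (inverse-variance pooled) A and B.
    Competitive: k-0 is the pooled B; k+0 comes from the linear relation
    1/A = (1/k+0)*(1 + [S]/Km).  With ``Km`` supplied the line is forced
    through the origin in the regressor x = 1 + S/Km; with ``Km=None`` both
    k+0 and Km are read off the free 1/A-vs-[S] line (needs >= 2 levels).
    Ki = k-0/k+0 in molar.
    """
    if not regressions:
        raise InsufficientDesignError("no kobs regressions supplied")
    S = np.array(sorted(regressions), dtype=float)
    A = np.array([regressions[s].A for s in S])
    B = np.array([regressions[s].B for s in S])
    se_A = np.array([regressions[s].se_A for s in S])
    se_B = np.array([regressions[s].se_B for s in S])
    if np.any(A <= 0):
        raise InconsistentDataError("apparent association constants must be positive")

    k_minus0, se_k_minus0 = _weighted_mean(B, se_B)
    if modality == "noncompetitive":
        k_plus0, se_k_plus0 = _weighted_mean(A, se_A)
    elif modality == "competitive":
        if Km is not None:
            if Km <= 0:
                raise InvalidInputError("Km must be positive")
            x = 1.0 + S / Km
            # least squares through the origin: 1/A = x / k+0
            inv_k = float(np.dot(x, 1.0 / A) / np.dot(x, x))
            k_plus0 = 1.0 / inv_k
            se_k_plus0 = math.nan
        else:
            if S.size < 2:
                raise InsufficientDesignError(
                    "competitive derivation without Km needs >= 2 substrate levels"
                )
            res = stats.linregress(S, 1.0 / A)
            if res.intercept <= 0 or res.slope <= 0:
                raise InconsistentDataError("1/A-vs-[S] line has non-positive coefficients")
            k_plus0 = 1.0 / res.intercept
            se_k_plus0 = float(res.intercept_stderr) * k_plus0**2
    else:
        raise InvalidInputError(f"cannot derive constants for modality {modality!r}")
    if k_plus0 <= 0 or k_minus0 <= 0:
        raise InconsistentDataError("derived rate constants must be positive")
    return MicroscopicConstants(
        k_plus0=float(k_plus0), k_minus0=float(k_minus0), modality=modality,
        se_k_plus0=se_k_plus0, se_k_minus0=se_k_minus0,
    )


@dataclass
class SlowBindingStudy:
    """Container for a full slow-binding study work-up."""

    curves: list[ProgressCurve]
    fits: list[SlowBindingCurveFit]
    regressions: dict[float, KobsRegression]
    evidence: ModalityEvidence | None
    constants: MicroscopicConstants | None


class SlowBindingAnalyzer(BaseEstimator):
    """End-to-end slow-binding inference on a set of progress curves.

    ``fit`` takes a list of :class:`ProgressCurve` spanning a grid of
    substrate and inhibitor levels, fits every trace, builds one
    kobs-vs-[I] regression per substrate level with >= 3 usable inhibitor
    levels, classifies the modality from the A/B trends (unless ``modality``
    is forced), and derives the microscopic constants.

    Parameters
    ----------
    Km : float or None
        Michaelis constant of the varied substrate, molar.  Required to pin
        k+0 in the competitive case when only one or two substrate levels
        are available; when given it constrains the 1/A-vs-[S] line.
    modality : str or None
        Force "competitive" or "noncompetitive" instead of classifying.
    alpha, equivalence_band : float
        Settings of the modality tests (see
        :func:`classify_slow_binding_modality`).

    Attributes (after fit)
    ----------------------
    fits_, regressions_, evidence_, modality_, constants_,
    k_plus0_, k_minus0_, Ki_
    """

    def __init__(self, Km: float | None = None, modality: str | None = None,
                 alpha: float = 0.05, equivalence_band: float = 0.20,
                 fit_alpha: float = 0.05):
        self.Km = Km
        self.modality = modality
        self.alpha = alpha
        self.equivalence_band = equivalence_band
        self.fit_alpha = fit_alpha

    def fit(self, curves: Sequence[ProgressCurve]):
        curves = list(curves)
        if not curves:
            raise InvalidInputError("no curves supplied")
        fits = [fit_progress_curve(c, alpha=self.fit_alpha) for c in curves]

        by_S: dict[float, list[tuple[float, float]]] = {}
        for c, f in zip(curves, fits):
            if c.I > 0 and f.converged and f.slow_binding and math.isfinite(f.kobs):
                by_S.setdefault(c.S, []).append((c.I, f.kobs))
        regressions: dict[float, KobsRegression] = {}
        for s, pts in by_S.items():
            I = [p[0] for p in pts]
            if len(set(I)) < 3:
                continue
            regressions[s] = regress_kobs_vs_inhibitor(I, [p[1] for p in pts], S=s)
        if not regressions:
            raise InsufficientDesignError(
                "no substrate level has >= 3 inhibitor levels with usable kobs fits"
            )

        evidence = classify_slow_binding_modality(
            regressions, alpha=self.alpha, equivalence_band=self.equivalence_band
        )
        modality = self.modality or evidence.modality
        constants = None
        if modality in ("competitive", "noncompetitive"):
            constants = derive_microscopic_constants(regressions, modality, Km=self.Km)

        self.fits_ = fits
        self.regressions_ = regressions
        self.evidence_ = evidence
        self.modality_ = modality
        self.constants_ = constants
        self.k_plus0_ = constants.k_plus0 if constants else math.nan
        self.k_minus0_ = constants.k_minus0 if constants else math.nan
        self.Ki_ = constants.Ki if constants else math.nan
        self.study_ = SlowBindingStudy(curves, fits, regressions, evidence, constants)
        return self
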