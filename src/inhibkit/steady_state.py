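"""Fast-binding (classical) inhibition analysis on initial-rate grids.

The primary fit is a global nonlinear least-squares fit of the untransformed
rates to each of the four Michaelis-Menten inhibition laws, selected by
AICc.  Double-reciprocal (Lineweaver-Burk) diagnostics are provided for the
classical plot-pattern reading — lines meeting on the 1/v axis (competitive),
on the 1/S axis (noncompetitive), or running parallel (uncompetitive) — but
are diagnostic only: transformed-space regression is biased under
proportional noise, so the nonlinear fit is the report of record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .errors import InsufficientDesignError, InvalidInputError
from .models import FAST_MODALITIES, mm_rate

_N_PARAMS = {"competitive": 3, "noncompetitive": 3, "uncompetitive": 3, "mixed": 4}


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("S", "I", "v"):
        if col not in table.columns:
            raise InvalidInputError(f"rate table must carry column {col!r}")
    t = table[["S", "I", "v"]].astype(float)
    if (t["S"] <= 0).any():
        raise InvalidInputError("substrate concentrations must be positive")
    if (t["v"] < 0).any() or (t["I"] < 0).any():
        raise InvalidInputError("rates and inhibitor concentrations must be >= 0")
    return t


def _rate(modality: str, S, I, theta):
    if modality == "mixed":
        return mm_rate(S, I, "mixed", Vmax=theta[0], Km=theta[1], Kic=theta[2], Kiu=theta[3])
    return mm_rate(S, I, modality, Vmax=theta[0], Km=theta[1], Ki=theta[2])


def _fit_one_model(modality: str, S, I, v, weights, max_nfev=2000):
    """Weighted least squares in log-parameter space (enforces positivity)."""
    vmax0 = float(np.max(v)) * 1.1 + 1e-300
    # Km seed: substrate level nearest half-max among the least-inhibited rows
    i_min = I == I.min()
    order = np.argsort(S[i_min])
    s_sorted, v_sorted = S[i_min][order], v[i_min][order]
    half = 0.5 * np.max(v_sorted)
    km0 = float(np.interp(half, v_sorted, s_sorted)) if v_sorted.size > 1 else float(np.median(S))
    km0 = max(km0, 1e-12)
    pos_I = I[I > 0]
    ki_med = float(np.median(pos_I)) if pos_I.size else 1e-6

    def residuals(logp):
        theta = np.exp(np.clip(logp, -230.0, 230.0))
        return (_rate(modality, S, I, theta) - v) / weights

    best = None
    for ki_fac in (0.1, 1.0, 10.0):
        ki0 = ki_med * ki_fac
        p0 = [vmax0, km0, ki0] + ([ki0] if modality == "mixed" else [])
        try:
            sol = optimize.least_squares(
                residuals, np.log(p0), max_nfev=max_nfev, ftol=1e-12, xtol=1e-12
            )
        except Exception:
            continue
        sse = float(2.0 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        return None
    sse, sol = best
    theta = np.exp(np.clip(sol.x, -230.0, 230.0))
    n, k = v.size, _N_PARAMS[modality]
    k_tot = k + 1  # +1 for the residual variance
    # Scale-aware floor keeps AICc finite and comparable on exact fits: any
    # model whose residuals are below 1e-12 of the data scale is "exact".
    res_scale = float(np.max(np.abs(v / weights))) or 1.0
    sse_f = max(sse, n * (1e-12 * res_scale) ** 2)
    aicc = n * math.log(sse_f / n) + 2 * k_tot
    if n - k_tot - 1 > 0:
        aicc += 2 * k_tot * (k_tot + 1) / (n - k_tot - 1)
    return {
        "modality": modality, "theta": theta, "sse": sse, "aicc": float(aicc),
        "n_params": k, "converged": bool(sol.status > 0),
    }


@dataclass
class ReciprocalDiagnostics:
    """Per-inhibitor-level Lineweaver-Burk lines and their convergence pattern.

    ``lines`` has one row per inhibitor level (slope and intercept of 1/v on
    1/S with standard errors); ``classification`` names the pattern whose
    characteristic quantity (1/v-axis intercept, 1/S-axis intercept, or
    slope) is most nearly common across levels; ``spreads`` holds the
    relative ranges of the three quantities.
    """

    lines: pd.DataFrame
    classification: str
    spreads: dict[str, float]
    n_dropped: int = 0


def reciprocal_diagnostics(table: pd.DataFrame, tol: float = 1e-6) -> ReciprocalDiagnostics:
    """Double-reciprocal plot diagnostics of an initial-rate table.

    Rows with v == 0 are dropped (counted in ``n_dropped``).  A pattern is
    called clear-cut when its relative spread is below ``tol``; otherwise
    the pattern is accepted when every level's value lies within two pooled
    standard errors of the mean, and the tightest qualifying pattern wins.
    """
    t = _validate_table(table)
    n_dropped = int((t["v"] == 0).sum())
    t = t[t["v"] > 0]
    rows = []
    for i_level, grp in t.groupby("I"):
        if grp["S"].nunique() < 2:
            continue
        res = stats.linregress(1.0 / grp["S"], 1.0 / grp["v"])
        rows.append({
            "I": float(i_level), "slope": float(res.slope),
            "intercept": float(res.intercept),
            "se_slope": float(res.stderr), "se_intercept": float(res.intercept_stderr),
            "r_squared": float(res.rvalue**2), "n": int(len(grp)),
        })
    if len(rows) < 2:
        raise InsufficientDesignError("need >= 2 inhibitor levels with >= 2 substrate levels")
    lines = pd.DataFrame(rows).sort_values("I").reset_index(drop=True)

    y_int = lines["intercept"].to_numpy()
    x_int = (-lines["intercept"] / lines["slope"]).to_numpy()
    slopes = lines["slope"].to_numpy()

    def rel_spread(vals):
        m = np.mean(vals)
        return float(np.ptp(vals) / abs(m)) if m != 0 else math.inf

    spreads = {
        "competitive": rel_spread(y_int),      # common 1/v-axis intercept
        "noncompetitive": rel_spread(x_int),   # common 1/S-axis intercept
        "uncompetitive": rel_spread(slopes),   # parallel lines
    }
    se_pool = {
        "competitive": float(np.sqrt(np.mean(lines["se_intercept"] ** 2))),
        "noncompetitive": math.nan,
        "uncompetitive": float(np.sqrt(np.mean(lines["se_slope"] ** 2))),
    }
    qualifying = []
    for name, vals in (("competitive", y_int), ("noncompetitive", x_int),
                       ("uncompetitive", slopes)):
        if spreads[name] < tol:
            qualifying.append(name)
            continue
        se = se_pool[name]
        if math.isfinite(se) and se > 0 and np.all(np.abs(vals - np.mean(vals)) <= 2 * se):
            qualifying.append(name)
    classification = min(qualifying, key=lambda nm: spreads[nm]) if qualifying else "undetermined"
    return ReciprocalDiagnostics(lines, classification, spreads, n_dropped)


class InhibitionKineticsFitter(BaseEstimator):
    """Global Michaelis-Menten inhibition fit with AICc model selection.

    ``fit(X, y)`` takes ``X`` of shape (n, 2) with columns ([S], [I]) in
    molar and ``y`` the initial rates.  With ``modality="auto"`` all four
    laws are fitted and selected by AICc; among models within ``tie_delta``
    of the best, the one with fewest parameters is preferred (the mixed law
    nests the other three), and a same-complexity tie is reported as
    "undetermined".

    Parameters
    ----------
    modality : str
        "auto" or one of the four law names.
    weighting : str
        "proportional" (weights 1/v, matching constant-CV noise; default) or
        "none".
    tie_delta : float
        AICc window of the parsimony/tie rule.

    Attributes (after fit)
    ----------------------
    modality_, Vmax_, Km_, Ki_ (or Kic_/Kiu_ for mixed), aicc_ (per-model
    dict), margin_ (AICc gap to the best non-nesting alternative),
    results_ (per-model details), apparent_ (per-[I] Km_app/Vmax_app table).
    """

    def __init__(self, modality: str = "auto", weighting: str = "proportional",
                 tie_delta: float = 2.0):
        self.modality = modality
        self.weighting = weighting
        self.tie_delta = tie_delta

    def _weights(self, v: np.ndarray) -> np.ndarray:
        if self.weighting == "proportional":
            return np.maximum(v, 1e-12 * np.max(v))
        if self.weighting == "none":
            return np.ones_like(v)
        raise InvalidInputError(f"unknown weighting {self.weighting!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2 or X.shape[0] != y.size:
            raise InvalidInputError("X must be (n, 2) with columns (S, I)")
        S, I = X[:, 0], X[:, 1]
        if np.unique(S).size < 3 or np.unique(I).size < 2:
            raise InsufficientDesignError("need >= 3 substrate and >= 2 inhibitor levels")
        w = self._weights(y)

        wanted = list(FAST_MODALITIES) if self.modality == "auto" else [self.modality]
        if any(m not in FAST_MODALITIES for m in wanted):
            raise InvalidInputError(f"unknown modality {self.modality!r}")
        results = {}
        for m in wanted:
            r = _fit_one_model(m, S, I, y, w)
            if r is not None:
                results[m] = r
        if not results:
            raise InvalidInputError("no inhibition model converged")
        self.results_ = results
        self.aicc_ = {m: r["aicc"] for m, r in results.items()}

        if self.modality == "auto":
            best_aicc = min(self.aicc_.values())
            window = [m for m, a in self.aicc_.items() if a - best_aicc < self.tie_delta]
            min_k = min(_N_PARAMS[m] for m in window)
            parsimonious = [m for m in window if _N_PARAMS[m] == min_k]
            selected = min(parsimonious, key=lambda m: self.aicc_[m])
            self.modality_ = selected if len(parsimonious) == 1 else "undetermined"
            # margin over the wrong models that do not nest the selected law
            others = [a for m, a in self.aicc_.items()
                      if m != selected and not (m == "mixed" and selected != "mixed")]
            self.margin_ = (min(others) - self.aicc_[selected]) if others else math.inf
        else:
            selected = wanted[0]
            self.modality_ = selected
            self.margin_ = math.nan
        self.selected_ = selected

        r = results[selected]
        self.Vmax_, self.Km_ = float(r["theta"][0]), float(r["theta"][1])
        if selected == "mixed":
            self.Kic_, self.Kiu_ = float(r["theta"][2]), float(r["theta"][3])
            self.Ki_ = self.Kic_
        else:
            self.Ki_ = float(r["theta"][2])
            self.Kic_ = self.Kiu_ = math.nan
        self.sse_ = r["sse"]
        self.converged_ = r["converged"]
        self.apparent_ = self._apparent(S, I, y, w)
        return self

    def _apparent(self, S, I, v, w) -> pd.DataFrame:
        """Unconstrained per-inhibitor-level MM fits -> (Km_app, Vmax_app)."""
        rows = []
        for i_level in np.unique(I):
            sel = I == i_level
            if np.unique(S[sel]).size < 3:
                continue
            Ss, vs_, ws = S[sel], v[sel], w[sel]

            def res_fn(logp):
                vmax, km = np.exp(logp)
                return (vmax * Ss / (km + Ss) - vs_) / ws

            p0 = np.log([np.max(vs_) * 1.1 + 1e-300, max(np.median(Ss), 1e-12)])
            try:
                sol = optimize.least_squares(res_fn, p0, ftol=1e-12, xtol=1e-12)
            except Exception:
                continue
            vmax_app, km_app = np.exp(sol.x)
            rows.append({"I": float(i_level), "Vmax_app": float(vmax_app),
                         "Km_app": float(km_app)})
        return pd.DataFrame(rows)

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        theta = self.results_[self.selected_]["theta"]
        return _rate(self.selected_, X[:, 0], X[:, 1], theta)


@dataclass
class SteadyStateFit:
    """Report of a steady-state inhibition analysis."""

    modality: str
    Vmax: float
    Km: float
    Ki: float
    Kic: float
    Kiu: float
    sse: float
    aicc: dict[str, float]
    margin: float
    apparent: pd.DataFrame
    converged: bool


def fit_inhibition_models(table: pd.DataFrame, modality: str = "auto",
                          weighting: str = "proportional") -> SteadyStateFit:
    """Globally fit an initial-rate table (columns S, I, v; molar, rate/s)."""
    t = _validate_table(table)
    est = InhibitionKineticsFitter(modality=modality, weighting=weighting)
    est.fit(t[["S", "I"]].to_numpy(), t["v"].to_numpy())
    return SteadyStateFit(
        modality=est.modality_, Vmax=est.Vmax_, Km=est.Km_, Ki=est.Ki_,
        Kic=est.Kic_, Kiu=est.Kiu_, sse=est.sse_, aicc=est.aicc_,
        margin=est.margin_, apparent=est.apparent_, converged=est.converged_,
    )


@dataclass
class ApparentTrend:
    """Linear trends of the apparent parameters in [I]."""

    km_slope: float
    km_intercept: float
    km_pvalue: float
    ki_from_trend: float
    vmax_slope_pvalue: float
    vmax_rel_range: float
    vmax_invariant: bool
    km_increases: bool


def apparent_parameter_trend(fit: SteadyStateFit, alpha: float = 0.05,
                             equivalence_band: float = 0.20) -> ApparentTrend:
    """Test the competitive signature on the apparent-parameter table.

    For a competitive inhibitor Km_app = Km*(1 + I/Ki) grows linearly in [I]
    while Vmax_app stays flat; the Km_app line's intercept/slope ratio gives
    an independent Ki estimate.
    """
    ap = fit.apparent
    if ap is None or len(ap) < 2:
        raise InsufficientDesignError("apparent parameters at >= 2 inhibitor levels required")
    res_km = stats.linregress(ap["I"], ap["Km_app"])
    res_vm = stats.linregress(ap["I"], ap["Vmax_app"])
    vmax_rel_range = float(np.ptp(ap["Vmax_app"]) / np.mean(ap["Vmax_app"]))
    ki = float(res_km.intercept / res_km.slope) if res_km.slope > 0 else math.nan
    km_p = float(res_km.pvalue) if len(ap) > 2 else (0.0 if res_km.slope > 0 else 1.0)
    vm_p = float(res_vm.pvalue) if len(ap) > 2 else 1.0
    return ApparentTrend(
        km_slope=float(res_km.slope), km_intercept=float(res_km.intercept),
        km_pvalue=km_p, ki_from_trend=ki,
        vmax_slope_pvalue=vm_p, vmax_rel_range=vmax_rel_range,
        vmax_invariant=(vm_p > alpha) and (vmax_rel_range < equivalence_band),
        km_increases=(res_km.slope > 0) and (km_p < alpha),
    )
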