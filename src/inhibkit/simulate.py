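"""Synthetic assay generator.

Emulates the two bc1-complex inhibition assay systems used throughout the
package — the succinate-cytochrome c reductase (SCR) system with cytochrome
c as the varied substrate, and the decylubiquinol (DBH2)-cytochrome c
system — under fast-binding (initial-rate grids) and one-step slow-binding
(progress-curve grids) mechanisms, with seeded Gaussian noise.

The default designs reproduce the published concentration grids:

* ``AZ_DBH2_DESIGN`` — DBH2 20-120 uM against azoxystrobin 0-5000 nM
  (fast competitive; truth Km = 80 uM, Ki = 394.7 nM);
* ``HIT_CYTC_DESIGN`` — cytochrome c 1.13-15.6 uM against the hit compound
  0-60 nM (fast noncompetitive; truth Km = 4.3 uM, Ki = 31.1 nM);
* ``LEAD_CYTC_SLOW_DESIGN`` — cytochrome c fixed at 60 uM, lead compound
  0-50 nM (slow-binding noncompetitive; truth k+0 = 0.00066 s^-1 nM^-1,
  k-0 = 0.00271 s^-1);
* ``LEAD_DBH2_SLOW_DESIGN`` — DBH2 20-120 uM with inhibitor titrations
  scaled to each substrate level (slow-binding competitive; truth
  k+0 = 0.00038 s^-1 nM^-1, k-0 = 0.00509 s^-1, Km = 80 uM).

Noise defaults: additive Gaussian with sigma = 2% of each curve's final
noiseless signal for progress traces; proportional 3% for rate tables.
Randomness comes from numpy's default PCG64 generator seeded from
``GeneratorSpec.seed``, so a fixed spec reproduces byte-identical data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .models import (
    AssayDesign,
    ProgressCurve,
    apparent_ki,
    kobs_law,
    linear_progress,
    mm_rate,
    slow_binding_progress,
)

FAST_MECHANISMS = ("fast-competitive", "fast-noncompetitive",
                   "fast-uncompetitive", "fast-mixed")
SLOW_MECHANISMS = ("slow-binding-competitive", "slow-binding-noncompetitive")

_uM = 1e-6
_nM = 1e-9


def _uM_grid(vals) -> tuple[float, ...]:
    return tuple(v * _uM for v in vals)


def _nM_grid(vals) -> tuple[float, ...]:
    return tuple(v * _nM for v in vals)


AZ_DBH2_DESIGN = AssayDesign(
    assay_id="DBH2-cytc", varied_substrate="DBH2",
    substrate_concs=_uM_grid([20, 40, 60, 80, 100, 120]),
    inhibitor_concs=_nM_grid([0, 500, 1000, 2000, 3000, 5000]),
)
AZ_DBH2_TRUTH = {"modality": "competitive", "Vmax": 1e-8, "Km": 80e-6, "Ki": 394.7e-9}

HIT_CYTC_DESIGN = AssayDesign(
    assay_id="SCR-cytc", varied_substrate="cytochrome c",
    substrate_concs=tuple(np.geomspace(1.13e-6, 15.6e-6, 6)),
    inhibitor_concs=_nM_grid([0, 10, 20, 40, 60]),
)
HIT_CYTC_TRUTH = {"modality": "noncompetitive", "Vmax": 1e-8, "Km": 4.3e-6, "Ki": 31.1e-9}

HIT_DBH2_DESIGN = AssayDesign(
    assay_id="DBH2-cytc", varied_substrate="DBH2",
    substrate_concs=_uM_grid([20, 40, 60, 80, 100, 120]),
    inhibitor_concs=_nM_grid([0, 50, 100, 200, 300, 500]),
)
HIT_DBH2_TRUTH = {"modality": "competitive", "Vmax": 1e-8, "Km": 80e-6, "Ki": 96.5e-9}

LEAD_CYTC_SLOW_DESIGN = AssayDesign(
    assay_id="SCR-cytc", varied_substrate="cytochrome c",
    substrate_concs=(60e-6,),
    inhibitor_concs=_nM_grid([0, 15, 20, 30, 40, 50]),
    duration=600.0, n_timepoints=60,
)
LEAD_CYTC_SLOW_TRUTH = {
    "modality": "noncompetitive",
    "k_plus0": 0.00066 / _nM,  # s^-1 M^-1
    "k_minus0": 0.00271,       # s^-1
    "v_scale": 1e-8, "Km": 4.3e-6,
}

# Inhibitor titrations are scaled with the substrate level (top level
# = S/uM + 60 nM, quarter spacing), matching the published endpoint grids
# {20,40,60,80} nM at 20 uM and {40,80,120,180} nM at 120 uM.
LEAD_DBH2_SLOW_DESIGN = AssayDesign(
    assay_id="DBH2-cytc", varied_substrate="DBH2",
    substrate_concs=_uM_grid([20, 40, 80, 120]),
    per_substrate_inhibitors=(
        _nM_grid([0, 20, 40, 60, 80]),
        _nM_grid([0, 25, 50, 75, 100]),
        _nM_grid([0, 35, 70, 105, 140]),
        _nM_grid([0, 40, 80, 120, 180]),
    ),
    duration=600.0, n_timepoints=60,
)
LEAD_DBH2_SLOW_TRUTH = {
    "modality": "competitive",
    "k_plus0": 0.00038 / _nM,
    "k_minus0": 0.00509,
    "v_scale": 1e-8, "Km": 80e-6,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Complete recipe for one synthetic dataset.

    ``truth`` holds the generative parameters: (Vmax, Km, Ki[, Kic, Kiu],
    modality) for fast mechanisms; (k_plus0 [s^-1 M^-1], k_minus0 [s^-1],
    v_scale, Km, modality) for slow-binding ones.  ``noise_model`` is
    "additive" (sigma x final signal, progress curves) or "proportional"
    (sigma x value, rate tables).
    """

    mechanism: str
    truth: dict[str, Any]
    design: AssayDesign
    noise_model: str = "additive"
    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in FAST_MECHANISMS + SLOW_MECHANISMS:
            raise InvalidInputError(f"unknown mechanism {self.mechanism!r}")
        if self.sigma < 0:
            raise InvalidInputError("sigma must be >= 0")
        if self.noise_model not in ("additive", "proportional"):
            raise InvalidInputError(f"unknown noise model {self.noise_model!r}")


def _manifest(spec: GeneratorSpec, extra: dict) -> dict:
    return {
        "mechanism": spec.mechanism,
        "truth": dict(spec.truth),
        "noise_model": spec.noise_model,
        "sigma": spec.sigma,
        "seed": spec.seed,
        "rng": "numpy default_rng (PCG64)",
        "assay_id": spec.design.assay_id,
        "varied_substrate": spec.design.varied_substrate,
        **extra,
    }


def generate_rate_table(spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Initial-rate grid under a fast-binding mechanism.

    Returns a tidy table (columns S, I, v in molar and rate/s, plus
    replicate) and a truth manifest.  Rates are the exact law value times
    (1 + eps) for proportional noise or plus eps*Vmax-scale for additive.
    """
    if spec.mechanism not in FAST_MECHANISMS:
        raise InvalidInputError(
            "slow-binding mechanisms generate curves; use generate_progress_curves"
        )
    modality = spec.mechanism.removeprefix("fast-")
    t = spec.truth
    rng = np.random.default_rng(spec.seed)
    rows = []
    for s, i in spec.design.grid():
        v = float(mm_rate(s, i, modality, Vmax=t["Vmax"], Km=t["Km"],
                          Ki=t.get("Ki"), Kic=t.get("Kic"), Kiu=t.get("Kiu")))
        if spec.sigma > 0:
            eps = rng.normal(0.0, spec.sigma)
            v = v * (1.0 + eps) if spec.noise_model == "proportional" \
                else v + eps * t["Vmax"]
        rows.append({"S": s, "I": i, "v": max(v, 0.0), "replicate": 0})
    table = pd.DataFrame(rows)
    return table, _manifest(spec, {"modality": modality, "n_rows": len(table)})


def generate_progress_curves(spec: GeneratorSpec) -> tuple[list[ProgressCurve], dict]:
    """Progress-curve grid under a one-step slow-binding mechanism.

    At each (S, I) grid point the noiseless backbone is the integrated
    slow-binding trace with v0 = v_scale*S/(Km+S) (the uninhibited rate),
    kobs from the slow-binding rate law, and vs = v0/(1 + I/Ki_app), where
    Ki_app = Ki*(1+S/Km) for the competitive mechanism.  Curves at I = 0
    are exactly linear.  Additive noise has sigma = ``spec.sigma`` times the
    curve's final noiseless signal.  The manifest records the per-curve
    true (v0, vs, kobs).
    """
    if spec.mechanism not in SLOW_MECHANISMS:
        raise InvalidInputError(
            "fast mechanisms generate rate tables; use generate_rate_table"
        )
    modality = spec.mechanism.removeprefix("slow-binding-")
    t = spec.truth
    k_plus0, k_minus0 = t["k_plus0"], t["k_minus0"]
    Ki = k_minus0 / k_plus0
    rng = np.random.default_rng(spec.seed)
    times = np.linspace(0.0, spec.design.duration, spec.design.n_timepoints)
    curves, truth_rows = [], []
    for s, i in spec.design.grid():
        v0 = t["v_scale"] * s / (t["Km"] + s)
        if i == 0:
            y = linear_progress(times, v0)
            vs, kobs = v0, float("nan")
        else:
            kobs = float(kobs_law(i, k_plus0, k_minus0, modality, S=s, Km=t.get("Km")))
            vs = v0 / (1.0 + i / apparent_ki(Ki, modality, S=s, Km=t.get("Km")))
            if kobs * spec.design.duration < 1.0:
                warnings.warn(
                    f"kobs*duration < 1 at S={s:.3g}, I={i:.3g}; "
                    "steady state not reached within the trace", stacklevel=2,
                )
            y = slow_binding_progress(times, v0, vs, kobs)
        if spec.sigma > 0:
            eps = rng.normal(0.0, 1.0, size=times.size)
            if spec.noise_model == "proportional":
                y = y + eps * spec.sigma * y
            else:
                y = y + eps * spec.sigma * abs(y[-1])
        label = f"S{s:.6g}_I{i:.6g}"
        curves.append(ProgressCurve(times=times.copy(), signal=y, S=s, I=i,
                                    assay_id=spec.design.assay_id, label=label))
        truth_rows.append({"label": label, "S": s, "I": i,
                           "v0": v0, "vs": vs, "kobs": kobs})
    return curves, _manifest(spec, {"modality": modality, "curves": truth_rows})
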