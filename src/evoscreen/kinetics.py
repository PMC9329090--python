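"""Microfermentation screen statistics and candidate selection.

The screen measures residual glucose and fructose (g l⁻¹) over time in
0.2 ml plate wells.  Fermentation performance is summarised bidimensionally
as the area under the residual-sugar curve (AUC, g·h l⁻¹): the GLU/FRU
ratio (glucose AUC over fructose AUC) measures fructophilicity — the closer
to 1, the smaller the kinetic gap between the two sugars — while the
overall-fermentation-performance (OFP) ratio compares an isolate's
total-sugar AUC to the in-plate parent's, values ≤ 1 meaning fermentation
at least as fast as the parent.  Candidates are selected on both criteria.

A shared two-substrate Monod forward model (:func:`model_curve`) generates
well curves for the synthetic plates: biomass grows on the sum of consumable
sugar, per-sugar uptake is Monod in that sugar, fructose uptake is scaled by
a preference factor in (0, 1], and both rates decay exponentially with
cumulative sugar consumed (an ethanol proxy), which can strand fructose in
strongly damped strains — a stuck fermentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StrainParams",
    "FermentationCurve",
    "ScreenRecord",
    "SelectionCriteria",
    "model_curve",
    "auc",
    "glu_fru_ratio",
    "ofp_ratio",
    "summarize_plates",
    "select_candidates",
    "screen_design",
    "read_plate_csv",
    "write_plate_csv",
]

ROLES = ("isolate", "parent", "MP", "sterile")


@dataclass(frozen=True)
class StrainParams:
    """Phenotype parameters of one strain for the forward fermentation model.

    Parameters
    ----------
    mu_max_glu, mu_max_fru
        Maximum specific consumption-linked growth rates on glucose and
        fructose (h⁻¹).
    ks_glu, ks_fru
        Monod half-saturation constants (g l⁻¹).
    yield_coeff
        Biomass formed per gram of sugar consumed (g g⁻¹).
    fructo_pref
        Fructose-preference scalar in (0, 1] multiplying the fructose uptake
        rate; 1 means glucose and fructose kinetics are identical
        (fructophilic), values < 1 encode glucophily.
    lag_h
        Lag before any growth or consumption (h).
    ethanol_sensitivity
        Exponential decay constant of both uptake rates with cumulative
        sugar consumed (l g⁻¹, the ethanol proxy); ≥ 0.
    """

    mu_max_glu: float = 0.12
    mu_max_fru: float = 0.12
    ks_glu: float = 2.0
    ks_fru: float = 2.0
    yield_coeff: float = 0.05
    fructo_pref: float = 0.65
    lag_h: float = 4.0
    ethanol_sensitivity: float = 0.03

    def __post_init__(self) -> None:
        for name in ("mu_max_glu", "mu_max_fru", "ks_glu", "ks_fru", "yield_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.fructo_pref <= 1:
            raise ValueError("fructo_pref must lie in (0, 1]")
        if self.lag_h < 0 or self.ethanol_sensitivity < 0:
            raise ValueError("lag_h and ethanol_sensitivity must be ≥ 0")


@dataclass
class FermentationCurve:
    """One well's residual glucose/fructose time course."""

    isolate: str
    plate: str
    well: str
    role: str
    times: np.ndarray  # hours, strictly increasing
    glucose: np.ndarray  # g/l
    fructose: np.ndarray  # g/l

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.fructose = np.asarray(self.fructose, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if not (len(self.times) == len(self.glucose) == len(self.fructose)):
            raise ValueError("times, glucose, fructose must have equal length")
        if len(self.times) < 2:
            raise ValueError("need at least 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.glucose < 0) or np.any(self.fructose < 0):
            raise ValueError("concentrations must be ≥ 0")

    @property
    def total(self) -> np.ndarray:
        return self.glucose + self.fructose


@dataclass
class ScreenRecord:
    """Per-isolate screen summary for one plate."""

    isolate: str
    plate: str
    auc_glu: float
    auc_fru: float
    auc_total: float
    glu_fru_ratio: float
    ofp_ratio: float
    parent_glu_fru_ratio: float
    selected: bool = False
    dry: bool = False


@dataclass(frozen=True)
class SelectionCriteria:
    """Two-criterion candidate selection rule.

    ``ofp_max`` keeps isolates fermenting at least as fast as the parent
    (OFP ≤ 1 by default); ``require_ratio_above_parent`` additionally demands
    a GLU/FRU ratio above the in-plate parent's.  ``shortlist_n`` optionally
    pre-trims to the top-N most fructophilic isolates before applying the
    two criteria.  ``dryness_threshold`` (g l⁻¹ total sugar at the final
    sample) marks completed fermentations.
    """

    ofp_max: float = 1.0
    require_ratio_above_parent: bool = True
    shortlist_n: int | None = None
    dryness_threshold: float = 2.5

    def __post_init__(self) -> None:
        if self.ofp_max <= 0:
            raise ValueError("ofp_max must be > 0")
        if self.dryness_threshold < 0:
            raise ValueError("dryness_threshold must be ≥ 0")


# ---------------------------------------------------------------------------
# forward model


def _rk4_segment(state, t0, t1, dt, deriv):
    """Integrate ``state`` from t0 to t1 with fixed-step classical RK4."""
    n_steps = max(1, int(round((t1 - t0) / dt)))
    h = (t1 - t0) / n_steps
    y = np.array(state, dtype=float)
    for _ in range(n_steps):
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * h * k1)
        k3 = deriv(y + 0.5 * h * k2)
        k4 = deriv(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def model_curve(
    params: StrainParams,
    glucose0: float,
    fructose0: float,
    t_grid: np.ndarray,
    x0: float = 0.05,
    dt: float = 0.05,
    isolate: str = "model",
    plate: str = "model",
    well: str = "A1",
    role: str = "isolate",
) -> FermentationCurve:
    """Integrate the two-substrate depletion model and sample it on ``t_grid``.

    State is (biomass X g l⁻¹, glucose G, fructose F).  With cumulative
    consumption E = (G₀−G) + (F₀−F) and damping d = exp(−k_e·E):

        v_g = μ_glu·G/(K_g+G)·d,   v_f = p_f·μ_fru·F/(K_f+F)·d
        dX/dt = (v_g+v_f)·X,  dG/dt = −v_g·X/Y,  dF/dt = −v_f·X/Y

    Nothing moves before ``lag_h``.  Both sugars are monotone non-increasing;
    Monod kinetics keep them non-negative without clipping.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with ≥ 2 points")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at or after 0")
    if glucose0 < 0 or fructose0 < 0:
        raise ValueError("initial sugars must be ≥ 0")

    p = params
    total0 = glucose0 + fructose0

    def deriv(y):
        X, G, F = y
        G = max(G, 0.0)
        F = max(F, 0.0)
        consumed = total0 - G - F
        damp = math.exp(-p.ethanol_sensitivity * consumed)
        v_g = p.mu_max_glu * G / (p.ks_glu + G) * damp
        v_f = p.fructo_pref * p.mu_max_fru * F / (p.ks_fru + F) * damp
        return np.array(
            [(v_g + v_f) * X, -v_g * X / p.yield_coeff, -v_f * X / p.yield_coeff]
        )

    glucose = np.empty_like(t_grid)
    fructose = np.empty_like(t_grid)
    state = np.array([x0, glucose0, fructose0])
    t_prev = p.lag_h
    for i, t in enumerate(t_grid):
        if t > t_prev:
            state = _rk4_segment(state, t_prev, t, dt, deriv)
            t_prev = t
        glucose[i] = max(state[1], 0.0)
        fructose[i] = max(state[2], 0.0)

    return FermentationCurve(
        isolate=isolate, plate=plate, well=well, role=role,
        times=t_grid, glucose=glucose, fructose=fructose,
    )


# ---------------------------------------------------------------------------
# screen statistics


def auc(times: np.ndarray, values: np.ndarray) -> float:
    """Composite trapezoidal area of residual concentration vs time.

    Exact for piecewise-linear inputs sampled at their breakpoints.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have equal length")
    if len(times) < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(values, times))


def glu_fru_ratio(curve: FermentationCurve) -> float:
    """GLU/FRU ratio: glucose AUC over fructose AUC on the shared grid."""
    a_fru = auc(curve.times, curve.fructose)
    if a_fru == 0:
        raise ZeroDivisionError("fructose AUC is zero; GLU/FRU ratio undefined")
    return auc(curve.times, curve.glucose) / a_fru


def _interp_curve(curve: FermentationCurve, grid: np.ndarray) -> FermentationCurve:
    return replace(
        curve,
        times=grid,
        glucose=np.interp(grid, curve.times, curve.glucose),
        fructose=np.interp(grid, curve.times, curve.fructose),
    )


def _common_grid(curves: list[FermentationCurve]) -> np.ndarray:
    """Union of time points restricted to the overlapping range."""
    lo = max(c.times[0] for c in curves)
    hi = min(c.times[-1] for c in curves)
    if hi <= lo:
        raise ValueError("curves share no overlapping time range")
    grid = np.unique(np.concatenate([c.times for c in curves]))
    return grid[(grid >= lo) & (grid <= hi)]


def ofp_ratio(isolate: FermentationCurve, parent: FermentationCurve) -> float:
    """Overall fermentation performance: total-sugar AUC vs in-plate parent.

    Values < 1 mean the isolate ferments faster than the parent.  Curves on
    mismatched grids are linearly interpolated onto the union grid over
    their overlapping range.
    """
    if isolate.plate != parent.plate:
        raise ValueError(
            f"parent curve is from plate {parent.plate!r}, isolate from {isolate.plate!r}"
        )
    if not np.array_equal(isolate.times, parent.times):
        grid = _common_grid([isolate, parent])
        isolate = _interp_curve(isolate, grid)
        parent = _interp_curve(parent, grid)
    a_parent = auc(parent.times, parent.total)
    if a_parent == 0:
        raise ZeroDivisionError("parent total-sugar AUC is zero; OFP undefined")
    return auc(isolate.times, isolate.total) / a_parent


def _mean_curve(curves: list[FermentationCurve]) -> FermentationCurve:
    """Pointwise replicate mean on the common grid."""
    grid = _common_grid(curves)
    interped = [_interp_curve(c, grid) for c in curves]
    return replace(
        interped[0],
        glucose=np.mean([c.glucose for c in interped], axis=0),
        fructose=np.mean([c.fructose for c in interped], axis=0),
    )


def summarize_plates(
    curves: list[FermentationCurve],
    criteria: SelectionCriteria | None = None,
) -> list[ScreenRecord]:
    """Reduce well curves to one :class:`ScreenRecord` per isolate per plate.

    Replicate wells are averaged pointwise on their common grid before any
    AUC is taken; sterile wells are dropped; every plate must contain exactly
    one parent identity.  Records are ordered by (plate, isolate); control
    rows (parent, mixed population) are not emitted — the parent enters each
    record through the OFP denominator and ``parent_glu_fru_ratio``.
    """
    criteria = criteria or SelectionCriteria()
    by_plate: dict[str, list[FermentationCurve]] = {}
    for c in curves:
        if c.role == "sterile":
            continue
        by_plate.setdefault(c.plate, []).append(c)

    records: list[ScreenRecord] = []
    for plate in sorted(by_plate):
        plate_curves = by_plate[plate]
        parents = sorted({c.isolate for c in plate_curves if c.role == "parent"})
        if len(parents) != 1:
            raise ValueError(
                f"plate {plate!r} must contain exactly one parent, found {parents}"
            )
        parent_mean = _mean_curve(
            [c for c in plate_curves if c.role == "parent"]
        )
        parent_ratio = glu_fru_ratio(parent_mean)
        isolate_ids = sorted(
            {c.isolate for c in plate_curves if c.role == "isolate"}
        )
        for iso in isolate_ids:
            mean = _mean_curve(
                [c for c in plate_curves if c.role == "isolate" and c.isolate == iso]
            )
            a_g = auc(mean.times, mean.glucose)
            a_f = auc(mean.times, mean.fructose)
            records.append(
                ScreenRecord(
                    isolate=iso,
                    plate=plate,
                    auc_glu=a_g,
                    auc_fru=a_f,
                    auc_total=a_g + a_f,
                    glu_fru_ratio=glu_fru_ratio(mean),
                    ofp_ratio=ofp_ratio(mean, parent_mean),
                    parent_glu_fru_ratio=parent_ratio,
                    dry=bool(mean.total[-1] < criteria.dryness_threshold),
                )
            )
    return records


def select_candidates(
    records: list[ScreenRecord],
    criteria: SelectionCriteria | None = None,
) -> list[ScreenRecord]:
    """Apply the two-criterion selection rule and return ordered candidates.

    An optional top-``shortlist_n`` cut on GLU/FRU ratio first, then keep
    isolates with OFP ≤ ``ofp_max`` and (if required) GLU/FRU above the
    in-plate parent's.  Output is ordered by descending GLU/FRU; ties break
    towards lower OFP, then isolate id.  Selected records get their
    ``selected`` flag set.
    """
    criteria = criteria or SelectionCriteria()
    key = lambda r: (-r.glu_fru_ratio, r.ofp_ratio, r.isolate)
    pool = sorted(records, key=key)
    if criteria.shortlist_n is not None:
        pool = pool[: criteria.shortlist_n]
    chosen = []
    for r in pool:
        if r.ofp_ratio > criteria.ofp_max:
            continue
        if criteria.require_ratio_above_parent and not (
            r.glu_fru_ratio > r.parent_glu_fru_ratio
        ):
            continue
        r.selected = True
        chosen.append(r)
    return chosen


def screen_design(
    n_populations: int = 7,
    isolates_per_population: int = 54,
    isolates_per_plate: int = 18,
) -> dict[str, int]:
    """Screen layout arithmetic: totals implied by the sampling design.

    Seven ~50-generation population samples of 54 single-colony isolates,
    screened 18 isolates per quadruplicated plate, give 378 isolates across
    21 plate screens.
    """
    if isolates_per_population % isolates_per_plate != 0:
        raise ValueError("isolates_per_population must divide into whole plates")
    plates_per_population = isolates_per_population // isolates_per_plate
    return {
        "n_populations": n_populations,
        "isolates_per_population": isolates_per_population,
        "isolates_per_plate": isolates_per_plate,
        "total_isolates": n_populations * isolates_per_population,
        "total_plates": n_populations * plates_per_population,
    }


# ---------------------------------------------------------------------------
# plate CSV I/O (long format: one row per well per time point)

PLATE_COLUMNS = ["plate", "well", "isolate", "role", "time_h", "glucose_gL", "fructose_gL"]


def write_plate_csv(curves: list[FermentationCurve], path: str | Path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "plate": c.plate,
                    "well": c.well,
                    "isolate": c.isolate,
                    "role": c.role,
                    "time_h": c.times,
                    "glucose_gL": c.glucose,
                    "fructose_gL": c.fructose,
                }
            )
        )
    pd.concat(frames, ignore_index=True)[PLATE_COLUMNS].to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> list[FermentationCurve]:
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    curves = []
    for (plate, well), grp in df.groupby(["plate", "well"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            FermentationCurve(
                isolate=str(grp["isolate"].iloc[0]),
                plate=str(plate),
                well=str(well),
                role=str(grp["role"].iloc[0]),
                times=grp["time_h"].to_numpy(),
                glucose=grp["glucose_gL"].to_numpy(),
                fructose=grp["fructose_gL"].to_numpy(),
            )
        )
    return curves
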