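"""Continuous-culture directed-evolution simulation and design arithmetic.

The evolution experiment runs a fructose-limited chemostat: a stirred vessel
of constant volume V fed at dilution rate D (h⁻¹) with medium carrying
fructose at S_f (g l⁻¹).  At steady state the specific growth rate equals D,
so generations accumulate as ∫D dt / ln 2, and the classical Monod closed
forms hold: residual sugar S* = Ks·D/(μ_max − D), biomass X* = Y·(S_f − S*).
The stepped dilution program of the experiment — 0.08 h⁻¹ ramped through
0.12, 0.14, 0.15, 0.18 to 0.2 h⁻¹ over 220 h, then held to 1278 h — yields
≈350 generations in ~53 days.

The simulator integrates per-genotype Monod growth with RK4 and accounts
cell divisions so the expected supply of adaptive mutants (at ~1 per 10¹¹
divisions) can be computed or realised as a thinned Poisson process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Phase",
    "DilutionSchedule",
    "ChemostatParams",
    "ChemostatTrajectory",
    "flow_rate",
    "generations",
    "sampling_plan",
    "simulate",
    "expected_mutants",
    "study_schedule",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Phase:
    start_time: float  # h
    dilution_rate: float  # h⁻¹
    feed_fructose: float  # g/l

    def __post_init__(self) -> None:
        if self.start_time < 0 or self.dilution_rate < 0 or self.feed_fructose < 0:
            raise ValueError("phase values must be ≥ 0")


@dataclass(frozen=True)
class DilutionSchedule:
    """Stepped (time, dilution rate, feed concentration) program."""

    phases: tuple[Phase, ...]
    volume: float  # l, constant
    end_time: float  # h

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        starts = [p.start_time for p in self.phases]
        if starts[0] != 0 or any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("phase start times must strictly increase from 0")
        if self.end_time <= starts[-1]:
            raise ValueError("end_time must exceed the last phase start")

    def segments(self) -> list[tuple[float, float, float, float]]:
        """(t_start, t_end, D, S_f) per phase."""
        out = []
        for i, p in enumerate(self.phases):
            t_end = (
                self.phases[i + 1].start_time
                if i + 1 < len(self.phases)
                else self.end_time
            )
            out.append((p.start_time, t_end, p.dilution_rate, p.feed_fructose))
        return out

    @classmethod
    def from_yaml(cls, path) -> "DilutionSchedule":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        phases = tuple(
            Phase(float(p["start_time"]), float(p["dilution_rate"]), float(p["feed_fructose"]))
            for p in cfg["phases"]
        )
        return cls(phases=phases, volume=float(cfg["volume"]), end_time=float(cfg["end_time"]))


def study_schedule(
    volume: float = 0.5,
    feed_fructose: float = 4.0,
    batch_hours: float = 24.0,
) -> DilutionSchedule:
    """The printed dilution program of the evolution experiment.

    A 24 h batch phase (D = 0), then continuous culture starting at
    0.08 h⁻¹, ramped through 0.12, 0.14, 0.15 and 0.18 h⁻¹ in equal-duration
    steps over 220 h to a final 0.2 h⁻¹ held until 1278 h of continuous
    culture.  Step durations within the ramp are equal by assumption — only
    the rate list and the 220 h total are reported.
    """
    ramp_rates = [0.08, 0.12, 0.14, 0.15, 0.18]
    step = 220.0 / len(ramp_rates)
    phases = [Phase(0.0, 0.0, feed_fructose)]
    for i, d in enumerate(ramp_rates):
        phases.append(Phase(batch_hours + i * step, d, feed_fructose))
    phases.append(Phase(batch_hours + 220.0, 0.2, feed_fructose))
    return DilutionSchedule(
        phases=tuple(phases), volume=volume, end_time=batch_hours + 1278.0
    )


@dataclass(frozen=True)
class ChemostatParams:
    """Monod growth parameters and mutation supply for the resident strain."""

    mu_max: float = 0.35  # h⁻¹
    Ks: float = 0.05  # g/l
    yield_coeff: float = 1.25e7  # cells ml⁻¹ per g l⁻¹ consumed
    initial_density: float = 1e5  # cells/ml
    initial_sugar: float = 4.0  # g/l
    adaptive_mutation_rate: float = 1e-11  # per cell division
    mutant_advantage: float = 0.0  # relative fitness increment
    initial_mutant_density: float = 0.0  # cells/ml, deterministic seeding at t0

    def __post_init__(self) -> None:
        if min(self.mu_max, self.Ks, self.yield_coeff, self.initial_density) <= 0:
            raise ValueError("mu_max, Ks, yield, initial_density must be > 0")
        if not 0 <= self.adaptive_mutation_rate <= 1:
            raise ValueError("adaptive_mutation_rate must lie in [0, 1]")
        if self.initial_sugar < 0 or self.mutant_advantage < 0:
            raise ValueError("initial_sugar and mutant_advantage must be ≥ 0")
        if self.initial_mutant_density < 0:
            raise ValueError("initial_mutant_density must be ≥ 0")


@dataclass
class ChemostatTrajectory:
    """Simulated chemostat state path with division/generation accounting."""

    times: np.ndarray  # h
    X: np.ndarray  # cells/ml, shape (n_times, n_genotypes); column 0 = resident
    S: np.ndarray  # residual fructose g/l
    cumulative_divisions: np.ndarray
    cumulative_generations: np.ndarray
    mutation_times: list[float] = field(default_factory=list)

    @property
    def total_divisions(self) -> float:
        return float(self.cumulative_divisions[-1])

    @property
    def mutant_frequency(self) -> np.ndarray:
        tot = self.X.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.X[:, 1:].sum(axis=1) / tot, 0.0)


def flow_rate(dilution_rate: float, volume: float) -> float:
    """Feed flow (l h⁻¹) implied by dilution rate (h⁻¹) and volume (l)."""
    if dilution_rate < 0 or volume <= 0:
        raise ValueError("need D ≥ 0 and V > 0")
    return dilution_rate * volume


def generations(schedule: DilutionSchedule) -> float:
    """Generations accumulated over the schedule: ∫D(t) dt / ln 2.

    At chemostat steady state the specific growth rate equals D, so the
    integral is piecewise-exact for a step schedule.  Batch phases (D = 0)
    contribute nothing.
    """
    total = sum((t1 - t0) * d for t0, t1, d, _ in schedule.segments())
    return total / LN2


def sampling_plan(total_generations: float, interval: float) -> list[float]:
    """Generation marks at interval, 2·interval, … ≤ total_generations."""
    if interval <= 0:
        raise ValueError("interval must be > 0")
    n = int(math.floor(total_generations / interval + 1e-12))
    return [interval * (i + 1) for i in range(n)]


def expected_mutants(trajectory: ChemostatTrajectory, rate: float) -> float:
    """Expected adaptive-mutant count: cumulative divisions × rate."""
    return trajectory.total_divisions * rate


def simulate(
    schedule: DilutionSchedule,
    params: ChemostatParams,
    dt: float = 0.01,
    stochastic_mutants: bool = False,
    seed: int | None = None,
    record_every: int = 10,
) -> ChemostatTrajectory:
    """Integrate the chemostat ODEs over the schedule.

    Two genotype classes are tracked: the resident and a single adaptive
    class with μ_max scaled by (1 + mutant_advantage).  Dynamics per class i:

        dX_i/dt = (μ_i(S) − D)·X_i,   μ_i = μ_max,i·S/(Ks + S)
        dS/dt   = D·(S_f − S) − Σ_i μ_i(S)·X_i / Y

    X is cells ml⁻¹ and Y cells ml⁻¹ per g l⁻¹, so X* = Y·(S_f − S*) holds in
    those volumetric units.  Divisions accumulate as ∫ Σμ_i X_i V·10³ dt
    (vessel total).  With ``stochastic_mutants`` adaptive genotypes arise as
    a thinned Poisson process on resident division increments at
    ``adaptive_mutation_rate``; each event seeds one cell into the vessel.

    ``record_every`` thins stored output; accounting always uses the fine step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    segs = schedule.segments()
    min_dur = min(t1 - t0 for t0, t1, _, _ in segs)
    if dt > min_dur:
        raise ValueError(f"dt={dt} exceeds shortest phase duration {min_dur}")
    max_mu = params.mu_max * (1.0 + params.mutant_advantage)
    max_d = max(d for _, _, d, _ in segs)
    if dt * (max_mu + max_d) > 0.5:
        raise ValueError(
            "dt too coarse for stability: require dt·(μ_max + D_max) ≤ 0.5; "
            "reduce dt"
        )
    rng = np.random.default_rng(seed)
    vessel_ml = schedule.volume * 1000.0

    mu_maxes = np.array([params.mu_max, max_mu])
    X = np.array([params.initial_density, params.initial_mutant_density])
    S = params.initial_sugar
    divisions = 0.0
    gens = 0.0

    times = [0.0]
    Xs = [X.copy()]
    Ss = [S]
    cum_div = [0.0]
    cum_gen = [0.0]
    mutation_times: list[float] = []

    def deriv(y, d_rate, s_feed):
        x = np.maximum(y[:-1], 0.0)
        s = max(y[-1], 0.0)
        mu = mu_maxes * s / (params.Ks + s)
        dx = (mu - d_rate) * x
        ds = d_rate * (s_feed - s) - float(mu @ x) / params.yield_coeff
        return np.append(dx, ds)

    step_count = 0
    for t0, t1, d_rate, s_feed in segs:
        n_steps = max(1, int(round((t1 - t0) / dt)))
        h = (t1 - t0) / n_steps
        t = t0
        for _ in range(n_steps):
            y = np.append(X, S)
            k1 = deriv(y, d_rate, s_feed)
            k2 = deriv(y + 0.5 * h * k1, d_rate, s_feed)
            k3 = deriv(y + 0.5 * h * k2, d_rate, s_feed)
            k4 = deriv(y + h * k3, d_rate, s_feed)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            X = np.maximum(y[:-1], 0.0)
            S = max(y[-1], 0.0)
            mu = mu_maxes * S / (params.Ks + S)
            div_inc = float(mu @ X) * vessel_ml * h
            divisions += div_inc
            pop = float(np.sum(X))
            if pop > 0:
                # population-mean growth rate; equals D at steady state
                gens += float(mu @ X) / pop * h / LN2
            if stochastic_mutants and X[1] == 0.0:
                resident_divs = mu[0] * X[0] * vessel_ml * h
                lam = resident_divs * params.adaptive_mutation_rate
                if lam > 0 and rng.poisson(lam) > 0:
                    X[1] = 1.0 / vessel_ml  # one founding cell
                    mutation_times.append(t + h)
            t += h
            step_count += 1
            if step_count % record_every == 0 or step_count == 1:
                times.append(t)
                Xs.append(X.copy())
                Ss.append(S)
                cum_div.append(divisions)
                cum_gen.append(gens)
    if times[-1] != t:
        times.append(t)
        Xs.append(X.copy())
        Ss.append(S)
        cum_div.append(divisions)
        cum_gen.append(gens)

    return ChemostatTrajectory(
        times=np.array(times),
        X=np.array(Xs),
        S=np.array(Ss),
        cumulative_divisions=np.array(cum_div),
        cumulative_generations=np.array(cum_gen),
        mutation_times=mutation_times,
    )
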