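"""Synthetic dilution-disturbance microcosm experiment.

Simulates replicated bacterial microcosms growing logistically toward a
carrying capacity while being diluted either continuously (chemostat-like,
"undisturbed", U) or by periodic pulse dilutions ("disturbed", D), in a
2 x 2 factorial crossover design (disturbance regime x carrying capacity,
regime switched mid-experiment), and emulates amplicon sequencing of the
communities by multinomial read sampling.

The per-taxon dynamic is a discrete-time logistic-with-washout skeleton

    n_i  <-  n_i * exp(step * [mu_i * (1 - N/K) - D])

with demographic drift injected by drawing the realised abundance from a
Poisson distribution with that mean, and pulse dilutions applied as
binomial survival with probability ``pulse_fraction``.  Equal growth rates
mu_i give a neutral community in which only drift changes composition;
dispersed mu_i are the selection mechanism.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import ValidationError, child_rng, logger

#: default per-day intrinsic growth rate (neutral communities)
DEFAULT_GROWTH_RATE = 2.5
#: default chemostat dilution rate for undisturbed periods, day^-1
DEFAULT_CONTINUOUS_DILUTION = 1.0
#: default pulse survival fraction (1:50 dilution)
DEFAULT_PULSE_FRACTION = 1.0 / 50.0
#: 17 sampling days spread over [2, 50], including the crossover day and the last day
DEFAULT_SAMPLING_DAYS = (2, 5, 8, 11, 14, 17, 20, 23, 26, 28, 32, 35, 38, 41, 44, 47, 50)
#: regime codes: period-1 disturbance, period-2 disturbance, capacity level
DEFAULT_REGIMES = ("UDH", "UDL", "DUH", "DUL")
#: default carrying capacity (individuals) of the low-nutrient regime
DEFAULT_K_LOW = 1e6

INOCULUM_REGIME = "inoculum"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonProfile:
    """One taxon: identity, intrinsic growth rate (day^-1), inoculum abundance,
    and an optional niche share.

    ``niche_share`` is the fraction of the carrying capacity this taxon can
    claim for itself.  When set (for every taxon of a community), part of the
    density limitation is taxon-specific, which turns the community
    composition into a stable attractor: perturbations decay instead of
    drifting.  This is the mechanism of homogeneous selection — replicates
    return to one shared equilibrium.  When None, all taxa compete for one
    shared capacity and composition is free to drift.
    """

    taxon_id: str
    growth_rate: float = DEFAULT_GROWTH_RATE
    initial_abundance: int = 0
    niche_share: float | None = None

    def __post_init__(self):
        if not self.growth_rate > 0:
            raise ValidationError(
                f"growth_rate must be > 0, got {self.growth_rate} for {self.taxon_id}"
            )
        if self.initial_abundance < 0:
            raise ValidationError(
                f"initial_abundance must be >= 0, got {self.initial_abundance}"
            )
        if self.niche_share is not None and not self.niche_share > 0:
            raise ValidationError(
                f"niche_share must be > 0 when set, got {self.niche_share}"
            )


@dataclass(frozen=True)
class RegimeSchedule:
    """Cultivation schedule for one regime code over the whole experiment.

    ``period_modes`` gives the disturbance mode per period: 'U' means
    continuous dilution at ``continuous_dilution_rate``; 'D' means pulse
    dilution by ``pulse_fraction`` every ``pulse_interval`` days (continuous
    dilution off).  Exactly one of the two mechanisms is active per period.
    """

    carrying_capacity: float
    period_modes: tuple[str, str] = ("U", "D")
    continuous_dilution_rate: float = DEFAULT_CONTINUOUS_DILUTION
    pulse_fraction: float = DEFAULT_PULSE_FRACTION
    pulse_interval: float = 2.0
    crossover_day: float = 28.0
    total_days: float = 50.0

    def __post_init__(self):
        if not 0 < self.pulse_fraction <= 1:
            raise ValidationError(f"pulse_fraction must be in (0, 1], got {self.pulse_fraction}")
        if self.continuous_dilution_rate < 0:
            raise ValidationError("continuous_dilution_rate must be >= 0")
        if self.carrying_capacity <= 0:
            raise ValidationError("carrying_capacity must be > 0")
        if self.pulse_interval <= 0:
            raise ValidationError("pulse_interval must be > 0")
        if not self.crossover_day < self.total_days:
            raise ValidationError("crossover_day must be < total_days")
        for m in self.period_modes:
            if m not in ("U", "D"):
                raise ValidationError(f"period mode must be 'U' or 'D', got {m!r}")

    @classmethod
    def from_regime_code(cls, code: str, *, k_low: float | None = None,
                         k_high: float | None = None, **kwargs) -> "RegimeSchedule":
        """Build a schedule from a code like 'UDH' (period-1, period-2, capacity)."""
        if len(code) != 3 or code[0] not in "UD" or code[1] not in "UD" or code[2] not in "HL":
            raise ValidationError(f"regime code must match [UD][UD][HL], got {code!r}")
        if k_low is None:
            k_low = DEFAULT_K_LOW
        if k_high is None:
            k_high = 5.0 * k_low
        capacity = k_high if code[2] == "H" else k_low
        return cls(carrying_capacity=capacity, period_modes=(code[0], code[1]), **kwargs)

    def mode_at(self, day: float) -> str:
        """Disturbance mode in force at a given day (period boundary belongs to period 1)."""
        return self.period_modes[0] if day <= self.crossover_day else self.period_modes[1]

    def pulse_times(self) -> np.ndarray:
        """All pulse-dilution times, excluding the instant a period starts."""
        times = []
        for start, end, mode in (
            (0.0, self.crossover_day, self.period_modes[0]),
            (self.crossover_day, self.total_days, self.period_modes[1]),
        ):
            if mode == "D":
                t = start + self.pulse_interval
                while t <= end + 1e-9:
                    times.append(round(t, 9))
                    t += self.pulse_interval
        return np.asarray(times)


@dataclass(frozen=True)
class ReadDepthModel:
    """Log-normal sequencing-depth distribution, truncated below."""

    mean: float = 63460.0
    sd: float = 31411.0
    minimum: int = 10000

    def draw(self, rng: np.random.Generator) -> int:
        # moment-match the log-normal, reject draws below the floor
        v = math.log1p((self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - v / 2.0
        for _ in range(10_000):
            d = rng.lognormal(mu, math.sqrt(v))
            if d >= self.minimum:
                return int(round(d))
        raise RuntimeError("read-depth rejection sampling failed; check depth parameters")


@dataclass(frozen=True)
class DesignSpec:
    """The sampling design: regimes x replicates x sampling days + inoculum samples."""

    regimes: tuple[str, ...] = DEFAULT_REGIMES
    replicates_per_regime: int = 3
    sampling_days: tuple[float, ...] = DEFAULT_SAMPLING_DAYS
    inoculum_samples: int = 2
    crossover_day: float = 28.0
    reads_per_sample: ReadDepthModel = field(default_factory=ReadDepthModel)

    def __post_init__(self):
        if not self.regimes:
            raise ValidationError("regimes: at least one regime code is required")
        if len(set(self.regimes)) != len(self.regimes):
            raise ValidationError("regimes: regime codes must be unique")
        days = np.asarray(self.sampling_days, dtype=float)
        if days.size == 0:
            raise ValidationError("sampling_days: at least one sampling day is required")
        if not np.all(np.diff(days) > 0):
            raise ValidationError("sampling_days: must be strictly increasing")
        if self.replicates_per_regime < 1:
            raise ValidationError("replicates_per_regime must be >= 1")
        if self.inoculum_samples < 0:
            raise ValidationError("inoculum_samples must be >= 0")


@dataclass
class AbundanceTrajectory:
    """Recorded per-step taxon abundances for one microcosm.

    At pulse times the recorded state is the one immediately *before* the
    pulse (samples are taken right before dilutions).
    """

    times: np.ndarray
    states: np.ndarray  # (n_times, n_taxa)
    microcosm_id: str

    def __post_init__(self):
        if len(self.times) != len(self.states):
            raise ValidationError("times and states lengths disagree")
        if np.any(np.asarray(self.states) < 0):
            raise ValidationError("abundances must be non-negative")

    def state_at(self, day: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.times - day)))
        if abs(self.times[idx] - day) > 1e-6:
            raise ValidationError(f"day {day} not on the recorded time grid")
        return self.states[idx]

    @property
    def total(self) -> np.ndarray:
        return self.states.sum(axis=1)


# ---------------------------------------------------------------------------
# design manifest
# ---------------------------------------------------------------------------

def build_design(spec: DesignSpec) -> pd.DataFrame:
    """Expand a design into a per-sample manifest.

    One row per (regime, replicate, sampling day) plus inoculum rows. Each row
    carries the disturbance mode in force at its day (first regime letter up
    to and including the crossover day, second letter after), capacity level,
    period, and a stable microcosm id.
    """
    rows = []
    for i in range(spec.inoculum_samples):
        rows.append({
            "sample_id": f"inoculum-{i + 1}",
            "microcosm_id": INOCULUM_REGIME,
            "regime_code": INOCULUM_REGIME,
            "disturbance_at_sampling": "",
            "capacity": "",
            "replicate": i + 1,
            "day": 0.0,
            "period": 0,
        })
    for code in spec.regimes:
        RegimeSchedule.from_regime_code(code)  # validates the code
        for rep, day in itertools.product(
            range(1, spec.replicates_per_regime + 1), spec.sampling_days
        ):
            period = 1 if day <= spec.crossover_day else 2
            rows.append({
                "sample_id": f"{code}-{rep}-d{int(day):02d}",
                "microcosm_id": f"{code}-{rep}",
                "regime_code": code,
                "disturbance_at_sampling": code[0] if period == 1 else code[1],
                "capacity": code[2],
                "replicate": rep,
                "day": float(day),
                "period": period,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# community construction
# ---------------------------------------------------------------------------

def _species_abundance(n_taxa: int, total: float, sad_sigma: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Log-normal rank-abundance vector scaled to a total community size."""
    raw = rng.lognormal(0.0, sad_sigma, size=n_taxa)
    scaled = np.maximum(1, np.round(raw / raw.sum() * total)).astype(np.int64)
    return scaled


def neutral_community(n_taxa: int = 400, total_abundance: float = DEFAULT_K_LOW,
                      growth_rate: float = DEFAULT_GROWTH_RATE,
                      sad_sigma: float = 2.0, seed: int = 0) -> list[TaxonProfile]:
    """Community of ecologically equivalent taxa (all mu_i equal): drift only."""
    rng = child_rng(seed, "community", "neutral")
    abund = _species_abundance(n_taxa, total_abundance, sad_sigma, rng)
    return [
        TaxonProfile(f"OTU_{i + 1:04d}", growth_rate, int(a))
        for i, a in enumerate(abund)
    ]


def selection_community(n_taxa: int = 400, total_abundance: float = DEFAULT_K_LOW,
                        growth_rate: float = DEFAULT_GROWTH_RATE,
                        growth_rate_cv: float = 0.2, sad_sigma: float = 2.0,
                        fitness_abundance_corr: float = 0.95,
                        seed: int = 0) -> list[TaxonProfile]:
    """Community with log-normally dispersed growth rates: fitness differences
    drive deterministic convergence of replicates (selection).

    ``fitness_abundance_corr`` rank-correlates growth rate with inoculum
    abundance: an inoculum drawn into a culture environment is already
    enriched for taxa pre-adapted to it, so the fittest taxa are rarely
    vanishing-rare.  Without this correlation the eventual winner is decided
    by which ultra-rare fast grower happens to survive the inoculation
    bottleneck — a lottery that makes replicate outcomes stochastic rather
    than selective.

    """
    if not 0 <= fitness_abundance_corr <= 1:
        raise ValidationError("fitness_abundance_corr must be in [0, 1]")
    rng = child_rng(seed, "community", "selection")
    abund = _species_abundance(n_taxa, total_abundance, sad_sigma, rng)
    sigma = math.sqrt(math.log1p(growth_rate_cv ** 2))
    # regular (quantile-spaced) log-normal fitness spectrum: the gaps between
    # the fastest growers are a design property of the scenario, not a random
    # draw, so the strength of selection is reproducible across seeds
    from scipy.stats import norm as _norm
    z = _norm.ppf((np.arange(n_taxa) + 0.5) / n_taxa)
    mu = np.exp(math.log(growth_rate) - sigma ** 2 / 2.0 + sigma * z)
    # pair the sorted growth rates with a noisy abundance score
    la = np.log(abund.astype(float))
    z = (la - la.mean()) / max(la.std(), 1e-12)
    score = fitness_abundance_corr * z + math.sqrt(1.0 - fitness_abundance_corr ** 2) \
        * rng.standard_normal(n_taxa)
    mu_assigned = np.empty(n_taxa)
    mu_assigned[np.argsort(-score)] = np.sort(mu)[::-1]
    return [
        TaxonProfile(f"OTU_{i + 1:04d}", float(m), int(a))
        for i, (m, a) in enumerate(zip(mu_assigned, abund))
    ]


def scenario_bloom_rate(scenario: str) -> float:
    """Default bloom-event rate per scenario.

    The two study scenarios are the extremes of the stochasticity-
    determinism axis: under neutrality (ecological equivalence) episodic
    fitness excursions — blooms and crashes — are part of the stochastic
    dynamics, whereas the strong-selection scenario represents a fixed
    deterministic fitness ordering, which such excursions would contradict.
    """
    return DEFAULT_BLOOM_RATE if scenario == "neutral" else 0.0


def default_schedules(regimes: tuple[str, ...] = DEFAULT_REGIMES, *,
                      k_low: float = DEFAULT_K_LOW, k_high: float | None = None,
                      **kwargs) -> dict[str, RegimeSchedule]:
    """One schedule per regime code with the standard K contrast (high = 5 x low)."""
    return {
        code: RegimeSchedule.from_regime_code(code, k_low=k_low, k_high=k_high, **kwargs)
        for code in regimes
    }


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def pulse_dilute(abundances: np.ndarray, fraction: float,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a pulse dilution: binomial survival per taxon (deterministic if rng None)."""
    if not 0 < fraction <= 1:
        raise ValidationError(f"pulse fraction must be in (0, 1], got {fraction}")
    if rng is None:
        return abundances * fraction
    return rng.binomial(np.asarray(abundances, dtype=np.int64), fraction)


#: default stationary SD (day^-1) of the slow environmental growth-rate fluctuation
DEFAULT_ENV_NOISE_SD = 0.02
#: default correlation time (days) of the slow environmental fluctuation
DEFAULT_ENV_NOISE_TAU = 14.0
#: default SD of the log-normal sampling overdispersion (transient blooms +
#: extra-multinomial noise of amplicon sequencing)
DEFAULT_OVERDISPERSION_SD = 0.6
#: default rate (per taxon per day) of persistent bloom/crash events
DEFAULT_BLOOM_RATE = 0.01
#: default weight of per-taxon self-limitation when niche shares are set
DEFAULT_NICHE_STRENGTH = 0.4
#: default SD of the log-normal abundance shock applied at a bloom event
DEFAULT_BLOOM_SD = 1.0


def simulate_microcosm(taxa: list[TaxonProfile], schedule: RegimeSchedule,
                       step: float = 0.05, seed: int = 0, drift: bool = True,
                       env_noise_sd: float = DEFAULT_ENV_NOISE_SD,
                       env_noise_tau: float = DEFAULT_ENV_NOISE_TAU,
                       bloom_rate: float = DEFAULT_BLOOM_RATE,
                       bloom_sd: float = DEFAULT_BLOOM_SD,
                       niche_strength: float = DEFAULT_NICHE_STRENGTH,
                       microcosm_id: str = "microcosm") -> AbundanceTrajectory:
    """Integrate one microcosm over the full schedule.

    Discrete-time update per taxon: deterministic skeleton
    ``n <- n * exp(step * (mu * (1 - N/K) - D))`` with, when ``drift`` is on,
    three stochastic components:

    * Poisson demographic noise — the realised abundance is drawn Poisson
      with the skeleton mean — which makes drift density-dependent;
    * slow environmental noise — each taxon's realised growth rate is
      perturbed by an independent Ornstein-Uhlenbeck process with
      stationary SD ``env_noise_sd`` (day^-1) and correlation time
      ``env_noise_tau`` (days), emulating persistent micro-environmental
      differences between replicate vessels; over windows shorter than a
      few correlation times it makes replicate pairs diverge roughly
      linearly in time;
    * episodic bloom/crash events — at rate ``bloom_rate`` per taxon per
      day a taxon's abundance is multiplied by a persistent log-normal
      shock with log-SD ``bloom_sd``, emulating the sudden outbreaks and
      collapses characteristic of bacterial community time series; their
      random timing makes between-replicate spread grow through the
      observation window rather than fan out smoothly.

    The multiplicative components reproduce the super-Poissonian,
    abundance-independent fluctuations of real community data; without
    them, between-replicate divergence self-averages over taxa and
    replicate trajectories are unrealistically synchronous.  Pulse
    survivors are binomial.  The recorded state at a pulse time is
    pre-pulse.  Transient day-scale fluctuations are additionally modelled
    at the sampling step (see :func:`sample_reads`).
    """
    if not taxa:
        raise ValidationError("taxa must be non-empty")
    n_pulse = schedule.pulse_interval / step
    if abs(n_pulse - round(n_pulse)) > 1e-9:
        raise ValidationError("step must divide pulse_interval")
    if step <= 0:
        raise ValidationError("step must be > 0")

    rng = child_rng(seed, microcosm_id, "dynamics")
    mu = np.array([t.growth_rate for t in taxa], dtype=float)
    n = np.array([t.initial_abundance for t in taxa], dtype=np.int64 if drift else float)
    K = schedule.carrying_capacity

    shares = [t.niche_share for t in taxa]
    if any(s is not None for s in shares):
        if any(s is None for s in shares):
            raise ValidationError("niche_share must be set for all taxa or none")
        a = np.array(shares, dtype=float)
        a = a / a.sum()
        if not 0 <= niche_strength <= 1:
            raise ValidationError("niche_strength must be in [0, 1]")
        w = niche_strength
    else:
        a, w = None, 0.0

    # inoculation dilution: disturbed-first microcosms start 1:50 diluted
    if schedule.period_modes[0] == "D":
        n = pulse_dilute(n, schedule.pulse_fraction, rng if drift else None)
        if not drift:
            n = n.astype(float)

    n_steps = int(round(schedule.total_days / step))
    times = np.arange(n_steps + 1) * step
    states = np.zeros((n_steps + 1, len(taxa)), dtype=np.int64 if drift else float)
    states[0] = n

    pulse_idx = {int(round(t / step)) for t in schedule.pulse_times()}
    env = np.zeros(len(taxa))
    if drift and env_noise_sd > 0:
        env = rng.normal(0.0, env_noise_sd, len(taxa))  # stationary start
    ou_decay = math.exp(-step / env_noise_tau)
    ou_innov = env_noise_sd * math.sqrt(1.0 - ou_decay ** 2)
    for i in range(1, n_steps + 1):
        t1 = i * step
        mode = schedule.mode_at(t1 - step / 2.0)  # mode of the elapsed interval
        dil = schedule.continuous_dilution_rate if mode == "U" else 0.0
        N = n.sum()
        if a is None:
            density = N / K
        else:
            # taxon-specific self-limitation + shared competition
            density = w * n / (a * K) + (1.0 - w) * N / K
        increment = step * (mu * (1.0 - density) - dil)
        if drift:
            if env_noise_sd > 0:
                env = ou_decay * env + ou_innov * rng.standard_normal(len(n))
                increment = increment + env * step
            if bloom_rate > 0:
                hit = rng.random(len(n)) < bloom_rate * step
                if hit.any():
                    increment = increment + hit * rng.normal(0.0, bloom_sd, len(n))
            n = rng.poisson(n * np.exp(increment))
        else:
            n = n * np.exp(increment)
        states[i] = n  # pre-pulse state is the recorded (sampled) one
        if i in pulse_idx:
            n = pulse_dilute(n, schedule.pulse_fraction, rng if drift else None)
    return AbundanceTrajectory(times=times, states=states, microcosm_id=microcosm_id)


def sample_reads(abundances: np.ndarray, depth: int,
                 rng: np.random.Generator | int = 0,
                 overdispersion_sd: float = 0.0) -> np.ndarray:
    """Emulate amplicon sequencing: multinomial draw of ``depth`` reads with
    probabilities proportional to abundances.

    ``overdispersion_sd`` > 0 adds log-normal overdispersion: each taxon's
    sampling probability is jittered by an independent factor
    ``exp(N(0, sd^2))`` before the draw.  This models the transient
    day-scale blooms and the extra-multinomial variation of real amplicon
    counts; it perturbs single samples without feeding back into the
    persistent community state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    abundances = np.asarray(abundances, dtype=float)
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    if overdispersion_sd < 0:
        raise ValidationError("overdispersion_sd must be >= 0")
    total = abundances.sum()
    if total <= 0:
        raise ValidationError("cannot sequence an extinct (all-zero) community")
    weights = abundances
    if overdispersion_sd > 0:
        weights = weights * np.exp(rng.normal(0.0, overdispersion_sd,
                                              size=abundances.shape))
    return rng.multinomial(int(depth), weights / weights.sum())


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def simulate_experiment(spec: DesignSpec, taxa: list[TaxonProfile],
                        schedules: dict[str, RegimeSchedule], seed: int = 0,
                        step: float = 0.05, drift: bool = True,
                        env_noise_sd: float = DEFAULT_ENV_NOISE_SD,
                        env_noise_tau: float = DEFAULT_ENV_NOISE_TAU,
                        bloom_rate: float = DEFAULT_BLOOM_RATE,
                        bloom_sd: float = DEFAULT_BLOOM_SD,
                        niche_strength: float = DEFAULT_NICHE_STRENGTH,
                        overdispersion_sd: float = DEFAULT_OVERDISPERSION_SD,
                        ) -> tuple["CountTable", pd.DataFrame]:
    """Run the full design: one trajectory per microcosm, one sequenced sample
    per manifest row.  Returns (count table as taxa x samples DataFrame wrapped
    by :class:`assemblage.counts.CountTable`, metadata aligned 1:1).
    """
    from .counts import CountTable  # local import to avoid a cycle

    missing = [c for c in spec.regimes if c not in schedules]
    if missing:
        raise ValidationError(f"no schedule supplied for regime code(s): {missing}")
    manifest = build_design(spec)
    taxon_ids = [t.taxon_id for t in taxa]
    init = np.array([t.initial_abundance for t in taxa], dtype=np.int64)

    trajectories: dict[str, AbundanceTrajectory] = {}
    for code in spec.regimes:
        for rep in range(1, spec.replicates_per_regime + 1):
            mid = f"{code}-{rep}"
            trajectories[mid] = simulate_microcosm(
                taxa, schedules[code], step=step, seed=seed, drift=drift,
                env_noise_sd=env_noise_sd, env_noise_tau=env_noise_tau,
                bloom_rate=bloom_rate, bloom_sd=bloom_sd,
                niche_strength=niche_strength, microcosm_id=mid,
            )

    columns = {}
    for row in manifest.itertuples():
        depth_rng = child_rng(seed, row.microcosm_id, row.day, "depth")
        read_rng = child_rng(seed, row.microcosm_id, row.day, "reads")
        depth = spec.reads_per_sample.draw(depth_rng)
        if row.regime_code == INOCULUM_REGIME:
            abund = init
        else:
            abund = trajectories[row.microcosm_id].state_at(row.day)
        if abund.sum() <= 0:
            logger.warning("microcosm %s extinct at day %s; emitting zero counts",
                           row.microcosm_id, row.day)
            columns[row.sample_id] = np.zeros(len(taxa), dtype=np.int64)
        else:
            od = overdispersion_sd if drift else 0.0
            columns[row.sample_id] = sample_reads(abund, depth, read_rng,
                                                  overdispersion_sd=od)

    counts = pd.DataFrame(columns, index=pd.Index(taxon_ids, name="OTU_ID"))
    return CountTable(counts), manifest


__all__ = [
    "TaxonProfile", "RegimeSchedule", "DesignSpec", "AbundanceTrajectory",
    "ReadDepthModel", "build_design", "simulate_microcosm", "sample_reads",
    "simulate_experiment", "pulse_dilute", "neutral_community", "scenario_bloom_rate", "DEFAULT_ENV_NOISE_SD", "DEFAULT_ENV_NOISE_TAU", "DEFAULT_OVERDISPERSION_SD", "DEFAULT_BLOOM_RATE", "DEFAULT_BLOOM_SD", "DEFAULT_NICHE_STRENGTH",
    "selection_community", "default_schedules", "DEFAULT_SAMPLING_DAYS",
    "DEFAULT_REGIMES", "DEFAULT_K_LOW", "INOCULUM_REGIME",
]
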