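"""Zero-state Monte Carlo run-length engine and run-length metrics.

No closed-form or Markov-chain run-length expressions exist for these
nonparametric charts, so run lengths are estimated by simulation.  Each
replication draws ONE fresh reference sample, holds it fixed, streams
independent (possibly shifted) test subgroups against it, updates the
chart from its zero state and records the first sampling time at which
the statistic plots beyond the time-varying limits.  The shared
reference sample induces serial dependence among the W statistics of a
replication; that dependence is intrinsic to the scheme's design and is
deliberately retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .charts import (
    ChartSpec,
    ChartState,
    Scheme,
    cusum_path,
    statistic_path,
    variance_factors,
)
from .rankstat import rank_sums_against_reference, w_moments
from .synthetic import ProcessModel, draw_subgroup_block, family_sigma

__all__ = [
    "SimulationConfig",
    "RunLengthSummary",
    "ShiftGridSummary",
    "simulate_one_run",
    "estimate_run_length",
    "shift_profile",
]

_PCTS = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one run-length estimate.

    ``delta`` is the sustained location shift in units of the family's
    population standard deviation; 0 means in control.  The cap
    ``max_run_length`` (default 100000, i.e. 200x the nominal in-control
    ARL of 500) censors pathological runs; censored replications are
    counted at the cap and reported, never dropped.
    """

    distribution: str = "normal"
    m: int = 100
    n: int = 5
    delta: float = 0.0
    replications: int = 10_000
    max_run_length: int = 100_000
    seed: int | None = None

    def __post_init__(self):
        family_sigma(self.distribution)
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.max_run_length < 1:
            raise ValueError("max_run_length must be >= 1")


@dataclass(frozen=True)
class RunLengthSummary:
    arl: float
    sdrl: float
    percentiles: dict[int, float]
    n_censored: int
    replications: int
    mc_se: float
    delta: float = 0.0
    warnings: tuple[str, ...] = ()
    run_lengths: np.ndarray | None = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class ShiftGridSummary:
    """Per-shift summaries over a (delta_min, delta_max] grid plus their means.

    ``earl``/``esdrl`` are the arithmetic means of the per-shift ARL and
    SDRL values; ``n_increments`` is the number of grid points.
    """

    grid: tuple[float, ...]
    summaries: tuple[RunLengthSummary, ...]
    earl: float
    esdrl: float
    n_increments: int


class _FactorCache:
    """Grow-on-demand half-width array for one chart spec."""

    def __init__(self, spec: ChartSpec, sigma_w: float):
        self.spec = spec
        self.sigma_w = sigma_w
        self.half = np.empty(0)

    def halfwidths(self, t_stop: int) -> np.ndarray:
        """Half-widths for t = 1..t_stop (index t-1)."""
        if t_stop > self.half.size:
            size = max(4096, 2 * self.half.size, t_stop)
            f = variance_factors(self.spec, size)
            self.half = self.spec.limit_constant * self.sigma_w * np.sqrt(f)
        return self.half


def _one_run(
    spec: ChartSpec,
    model: ProcessModel,
    m: int,
    n: int,
    delta: float,
    cap: int,
    rng: np.random.Generator,
    factors: _FactorCache,
    mu_w: float,
    moments,
) -> tuple[int, bool]:
    ref = np.sort(draw_subgroup_block(model, (1, m), 0.0, rng)[0])
    state = ChartState(mu_w=mu_w)
    block = 512
    while state.t < cap:
        b = min(block, cap - state.t)
        sub = draw_subgroup_block(model, (b, n), delta, rng)
        w = rank_sums_against_reference(ref, sub)
        t0 = state.t
        if spec.scheme is Scheme.CUSUM:
            cp, cn, state = cusum_path(spec, moments, w, state)
            h = spec.limit_constant * moments.sigma_w
            hit = np.flatnonzero((cp > h) | (cn > h))
        else:
            stats, state = statistic_path(spec, mu_w, w, state)
            half = factors.halfwidths(t0 + b)[t0 : t0 + b]
            hit = np.flatnonzero(np.abs(stats - mu_w) > half)
        if hit.size:
            return t0 + int(hit[0]) + 1, False
        block = min(4 * block, 8192)
    return cap, True


def simulate_one_run(
    spec: ChartSpec, config: SimulationConfig, rng: np.random.Generator
) -> int:
    """Run length of a single zero-state replication.

    Returns the first sampling time with a signal, or
    ``config.max_run_length`` if the run was censored at the cap.
    """
    moments = w_moments(config.m, config.n)
    model = ProcessModel(family=config.distribution)
    cache = _FactorCache(spec, moments.sigma_w)
    rl, _ = _one_run(
        spec,
        model,
        config.m,
        config.n,
        config.delta,
        config.max_run_length,
        rng,
        cache,
        moments.mu_w,
        moments,
    )
    return rl


def estimate_run_length(
    spec: ChartSpec,
    config: SimulationConfig,
    *,
    keep_run_lengths: bool = False,
) -> RunLengthSummary:
    """Replicate the zero-state run and summarise the run-length sample.

    Each replication uses an independent child stream spawned from the
    seed, so the study is reproducible from a single integer and the
    replications are statistically independent.
    """
    moments = w_moments(config.m, config.n)
    model = ProcessModel(family=config.distribution)
    cache = _FactorCache(spec, moments.sigma_w)
    ss = np.random.SeedSequence(config.seed)
    rls = np.empty(config.replications, dtype=np.int64)
    censored = 0
    for i, child in enumerate(ss.spawn(config.replications)):
        rng = np.random.Generator(np.random.PCG64(child))
        rl, cens = _one_run(
            spec,
            model,
            config.m,
            config.n,
            config.delta,
            config.max_run_length,
            rng,
            cache,
            moments.mu_w,
            moments,
        )
        rls[i] = rl
        censored += cens
    arl = float(np.mean(rls))
    sdrl = float(np.std(rls, ddof=1)) if config.replications > 1 else 0.0
    notes: list[str] = []
    if censored > 0.01 * config.replications:
        msg = (
            f"{censored}/{config.replications} runs censored at the cap "
            f"{config.max_run_length}; ARL/SDRL are biased low"
        )
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)
    pct = {p: float(np.percentile(rls, p)) for p in _PCTS}
    return RunLengthSummary(
        arl=arl,
        sdrl=sdrl,
        percentiles=pct,
        n_censored=int(censored),
        replications=config.replications,
        mc_se=sdrl / np.sqrt(config.replications),
        delta=config.delta,
        warnings=tuple(notes),
        run_lengths=rls if keep_run_lengths else None,
    )


def shift_profile(
    spec: ChartSpec,
    base_config: SimulationConfig,
    delta_min: float,
    delta_max: float,
    step: float = 0.1,
) -> ShiftGridSummary:
    """Run-length summaries over the open-left shift grid (delta_min, delta_max].

    The expected ARL (EARL) and expected SDRL (ESDRL) are the means of
    the per-shift values over the grid — the overall performance measure
    for a shift range.
    """
    if not (step > 0 and delta_min < delta_max):
        raise ValueError("need delta_min < delta_max and step > 0")
    k = int(round((delta_max - delta_min) / step))
    grid = tuple(round(delta_min + j * step, 10) for j in range(1, k + 1))
    if not grid:
        raise ValueError("shift grid is empty")
    children = np.random.SeedSequence(base_config.seed).spawn(len(grid))
    summaries = []
    for delta, child in zip(grid, children):
        cfg = SimulationConfig(
            distribution=base_config.distribution,
            m=base_config.m,
            n=base_config.n,
            delta=delta,
            replications=base_config.replications,
            max_run_length=base_config.max_run_length,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        summaries.append(estimate_run_length(spec, cfg))
    earl = float(np.mean([s.arl for s in summaries]))
    esdrl = float(np.mean([s.sdrl for s in summaries]))
    return ShiftGridSummary(
        grid=grid,
        summaries=tuple(summaries),
        earl=earl,
        esdrl=esdrl,
        n_increments=len(grid),
    )
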