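"""Model/results interface for rank-sum monitoring of a data stream.

`WilcoxonChart` is built from a phase-I reference sample and a sequence
of phase-II test subgroups; `fit()` runs the requested scheme over the
subgroups and returns a `WilcoxonChartResults` carrying the charting
statistics, time-varying control limits, signal flags and a summary
table in the layout practitioners tabulate (subgroup, statistic, LCL,
UCL, out-of-control flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .charts import (
    ChartSpec,
    ChartState,
    Scheme,
    cusum_path,
    statistic_path,
    variance_factors,
)
from .rankstat import WMoments, w_moments, wilcoxon_rank_sum
from .runlength import (
    RunLengthSummary,
    ShiftGridSummary,
    SimulationConfig,
    estimate_run_length,
    shift_profile,
)

__all__ = ["WilcoxonChart", "WilcoxonChartResults"]


class WilcoxonChart:
    """Distribution-free monitoring of test subgroups against a reference.

    Parameters
    ----------
    phase2 : array-like, shape (T, n)
        Phase-II test subgroups, one per row, all of common size ``n``.
    phase1 : array-like, shape (m,)
        Phase-I reference sample establishing in-control behaviour.
    scheme : str or Scheme
        ``hwma`` (default), ``dhwma``, ``hhwma``, ``ewma``, ``dewma``
        or ``cusum``.
    lambda1, lambda2, limit_constant, cusum_reference :
        Chart design parameters; see :class:`~rankcharts.charts.ChartSpec`.

    Examples
    --------
    >>> chart = WilcoxonChart(phase2, phase1, scheme="hhwma",
    ...                       lambda1=0.75, lambda2=0.5, limit_constant=2.1171)
    >>> res = chart.fit()
    >>> res.first_signal
    """

    def __init__(
        self,
        phase2,
        phase1,
        scheme: str | Scheme = Scheme.HWMA,
        *,
        lambda1: float = 0.5,
        lambda2: float | None = None,
        limit_constant: float = 3.0,
        cusum_reference: float | None = None,
    ):
        phase1 = np.asarray(phase1, dtype=float).ravel()
        phase2 = np.atleast_2d(np.asarray(phase2, dtype=float))
        if phase1.size < 2:
            raise ValueError("phase-I reference sample needs at least 2 values")
        if phase2.size == 0:
            raise ValueError("phase-II data are empty")
        if not (np.all(np.isfinite(phase1)) and np.all(np.isfinite(phase2))):
            raise ValueError("inputs must be finite")
        self.phase1 = phase1
        self.phase2 = phase2
        self.spec = ChartSpec(
            scheme=scheme,
            lambda1=lambda1,
            lambda2=lambda2,
            limit_constant=limit_constant,
            cusum_reference=cusum_reference,
        )
        self.moments: WMoments = w_moments(phase1.size, phase2.shape[1])

    @classmethod
    def from_dataframe(
        cls, phase2: pd.DataFrame, phase1, scheme="hwma", **kwargs
    ) -> "WilcoxonChart":
        """Build from a wide DataFrame (one subgroup per row).

        A leading ``subgroup`` index column, if present, is dropped.
        """
        df = phase2.copy()
        if "subgroup" in df.columns:
            df = df.drop(columns="subgroup")
        return cls(df.to_numpy(dtype=float), phase1, scheme=scheme, **kwargs)

    def rank_sums(self) -> np.ndarray:
        """Wilcoxon rank sum of each subgroup against the fixed reference."""
        return np.array(
            [wilcoxon_rank_sum(self.phase1, row) for row in self.phase2]
        )

    def fit(self) -> "WilcoxonChartResults":
        """Run the scheme over all subgroups and assemble the results."""
        w = self.rank_sums()
        tmax = w.size
        mo = self.moments
        state = ChartState(mu_w=mo.mu_w)
        if self.spec.scheme is Scheme.CUSUM:
            cp, cn, _ = cusum_path(self.spec, mo, w, state)
            h = self.spec.limit_constant * mo.sigma_w
            stats = np.maximum(cp, cn)
            signals = (cp > h) | (cn > h)
            lcl = np.full(tmax, np.nan)
            ucl = np.full(tmax, h)
        else:
            stats, _ = statistic_path(self.spec, mo.mu_w, w, state)
            half = self.spec.limit_constant * mo.sigma_w * np.sqrt(
                variance_factors(self.spec, tmax)
            )
            lcl, ucl = mo.mu_w - half, mo.mu_w + half
            signals = (stats > ucl) | (stats < lcl)
        return WilcoxonChartResults(
            model=self, w=w, statistics=stats, lcl=lcl, ucl=ucl, signals=signals
        )

    def simulate_run_length(
        self,
        delta: float = 0.0,
        distribution: str = "normal",
        replications: int = 10_000,
        seed: int | None = None,
        max_run_length: int = 100_000,
    ) -> RunLengthSummary:
        """Zero-state Monte Carlo run-length summary for this design.

        Uses the model's (m, n) and chart spec; data are synthetic draws
        from the named family, not the observed phases.
        """
        cfg = SimulationConfig(
            distribution=distribution,
            m=self.moments.m,
            n=self.moments.n,
            delta=delta,
            replications=replications,
            max_run_length=max_run_length,
            seed=seed,
        )
        return estimate_run_length(self.spec, cfg)

    def shift_profile(
        self,
        delta_min: float,
        delta_max: float,
        step: float = 0.1,
        **sim_kwargs,
    ) -> ShiftGridSummary:
        """EARL/ESDRL over a shift grid for this design (see runlength)."""
        cfg = SimulationConfig(
            m=self.moments.m,
            n=self.moments.n,
            **sim_kwargs,
        )
        return shift_profile(self.spec, cfg, delta_min, delta_max, step)


@dataclass
class WilcoxonChartResults:
    """Fitted monitoring sequence: statistics, limits and signals."""

    model: WilcoxonChart
    w: np.ndarray
    statistics: np.ndarray
    lcl: np.ndarray
    ucl: np.ndarray
    signals: np.ndarray
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def first_signal(self) -> int | None:
        """Smallest sampling time with a signal (1-based), or None."""
        idx = np.flatnonzero(self.signals)
        return int(idx[0]) + 1 if idx.size else None

    def to_frame(self) -> pd.DataFrame:
        if self._frame is None:
            self._frame = pd.DataFrame(
                {
                    "t": np.arange(1, self.w.size + 1),
                    "w": self.w,
                    "statistic": self.statistics,
                    "lcl": self.lcl,
                    "ucl": self.ucl,
                    "signal": self.signals,
                }
            )
        return self._frame

    def summary(self) -> str:
        """Plain-text monitoring report (2-decimal display rounding)."""
        mo = self.model.moments
        spec = self.model.spec
        lam = f"lambda1={spec.lambda1}"
        if spec.lambda2 is not None:
            lam += f", lambda2={spec.lambda2}"
        head = [
            f"{spec.scheme.value.upper()}-W monitoring scheme",
            f"m = {mo.m}, n = {mo.n}, mu_W = {mo.mu_w:g}, sigma_W = {mo.sigma_w:.4f}",
            f"{lam}, L = {spec.limit_constant}",
            f"subgroups: {self.w.size}, signals: {int(self.signals.sum())}, "
            f"first signal: {self.first_signal}",
            "",
        ]
        df = self.to_frame().copy()
        for c in ("w", "statistic", "lcl", "ucl"):
            df[c] = df[c].map(lambda x: f"{x:.2f}")
        df["signal"] = np.where(self.signals, "Yes", "No")
        return "\n".join(head) + df.to_string(index=False)

    def plot(self, ax=None):
        """Statistic versus time-varying limits; signals highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        t = np.arange(1, self.w.size + 1)
        ax.plot(t, self.statistics, marker="o", ms=3, lw=1, label="statistic")
        if np.all(np.isfinite(self.lcl)):
            ax.plot(t, self.lcl, "r--", lw=1, label="LCL/UCL")
        ax.plot(t, self.ucl, "r--", lw=1)
        ax.axhline(self.model.moments.mu_w, color="grey", lw=0.8)
        if self.signals.any():
            ax.plot(
                t[self.signals],
                self.statistics[self.signals],
                "rx",
                ms=8,
                label="signal",
            )
        ax.set_xlabel("subgroup")
        ax.set_ylabel("charting statistic")
        ax.set_title(f"{self.model.spec.scheme.value.upper()}-W scheme")
        ax.legend(loc="best", fontsize=8)
        return ax
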