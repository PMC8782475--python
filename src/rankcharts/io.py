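"""File I/O and multi-scheme monitoring reports.

Data conventions: phase I is a single-column CSV of reference values;
phase II is wide CSV, one subgroup per row (optional leading
``subgroup`` column, observation columns ``obs1..obsn``), or long CSV
with ``subgroup``/``value`` columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .charts import ChartSpec
from .model import WilcoxonChart, WilcoxonChartResults
from .rankstat import WMoments, w_moments

__all__ = [
    "read_phase1",
    "read_phase2",
    "MonitoringReport",
    "run_monitoring",
]


def read_phase1(path: str | Path) -> np.ndarray:
    """Read the reference sample from a single-column CSV."""
    df = pd.read_csv(path)
    if df.shape[1] != 1:
        raise ValueError(
            f"{path}: phase-I file must have exactly one column, found {df.shape[1]}"
        )
    values = df.iloc[:, 0].to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError(f"{path}: phase-I file is empty")
    return values


def read_phase2(path: str | Path, long: bool = False) -> np.ndarray:
    """Read phase-II subgroups; returns an array of shape (T, n).

    Wide layout by default; ``long=True`` accepts subgroup/value rows.
    Ragged subgroups raise a format error naming the offending row.
    """
    df = pd.read_csv(path)
    if long:
        if not {"subgroup", "value"}.issubset(df.columns):
            raise ValueError(f"{path}: long layout needs 'subgroup' and 'value' columns")
        sizes = df.groupby("subgroup").size()
        if sizes.nunique() != 1:
            bad = sizes[sizes != sizes.iloc[0]].index.tolist()
            raise ValueError(f"{path}: ragged subgroups {bad}")
        return (
            df.sort_values("subgroup")
            .groupby("subgroup")["value"]
            .apply(np.asarray)
            .pipe(np.stack)
            .astype(float)
        )
    if "subgroup" in df.columns:
        df = df.drop(columns="subgroup")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}: ragged or missing values at subgroup row {row}")
    return df.to_numpy(dtype=float)


@dataclass
class MonitoringReport:
    """Per-subgroup statistics, limits and signals for several schemes."""

    moments: WMoments
    results: dict[str, WilcoxonChartResults]

    @property
    def first_signal_index(self) -> dict[str, int | None]:
        return {name: res.first_signal for name, res in self.results.items()}

    def to_frame(self) -> pd.DataFrame:
        """Wide table, one block of columns per scheme."""
        frames = []
        for name, res in self.results.items():
            f = res.to_frame().drop(columns="w")
            f = f.rename(
                columns={
                    c: f"{name}_{c}" for c in ("statistic", "lcl", "ucl", "signal")
                }
            )
            frames.append(f.set_index("t"))
        return pd.concat(frames, axis=1).reset_index()

    def to_csv(self, path: str | Path) -> None:
        """Write the report; numeric display at 2 decimals (half-up)."""
        df = self.to_frame().copy()
        for c in df.columns:
            if df[c].dtype == float:
                df[c] = df[c].map(lambda x: _round2(x))
        df.to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "m": self.moments.m,
                "n": self.moments.n,
                "mu_w": self.moments.mu_w,
                "sigma_w": self.moments.sigma_w,
                "first_signal_index": self.first_signal_index,
            },
            indent=2,
        )


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (table display convention)."""
    if not np.isfinite(x):
        return x
    return float(np.floor(x * 100 + 0.5) / 100) if x >= 0 else -_round2(-x)


def run_monitoring(
    phase1_file: str | Path,
    phase2_file: str | Path,
    specs: list[ChartSpec],
    long: bool = False,
) -> MonitoringReport:
    """Compute W per subgroup and run each scheme; assemble the report."""
    phase1 = read_phase1(phase1_file)
    phase2 = read_phase2(phase2_file, long=long)
    results: dict[str, WilcoxonChartResults] = {}
    for spec in specs:
        chart = WilcoxonChart(
            phase2,
            phase1,
            scheme=spec.scheme,
            lambda1=spec.lambda1,
            lambda2=spec.lambda2,
            limit_constant=spec.limit_constant,
            cusum_reference=spec.cusum_reference,
        )
        results[spec.scheme.value] = chart.fit()
    return MonitoringReport(moments=w_moments(phase1.size, phase2.shape[1]), results=results)
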