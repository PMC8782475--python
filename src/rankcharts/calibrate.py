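"""Control-limit constant calibration.

The limit constant ``L`` is tuned so that the attained in-control
average run length matches a nominal value (conventionally 500).  The
attained ARL0 is monotone nondecreasing in ``L``, so a bisection on
``L`` converges; common random numbers (the same seed for every
evaluation) keep the estimated ARL0(L) curve smooth enough to bisect,
and a fresh-seed confirmation run reports the final attained value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .charts import ChartSpec
from .runlength import SimulationConfig, estimate_run_length

__all__ = ["CalibrationResult", "BracketError", "calibrate_limit"]


class BracketError(ValueError):
    """The search bracket does not straddle the target ARL0."""


@dataclass(frozen=True)
class CalibrationResult:
    limit_constant: float
    attained_arl0: float
    mc_standard_error: float
    iterations: int
    tolerance_met: bool
    target_arl0: float


def calibrate_limit(
    spec: ChartSpec,
    config: SimulationConfig,
    target_arl0: float = 500.0,
    tolerance: float = 2.0,
    bracket: tuple[float, float] = (0.5, 5.0),
    max_iter: int = 40,
) -> CalibrationResult:
    """Bisect the limit constant to attain a nominal in-control ARL.

    Parameters
    ----------
    spec : ChartSpec
        Chart design; its ``limit_constant`` is ignored and replaced by
        the bisection iterate.
    config : SimulationConfig
        Monte Carlo conditions (``delta`` must be 0); ``config.seed``
        seeds the common-random-number evaluations.
    target_arl0 : float
        Nominal in-control ARL (> 1).
    tolerance : float
        Stop when |attained - target| <= tolerance (or the bracket
        width falls below 1e-4).

    Raises
    ------
    BracketError
        If the attained ARL0 at the bracket ends does not straddle the
        target; the message carries both diagnostic values.
    """
    if target_arl0 <= 1:
        raise ValueError("target_arl0 must exceed 1")
    if config.delta != 0:
        raise ValueError("calibration is an in-control exercise; set delta = 0")

    def attained(L: float):
        s = estimate_run_length(replace(spec, limit_constant=L), config)
        return s.arl, s.mc_se

    lo, hi = bracket
    arl_lo, _ = attained(lo)
    arl_hi, _ = attained(hi)
    if not arl_lo <= target_arl0 <= arl_hi:
        raise BracketError(
            f"attained ARL0 at bracket ends ({lo}: {arl_lo:.1f}, {hi}: {arl_hi:.1f}) "
            f"does not straddle target {target_arl0}"
        )
    it = 0
    mid, arl_mid, se_mid = hi, arl_hi, 0.0
    while it < max_iter and hi - lo > 1e-4:
        mid = 0.5 * (lo + hi)
        arl_mid, se_mid = attained(mid)
        it += 1
        if abs(arl_mid - target_arl0) <= tolerance:
            break
        if arl_mid > target_arl0:
            hi = mid
        else:
            lo = mid
    # fresh-seed confirmation of the selected constant
    confirm_cfg = replace(
        config, seed=None if config.seed is None else config.seed + 7_654_321
    )
    final = estimate_run_length(replace(spec, limit_constant=mid), confirm_cfg)
    return CalibrationResult(
        limit_constant=mid,
        attained_arl0=final.arl,
        mc_standard_error=final.mc_se,
        iterations=it,
        tolerance_met=abs(final.arl - target_arl0) <= max(tolerance, 3 * final.mc_se),
        target_arl0=target_arl0,
    )
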