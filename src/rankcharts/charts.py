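"""Charting statistics, variances and control limits for rank-sum schemes.

Implements the homogeneously weighted moving average (HWMA) chart of the
Wilcoxon rank-sum statistic together with its double (DHWMA) and hybrid
(HHWMA) extensions, and the EWMA, DEWMA and CUSUM rank-sum competitors.

All schemes plot a smoothed version of the sequence ``W_1, W_2, ...`` of
test-subgroup rank sums.  The HWMA statistic puts weight ``lambda`` on
the current ``W_t`` and spreads ``1 - lambda`` homogeneously over the
past through the running mean ``Wbar_{t-1}``::

    H_t  = lambda * W_t + (1 - lambda) * Wbar_{t-1},     Wbar_0 = mu_W
    DH_t = lambda * H_t + (1 - lambda) * Hbar_{t-1},     Hbar_0 = mu_W
    HH_t = lambda1 * H_t + (1 - lambda1) * Hbar_{t-1},   H_t with lambda2

Control limits are time varying, ``mu_W +/- L * sigma_W * sqrt(f_t)``,
where ``f_t`` is the scheme's variance factor (the variance of the
plotted statistic in units of ``sigma_W^2`` under i.i.d. ``W``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .rankstat import WMoments

__all__ = [
    "Scheme",
    "ChartSpec",
    "ChartState",
    "LimitPair",
    "CoefficientVector",
    "hwma_update",
    "dhwma_update",
    "hhwma_update",
    "competitor_update",
    "hwma_variance_factor",
    "dhwma_variance_factor",
    "hhwma_variance_factor",
    "variance_factors",
    "control_limits",
    "coefficient_vector",
    "coefficient_oracle",
    "signal",
    "statistic_path",
]


class Scheme(str, Enum):
    HWMA = "hwma"
    DHWMA = "dhwma"
    HHWMA = "hhwma"
    EWMA = "ewma"
    DEWMA = "dewma"
    CUSUM = "cusum"


#: schemes whose statistic is an HWMA-type running-mean smoothing
HWMA_FAMILY = (Scheme.HWMA, Scheme.DHWMA, Scheme.HHWMA)


def _check_lambda(lam: float, name: str = "lambda1") -> float:
    lam = float(lam)
    if not 0.0 < lam <= 1.0:
        raise ValueError(f"{name} must lie in (0, 1], got {lam}")
    return lam


@dataclass(frozen=True)
class ChartSpec:
    """Design of one monitoring scheme.

    Parameters
    ----------
    scheme : Scheme or str
        One of ``hwma``, ``dhwma``, ``hhwma``, ``ewma``, ``dewma``,
        ``cusum``.
    lambda1 : float
        Smoothing parameter in (0, 1] (the outer parameter for HHWMA).
    lambda2 : float, optional
        Inner smoothing parameter; required for HHWMA, disallowed
        elsewhere.
    limit_constant : float
        The control-limit constant ``L`` (half-width multiplier of the
        statistic's in-control standard deviation; for CUSUM the
        decision interval is ``h = L * sigma_W``).
    cusum_reference : float, optional
        CUSUM reference value ``k`` in ``sigma_W`` units (default 0.5).
    """

    scheme: Scheme
    lambda1: float = 1.0
    lambda2: float | None = None
    limit_constant: float = 3.0
    cusum_reference: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        if self.scheme is not Scheme.CUSUM:
            _check_lambda(self.lambda1)
        if self.scheme is Scheme.HHWMA:
            if self.lambda2 is None:
                raise ValueError("HHWMA requires both lambda1 and lambda2")
            _check_lambda(self.lambda2, "lambda2")
        elif self.lambda2 is not None:
            raise ValueError(f"lambda2 is only meaningful for HHWMA, not {self.scheme.value}")
        if not self.limit_constant > 0:
            raise ValueError("limit_constant must be positive")
        if self.scheme is Scheme.CUSUM and self.cusum_reference is None:
            object.__setattr__(self, "cusum_reference", 0.5)
        if self.cusum_reference is not None:
            if self.scheme is not Scheme.CUSUM:
                raise ValueError("cusum_reference applies to the CUSUM scheme only")
            if self.cusum_reference < 0:
                raise ValueError("cusum_reference must be nonnegative")

    @property
    def inner_lambda(self) -> float:
        """Smoothing applied directly to W (lambda2 for HHWMA)."""
        return self.lambda2 if self.scheme is Scheme.HHWMA else self.lambda1


@dataclass
class ChartState:
    """Carry-over between sampling times of one monitoring sequence.

    ``t`` counts subgroups already absorbed; running sums (not means)
    are stored so updates are exact.  At ``t = 0`` both running means
    equal ``mu_w`` by convention.
    """

    mu_w: float
    t: int = 0
    w_sum: float = 0.0
    h_sum: float = 0.0
    ewma_level: float = field(default=np.nan)
    dewma_level: float = field(default=np.nan)
    cusum_pos: float = 0.0
    cusum_neg: float = 0.0
    last_statistic: float = np.nan

    def __post_init__(self):
        if np.isnan(self.ewma_level):
            self.ewma_level = self.mu_w
        if np.isnan(self.dewma_level):
            self.dewma_level = self.mu_w

    @property
    def w_running_mean(self) -> float:
        return self.mu_w if self.t == 0 else self.w_sum / self.t

    @property
    def h_running_mean(self) -> float:
        return self.mu_w if self.t == 0 else self.h_sum / self.t


@dataclass(frozen=True)
class LimitPair:
    lcl: float
    ucl: float
    center: float
    t: int


def signal(statistic: float, limits: LimitPair) -> bool:
    """True iff the statistic plots strictly beyond either limit.

    A statistic exactly on a limit is treated as in control.
    """
    return statistic > limits.ucl or statistic < limits.lcl


# ---------------------------------------------------------------------------
# scalar chart updates


def hwma_update(state: ChartState, w: float, spec: ChartSpec) -> tuple[float, ChartState]:
    if spec.scheme is not Scheme.HWMA:
        raise ValueError(f"spec scheme is {spec.scheme.value}, expected hwma")
    lam = spec.lambda1
    h = lam * w + (1.0 - lam) * state.w_running_mean
    new = replace(state, t=state.t + 1, w_sum=state.w_sum + w, last_statistic=h)
    return h, new


def _double_update(state: ChartState, w: float, lam_inner: float, lam_outer: float):
    h = lam_inner * w + (1.0 - lam_inner) * state.w_running_mean
    out = lam_outer * h + (1.0 - lam_outer) * state.h_running_mean
    new = replace(
        state,
        t=state.t + 1,
        w_sum=state.w_sum + w,
        h_sum=state.h_sum + h,
        last_statistic=out,
    )
    return out, new


def dhwma_update(state: ChartState, w: float, spec: ChartSpec) -> tuple[float, ChartState]:
    if spec.scheme is not Scheme.DHWMA:
        raise ValueError(f"spec scheme is {spec.scheme.value}, expected dhwma")
    return _double_update(state, w, spec.lambda1, spec.lambda1)


def hhwma_update(state: ChartState, w: float, spec: ChartSpec) -> tuple[float, ChartState]:
    if spec.scheme is not Scheme.HHWMA:
        raise ValueError(f"spec scheme is {spec.scheme.value}, expected hhwma")
    return _double_update(state, w, spec.lambda2, spec.lambda1)


def competitor_update(state: ChartState, w: float, spec: ChartSpec):
    """One step of the EWMA, DEWMA or CUSUM rank-sum competitor.

    Returns ``(statistic, new_state)``; for CUSUM the statistic is the
    pair ``(C_plus, C_minus)`` of one-sided sums.
    """
    if spec.scheme is Scheme.EWMA:
        lam = spec.lambda1
        z = lam * w + (1.0 - lam) * state.ewma_level
        new = replace(state, t=state.t + 1, ewma_level=z, last_statistic=z)
        return z, new
    if spec.scheme is Scheme.DEWMA:
        lam = spec.lambda1
        z = lam * w + (1.0 - lam) * state.ewma_level
        zz = lam * z + (1.0 - lam) * state.dewma_level
        new = replace(state, t=state.t + 1, ewma_level=z, dewma_level=zz, last_statistic=zz)
        return zz, new
    if spec.scheme is Scheme.CUSUM:
        if spec.cusum_reference is None:
            raise ValueError("CUSUM requires a reference value k")
        # k is carried in sigma_W units by the spec; convert at call sites
        # that know sigma_W.  Here w is expected already centred/scaled.
        raise NotImplementedError(
            "use cusum_step(), which needs mu_w and sigma_w explicitly"
        )
    raise ValueError(f"{spec.scheme.value} is not a competitor scheme")


def cusum_step(
    state: ChartState, w: float, spec: ChartSpec, moments: WMoments
) -> tuple[tuple[float, float], ChartState]:
    """Two-sided tabular CUSUM step with k = cusum_reference * sigma_W."""
    if spec.scheme is not Scheme.CUSUM:
        raise ValueError("cusum_step requires a CUSUM spec")
    k = spec.cusum_reference * moments.sigma_w
    dev = w - moments.mu_w
    cp = max(0.0, state.cusum_pos + dev - k)
    cn = max(0.0, state.cusum_neg - dev - k)
    new = replace(
        state, t=state.t + 1, cusum_pos=cp, cusum_neg=cn, last_statistic=max(cp, cn)
    )
    return (cp, cn), new


# ---------------------------------------------------------------------------
# variance factors (multipliers of sigma_W^2)


def hwma_variance_factor(t: int, lam: float) -> float:
    """Var(H_t) / sigma_W^2: lambda^2 at t = 1, + (1-lambda)^2/(t-1) after."""
    _check_lambda(lam, "lambda")
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    if t == 1:
        return lam**2
    return lam**2 + (1.0 - lam) ** 2 / (t - 1)


def hhwma_variance_factor(t: int, lambda1: float, lambda2: float) -> float:
    """Var(HH_t) / sigma_W^2 for the hybrid scheme."""
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    return float(_hhwma_factors(int(t), lambda1, lambda2)[-1])


def dhwma_variance_factor(t: int, lam: float) -> float:
    """Var(DH_t) / sigma_W^2; the hybrid factor with equal parameters."""
    return hhwma_variance_factor(t, lam, lam)


def _hhwma_factors(t_max: int, lambda1: float, lambda2: float) -> np.ndarray:
    """Vector of HHWMA variance factors for t = 1..t_max.

    The t > 2 branch contains a sum of squared terms built from partial
    harmonic sums; expanding the square reduces it to prefix sums of the
    harmonic numbers, giving an O(t_max) evaluation::

        f_t = A^2 + [B^2 + sum_{u=1}^{t-2} (B + C (Hm_{t-2} - Hm_{u-1}))^2] / (t-1)^2

    with A = l1 l2, B = l1 + l2 - 2 l1 l2, C = (1-l1)(1-l2) and Hm the
    harmonic numbers (Hm_0 = 0).
    """
    l1 = _check_lambda(lambda1, "lambda1")
    l2 = _check_lambda(lambda2, "lambda2")
    a = l1 * l2
    b = l1 + l2 - 2.0 * l1 * l2
    c = (1.0 - l1) * (1.0 - l2)
    out = np.empty(t_max)
    out[0] = a * a
    if t_max == 1:
        return out
    # harmonic numbers Hm[j] = sum_{k=1}^{j} 1/k for j = 0..t_max-2
    j = np.arange(t_max - 1)
    hm = np.concatenate([[0.0], np.cumsum(1.0 / j[1:])]) if t_max > 2 else np.zeros(1)
    # prefix sums over u of Hm_{u-1} and Hm_{u-1}^2
    p1 = np.concatenate([[0.0], np.cumsum(hm[:-1])])
    p2 = np.concatenate([[0.0], np.cumsum(hm[:-1] ** 2)])
    t = np.arange(2, t_max + 1)
    jj = t - 2
    ct = b + c * hm[jj]
    s = jj * ct**2 - 2.0 * ct * c * p1[jj] + c * c * p2[jj]
    out[1:] = a * a + (b * b + s) / (t - 1.0) ** 2
    return out


def _ewma_factors(t_max: int, lam: float) -> np.ndarray:
    q = (1.0 - lam) ** 2
    t = np.arange(1, t_max + 1)
    if q == 0.0:
        return np.full(t_max, lam**2)
    return lam**2 * (1.0 - q**t) / (1.0 - q)


def _dewma_factors(t_max: int, lam: float) -> np.ndarray:
    # coefficient on W_s is lam^2 (t-s+1) (1-lam)^(t-s)
    j = np.arange(t_max)
    q = (1.0 - lam) ** 2
    return lam**4 * np.cumsum((j + 1.0) ** 2 * q**j)


def variance_factors(spec: ChartSpec, t_max: int) -> np.ndarray:
    """Variance factors f_1..f_{t_max} of the plotted statistic."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    lam = spec.lambda1
    if spec.scheme is Scheme.HWMA:
        t = np.arange(1, t_max + 1)
        out = lam**2 + (1.0 - lam) ** 2 / np.maximum(t - 1, 1)
        out[0] = lam**2
        return out
    if spec.scheme is Scheme.DHWMA:
        return _hhwma_factors(t_max, lam, lam)
    if spec.scheme is Scheme.HHWMA:
        return _hhwma_factors(t_max, lam, spec.lambda2)
    if spec.scheme is Scheme.EWMA:
        return _ewma_factors(t_max, lam)
    if spec.scheme is Scheme.DEWMA:
        return _dewma_factors(t_max, lam)
    raise ValueError(f"no variance factors for scheme {spec.scheme.value}")


def control_limits(spec: ChartSpec, moments: WMoments, t: int) -> LimitPair:
    """Time-varying limits mu_W +/- L sigma_W sqrt(f_t) at sampling time t."""
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    if spec.scheme is Scheme.CUSUM:
        raise ValueError("CUSUM uses a decision interval, not two-sided limits")
    half = spec.limit_constant * moments.sigma_w * np.sqrt(
        variance_factors(spec, t)[-1]
    )
    return LimitPair(
        lcl=moments.mu_w - half, ucl=moments.mu_w + half, center=moments.mu_w, t=t
    )


# ---------------------------------------------------------------------------
# coefficient-propagation oracle


@dataclass(frozen=True)
class CoefficientVector:
    """Representation statistic_t = sum_s coefficients[s-1] * W_s + constant0 * mu_W."""

    coefficients: np.ndarray
    constant0: float

    def variance_multiplier(self) -> float:
        return float(np.sum(self.coefficients**2))

    def weight_sum(self) -> float:
        return float(np.sum(self.coefficients) + self.constant0)


def _inner_hwma_coeffs(s: int, t: int, lam: float) -> tuple[np.ndarray, float]:
    """Coefficients of H_s (inner HWMA with parameter lam) on W_1..W_t."""
    c = np.zeros(t)
    c[s - 1] = lam
    if s == 1:
        return c, 1.0 - lam
    c[: s - 1] = (1.0 - lam) / (s - 1)
    return c, 0.0


def coefficient_vector(
    scheme: Scheme | str, t: int, lambda1: float, lambda2: float | None = None
) -> CoefficientVector:
    """Propagate a chart recursion into explicit weights on W_1..W_t.

    Independent of the closed-form variance factors: the recursions are
    expanded symbolically (numerically exact linear algebra), so the sum
    of squared weights cross-checks the published variance expressions.
    """
    scheme = Scheme(scheme)
    if t < 1:
        raise ValueError("t must be >= 1")
    lam = _check_lambda(lambda1, "lambda1")
    if scheme is Scheme.HWMA:
        c, c0 = _inner_hwma_coeffs(t, t, lam)
        return CoefficientVector(c, c0)
    if scheme in (Scheme.DHWMA, Scheme.HHWMA):
        li = lam if scheme is Scheme.DHWMA else _check_lambda(lambda2, "lambda2")
        lo = lam
        sum_c = np.zeros(t)
        sum_c0 = 0.0
        for s in range(1, t):
            cs, cs0 = _inner_hwma_coeffs(s, t, li)
            sum_c += cs
            sum_c0 += cs0
        ct, ct0 = _inner_hwma_coeffs(t, t, li)
        if t == 1:
            return CoefficientVector(lo * ct, lo * ct0 + (1.0 - lo))
        return CoefficientVector(
            lo * ct + (1.0 - lo) * sum_c / (t - 1),
            lo * ct0 + (1.0 - lo) * sum_c0 / (t - 1),
        )
    if scheme in (Scheme.EWMA, Scheme.DEWMA):
        z = np.zeros(t)
        z0 = 1.0
        zz = np.zeros(t)
        zz0 = 1.0
        for s in range(1, t + 1):
            e = np.zeros(t)
            e[s - 1] = 1.0
            z = lam * e + (1.0 - lam) * z
            z0 = (1.0 - lam) * z0
            zz = lam * z + (1.0 - lam) * zz
            zz0 = lam * z0 + (1.0 - lam) * zz0
        if scheme is Scheme.EWMA:
            return CoefficientVector(z, z0)
        return CoefficientVector(zz, zz0)
    raise ValueError(f"coefficient propagation undefined for {scheme.value}")


def coefficient_oracle(
    scheme: Scheme | str, t: int, lambda1: float, lambda2: float | None = None
) -> float:
    """Variance multiplier of sigma_W^2 via coefficient propagation."""
    return coefficient_vector(scheme, t, lambda1, lambda2).variance_multiplier()


# ---------------------------------------------------------------------------
# vectorised statistic paths (run-length engine back end)


def statistic_path(
    spec: ChartSpec, mu_w: float, w_block: np.ndarray, state: ChartState
) -> tuple[np.ndarray, ChartState]:
    """Plotted statistics for a block of consecutive W values.

    Equivalent to repeated scalar updates but vectorised over the block;
    ``state`` carries the running sums between blocks.  CUSUM is handled
    separately in the run-length engine (one-sided decision rule).
    """
    w_block = np.asarray(w_block, dtype=float)
    b = w_block.size
    t = state.t + np.arange(1, b + 1)
    csum = np.cumsum(w_block)
    prev_sum = state.w_sum + csum - w_block
    wbar_prev = np.where(t == 1, mu_w, prev_sum / np.maximum(t - 1, 1))

    if spec.scheme is Scheme.HWMA:
        lam = spec.lambda1
        stats = lam * w_block + (1.0 - lam) * wbar_prev
        new = replace(
            state,
            t=state.t + b,
            w_sum=state.w_sum + csum[-1],
            last_statistic=stats[-1],
        )
        return stats, new
    if spec.scheme in (Scheme.DHWMA, Scheme.HHWMA):
        li = spec.inner_lambda
        lo = spec.lambda1
        h = li * w_block + (1.0 - li) * wbar_prev
        hsum = np.cumsum(h)
        hprev = state.h_sum + hsum - h
        hbar_prev = np.where(t == 1, mu_w, hprev / np.maximum(t - 1, 1))
        stats = lo * h + (1.0 - lo) * hbar_prev
        new = replace(
            state,
            t=state.t + b,
            w_sum=state.w_sum + csum[-1],
            h_sum=state.h_sum + hsum[-1],
            last_statistic=stats[-1],
        )
        return stats, new
    if spec.scheme in (Scheme.EWMA, Scheme.DEWMA):
        lam = spec.lambda1
        z = state.ewma_level
        zz = state.dewma_level
        stats = np.empty(b)
        for i in range(b):
            z = lam * w_block[i] + (1.0 - lam) * z
            if spec.scheme is Scheme.DEWMA:
                zz = lam * z + (1.0 - lam) * zz
                stats[i] = zz
            else:
                stats[i] = z
        new = replace(
            state,
            t=state.t + b,
            w_sum=state.w_sum + csum[-1],
            ewma_level=z,
            dewma_level=zz,
            last_statistic=stats[-1],
        )
        return stats, new
    raise ValueError(f"statistic_path does not handle {spec.scheme.value}")


def cusum_path(
    spec: ChartSpec, moments: WMoments, w_block: np.ndarray, state: ChartState
) -> tuple[np.ndarray, np.ndarray, ChartState]:
    """Vectorised two-sided CUSUM over a block.

    Uses the reflected-random-walk identity ``C_t = S_t - min_{j<=t} S_j``
    (with the initial sum folded into the running minimum).
    """
    w_block = np.asarray(w_block, dtype=float)
    k = spec.cusum_reference * moments.sigma_w
    dev = w_block - moments.mu_w

    def one_side(x: np.ndarray, c0: float) -> np.ndarray:
        s = np.cumsum(x)
        run_min = np.minimum.accumulate(np.minimum(s, -c0))
        return s - run_min

    cp = one_side(dev - k, state.cusum_pos)
    cn = one_side(-dev - k, state.cusum_neg)
    new = replace(
        state,
        t=state.t + w_block.size,
        w_sum=state.w_sum + float(np.sum(w_block)),
        cusum_pos=float(cp[-1]),
        cusum_neg=float(cn[-1]),
        last_statistic=float(max(cp[-1], cn[-1])),
    )
    return cp, cn, new
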