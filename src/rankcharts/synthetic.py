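"""Process-distribution sampling, shift injection and fixture generation.

Three continuous families are used throughout the simulation study: the
standard normal, Student's t with 5 degrees of freedom (heavy tails) and
Gamma(shape=3, scale=1) (right skew).  Location shifts are always
expressed in units of the family's population standard deviation
``sigma_F`` (1, sqrt(5/3) and sqrt(3) respectively), so in-control
behaviour of the rank-based charts is invariant to the family's scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = [
    "ProcessModel",
    "FAMILIES",
    "family_sigma",
    "draw_reference",
    "draw_test_subgroup",
    "make_illustration_fixture",
    "write_fixture",
]


_SAMPLERS: dict[str, Callable[[np.random.Generator, int], np.ndarray]] = {
    "normal": lambda rng, size: rng.standard_normal(size),
    "t5": lambda rng, size: rng.standard_t(5, size),
    "gamma31": lambda rng, size: rng.gamma(3.0, 1.0, size),
}

_SIGMAS = {"normal": 1.0, "t5": np.sqrt(5.0 / 3.0), "gamma31": np.sqrt(3.0)}

FAMILIES = tuple(_SAMPLERS)


def family_sigma(family: str) -> float:
    """Population standard deviation sigma_F of a named family."""
    try:
        return _SIGMAS[family]
    except KeyError:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}") from None


@dataclass(frozen=True)
class ProcessModel:
    """A process distribution with an optional sustained location shift.

    Parameters
    ----------
    family : str
        ``normal``, ``t5`` or ``gamma31``.
    delta : float
        Location shift in units of sigma_F (0 = in control).
    changepoint : int
        Subgroup index (1-based) at which the shift switches on when
        generating fixture sequences; draws before it are in control.
    """

    family: str = "normal"
    delta: float = 0.0
    changepoint: int = 1

    def __post_init__(self):
        family_sigma(self.family)
        if self.changepoint < 1:
            raise ValueError("changepoint must be >= 1")

    @property
    def sigma(self) -> float:
        return family_sigma(self.family)


def draw_reference(model: ProcessModel, m: int, rng: np.random.Generator) -> np.ndarray:
    """m i.i.d. in-control draws (the phase-I reference sample)."""
    if m < 2:
        raise ValueError("reference sample needs m >= 2")
    return _SAMPLERS[model.family](rng, m)


def draw_test_subgroup(
    model: ProcessModel, n: int, delta: float, rng: np.random.Generator
) -> np.ndarray:
    """n i.i.d. draws shifted by delta * sigma_F."""
    if n < 1:
        raise ValueError("test subgroup needs n >= 1")
    return _SAMPLERS[model.family](rng, n) + delta * model.sigma


def draw_subgroup_block(
    model: ProcessModel, shape: tuple[int, int], delta: float, rng: np.random.Generator
) -> np.ndarray:
    """A (B, n) block of independent test subgroups (simulation fast path)."""
    return _SAMPLERS[model.family](rng, shape) + delta * model.sigma


def make_illustration_fixture(
    rng: np.random.Generator,
    m: int = 520,
    n_subgroups: int = 78,
    n: int = 5,
    family: str = "gamma31",
    delta: float = 0.75,
    changepoint: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic stand-in shaped like the silica-in-iron-ore illustration.

    The real flotation-process measurements are not public; this fixture
    reproduces only the dimensions (m = 520 reference values, 78 test
    subgroups of size 5) and the right-skewed marginal, with a location
    shift injected at a known changepoint.

    Returns
    -------
    (phase1, phase2) : ndarray shape (m,), ndarray shape (n_subgroups, n)
    """
    model = ProcessModel(family=family, delta=delta, changepoint=changepoint)
    phase1 = draw_reference(model, m, rng)
    phase2 = np.empty((n_subgroups, n))
    for t in range(1, n_subgroups + 1):
        d = delta if t >= changepoint else 0.0
        phase2[t - 1] = draw_test_subgroup(model, n, d, rng)
    return phase1, phase2


def write_fixture(
    outdir: str | Path,
    phase1: np.ndarray,
    phase2: np.ndarray,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Serialize a fixture: phase-I single-column CSV, phase-II wide CSV.

    A manifest JSON records how the fixture was generated (family,
    delta, changepoint, seed) for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p1 = outdir / "phase1.csv"
    p2 = outdir / "phase2.csv"
    np.savetxt(p1, np.asarray(phase1), fmt="%.10g", header="value", comments="")
    n = phase2.shape[1]
    header = "subgroup," + ",".join(f"obs{j + 1}" for j in range(n))
    rows = np.column_stack([np.arange(1, phase2.shape[0] + 1), phase2])
    np.savetxt(p2, rows, fmt="%.10g", delimiter=",", header=header, comments="")
    paths = {"phase1": p1, "phase2": p2}
    if manifest is not None:
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        paths["manifest"] = mpath
    return paths
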