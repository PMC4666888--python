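"""Background (other-cause) mortality: life tables and death-age sampling.

The simulator needs an all-cause mortality schedule for causes other than
breast cancer.  National statistical-office life tables give the annual
death probability ``qx`` by integer age; within each one-year age band we
treat the hazard as constant, ``lambda_x = -ln(1 - qx)``, so survival is
piecewise exponential and age is continuous.

Because the exact national table behind the published analysis is not
reproduced anywhere, the package bundles a synthetic fixture approximating
the 2011 Austrian female schedule, generated from a Gompertz-Makeham hazard
``mu(x) = a * exp(b*x) + c`` calibrated so that remaining life expectancy at
age 50 is ~33 years (typical of a high-income female population).  The
generator itself is exposed so alternative schedules can be produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "MortalityModel",
    "annual_hazard",
    "sample_death_age",
    "make_synthetic_table",
    "life_expectancy",
    "load_life_table",
    "default_life_table",
    "GOMPERTZ_MAKEHAM_DEFAULTS",
]

# Hazard cap standing in for qx = 1 at the terminal age (survival ~1e-12/yr).
_QX_CAP = 1.0 - 1e-12


@dataclass(frozen=True)
class LifeTable:
    """Annual other-cause death probabilities by integer age.

    ``qx[k]`` is the probability of dying within ``[start_age + k,
    start_age + k + 1)`` conditional on being alive at its start; the last
    entry must be 1 so that nobody outlives ``terminal_age``.
    """

    start_age: int
    qx: np.ndarray

    def __post_init__(self) -> None:
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "qx", qx)
        if qx.ndim != 1 or len(qx) < 1:
            raise ValueError("qx must be a non-empty 1-D array")
        if np.any(qx < 0) or np.any(qx > 1):
            raise ValueError("qx values must lie in [0, 1]")
        if np.any(qx[:-1] >= 1):
            raise ValueError("qx must be < 1 below the terminal age")
        if qx[-1] != 1.0:
            raise ValueError("qx at the terminal age must equal 1")

    @property
    def terminal_age(self) -> int:
        """Age by which death is certain."""
        return self.start_age + len(self.qx)

    def band_hazards(self) -> np.ndarray:
        """Constant hazard per one-year band, ``-ln(1 - qx)``."""
        return -np.log1p(-np.minimum(self.qx, _QX_CAP))

    def cumulative_hazard_from(self, age: float) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints (years since *age*) and cumulative hazard at each.

        The first band may be partial if *age* is not an integer.
        """
        self._check_age(age)
        haz = self.band_hazards()
        k0 = int(np.floor(age)) - self.start_age
        frac = age - np.floor(age)
        # time from `age` to the end of each band k0, k0+1, ...
        edges = np.arange(k0 + 1, len(self.qx) + 1) - k0 - frac
        widths = np.diff(np.concatenate(([0.0], edges)))
        cum = np.concatenate(([0.0], np.cumsum(haz[k0:] * widths)))
        times = np.concatenate(([0.0], edges))
        return times, cum

    def _check_age(self, age: float) -> None:
        if not self.start_age <= age < self.terminal_age:
            raise ValueError(
                f"age {age} outside table range [{self.start_age}, {self.terminal_age})"
            )


@dataclass(frozen=True)
class MortalityModel:
    """Choice of mortality schedule: bundled fixture or parametric synthetic."""

    source: str = "fixture"
    a: float = 2.5e-5
    b: float = 0.095
    c: float = 5e-4

    def table(self, start_age: int = 40, terminal_age: int = 105) -> LifeTable:
        if self.source == "fixture":
            return default_life_table()
        if self.source == "gompertz_makeham":
            return make_synthetic_table(
                self, start_age=start_age, terminal_age=terminal_age
            )
        raise ValueError(f"unknown mortality source {self.source!r}")


def annual_hazard(table: LifeTable, age: float) -> float:
    """Piecewise-constant other-cause hazard at *age* (per year)."""
    table._check_age(age)
    k = int(np.floor(age)) - table.start_age
    return float(table.band_hazards()[k])


def sample_death_times(table: LifeTable, age: float, exp_draws: np.ndarray) -> np.ndarray:
    """Map Exp(1) draws to times-to-death (years from *age*); vectorised.

    Inverts the piecewise-linear cumulative hazard; results are capped at
    the terminal age.
    """
    times, cum = table.cumulative_hazard_from(age)
    e = np.asarray(exp_draws, dtype=float)
    idx = np.clip(np.searchsorted(cum, e, side="right") - 1, 0, len(times) - 2)
    haz_per_band = np.diff(cum) / np.diff(times)
    t = times[idx] + (e - cum[idx]) / haz_per_band[idx]
    return np.minimum(t, times[-1])


def sample_death_age(table: LifeTable, current_age: float, u) -> np.ndarray | float:
    """Inverse-CDF draw of the age at other-cause death.

    ``u`` is uniform(0, 1): the quantile of the death-age distribution, so
    ``u -> 1`` approaches the terminal age.  Scalar in, scalar out.
    """
    scalar = np.isscalar(u)
    e = -np.log1p(-np.asarray(u, dtype=float))
    ages = current_age + sample_death_times(table, current_age, e)
    return float(ages) if scalar else ages


def life_expectancy(table: LifeTable, age: float) -> float:
    """Deterministic remaining life expectancy at *age* (years).

    Closed-form integral of the piecewise-exponential survival curve.
    """
    times, cum = table.cumulative_hazard_from(age)
    widths = np.diff(times)
    haz = np.diff(cum) / widths
    s_start = np.exp(-cum[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        seg = np.where(
            haz > 0, s_start * -np.expm1(-haz * widths) / haz, s_start * widths
        )
    return float(np.sum(seg))


GOMPERTZ_MAKEHAM_DEFAULTS = MortalityModel(source="gompertz_makeham")


def make_synthetic_table(
    model: MortalityModel, start_age: int = 40, terminal_age: int = 105
) -> LifeTable:
    """Life table from a Gompertz-Makeham hazard ``mu(x) = a e^(b x) + c``.

    ``qx = 1 - exp(-integral of mu over the year)``; the terminal-age entry
    is forced to 1.
    """
    if terminal_age <= start_age:
        raise ValueError("terminal_age must exceed start_age")
    a, b, c = model.a, model.b, model.c
    ages = np.arange(start_age, terminal_age, dtype=float)
    if b != 0.0:
        integral = (a / b) * (np.exp(b * (ages + 1)) - np.exp(b * ages)) + c
    else:
        integral = np.full_like(ages, a + c)
    if np.any(integral < 0):
        raise ValueError("Gompertz-Makeham parameters give a negative hazard")
    qx = -np.expm1(-integral)
    qx = np.minimum(qx, _QX_CAP)
    qx[-1] = 1.0
    return LifeTable(start_age=start_age, qx=qx)


def load_life_table(path: str | Path) -> LifeTable:
    """Read a 2-column CSV (age, qx) into a :class:`LifeTable`."""
    df = pd.read_csv(path, comment="#")
    if list(df.columns[:2]) != ["age", "qx"]:
        raise ValueError("life-table CSV must have columns 'age', 'qx'")
    ages = df["age"].to_numpy()
    if not np.array_equal(ages, np.arange(ages[0], ages[0] + len(ages))):
        raise ValueError("life-table ages must be consecutive integers")
    return LifeTable(start_age=int(ages[0]), qx=df["qx"].to_numpy(dtype=float))


def write_life_table(table: LifeTable, path: str | Path) -> None:
    ages = np.arange(table.start_age, table.terminal_age)
    pd.DataFrame({"age": ages, "qx": table.qx}).to_csv(path, index=False)


def default_life_table() -> LifeTable:
    """The bundled synthetic fixture (approximate 2011 Austrian female schedule)."""
    from importlib.resources import files

    import io

    text = files("odxcea.data").joinpath("life_table_austria_female_2011_synthetic.csv").read_text()
    return load_life_table(io.StringIO(text))
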