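"""National life tables: sex x calendar-year x single-year-of-age death probabilities.

A :class:`LifeTable` stores the annual conditional probability of death
``q(sex, year, age)`` and is the sole source of background (referent)
mortality throughout the package.  The table must be rectangular over its
declared sexes, years and ages, and must *close*: ``q = 1`` at the final age,
so that every simulated referent eventually dies.

Annual probabilities are converted to a monthly hazard under a
constant-hazard-within-year assumption::

    h_month = -ln(1 - q_annual) / 12

and to a monthly death probability ``p = 1 - exp(-h_month)`` (equivalently
``1 - (1 - q)**(1/12)``).  Calendar years beyond the table's last year reuse
the last available year's column (explicit carry-forward), because referents
routinely outlive the table's calendar span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("M", "F")


@dataclass
class LifeTable:
    """Rectangular q(sex, year, age) container.

    Parameters
    ----------
    years : np.ndarray
        Consecutive calendar years covered.
    ages : np.ndarray
        Consecutive single years of age; the last age must carry q = 1.
    q : dict[str, np.ndarray]
        Per sex, an array of shape ``(n_years, n_ages)`` of annual
        conditional death probabilities.
    """

    years: np.ndarray
    ages: np.ndarray
    q: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.ages = np.asarray(self.ages, dtype=int)
        if not np.array_equal(self.years, np.arange(self.years[0], self.years[-1] + 1)):
            raise ValueError("life table years must be consecutive")
        if not np.array_equal(self.ages, np.arange(self.ages[0], self.ages[-1] + 1)):
            raise ValueError("life table ages must be consecutive")
        for sex in SEXES:
            if sex not in self.q:
                raise ValueError(f"life table missing sex {sex!r}")
            arr = np.asarray(self.q[sex], dtype=float)
            if arr.shape != (self.years.size, self.ages.size):
                raise ValueError(
                    f"q[{sex!r}] has shape {arr.shape}, expected "
                    f"{(self.years.size, self.ages.size)}"
                )
            if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
                raise ValueError(f"q[{sex!r}] outside [0, 1]")
            if not np.allclose(arr[:, -1], 1.0):
                raise ValueError("life table must close with q = 1 at the final age")
            self.q[sex] = arr

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_q(self, sex: str, year: int, age: int) -> float:
        """q for one cell; years beyond the span carry the last year forward."""
        return float(self.q[sex][self._year_index(year), age - self.ages[0]])

    def _year_index(self, year: int) -> int:
        if year < self.years[0]:
            raise KeyError(f"calendar year {year} precedes life table start {self.years[0]}")
        return min(int(year - self.years[0]), self.years.size - 1)

    def monthly_death_prob_path(self, sex: str, age_at_start: int, year_at_start: int,
                                n_months: int) -> np.ndarray:
        """Monthly death probabilities for a referent walked forward from
        (``age_at_start``, ``year_at_start``), age and calendar year advancing
        together.  Ages above the closing age are certain deaths (p = 1).
        """
        if sex not in self.q:
            raise KeyError(f"unknown sex {sex!r}")
        if age_at_start < self.ages[0]:
            raise KeyError(
                f"life table does not cover (sex={sex}, age={age_at_start}, "
                f"year={year_at_start}); table starts at age {self.ages[0]}"
            )
        if year_at_start < self.years[0]:
            raise KeyError(
                f"life table does not cover (sex={sex}, age={age_at_start}, "
                f"year={year_at_start}); consider last-year carry-forward from "
                f"{self.years[0]}"
            )
        months = np.arange(n_months)
        elapsed_years = months // 12
        age = age_at_start + elapsed_years
        year = year_at_start + elapsed_years
        qcol = self.q[sex]
        yi = np.minimum(year - self.years[0], self.years.size - 1)
        ai = np.minimum(age - self.ages[0], self.ages.size - 1)
        q = qcol[yi, ai].copy()
        q[age >= self.max_age] = 1.0
        # p = 1 - (1-q)^(1/12); q = 1 closes the table within 12 months
        with np.errstate(divide="ignore"):
            p = 1.0 - np.power(1.0 - np.minimum(q, 1.0), 1.0 / 12.0)
        p[q >= 1.0] = 1.0
        return p

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            arr = self.q[sex]
            yy, aa = np.meshgrid(self.years, self.ages, indexing="ij")
            rows.append(pd.DataFrame({
                "sex": sex, "year": yy.ravel(), "age": aa.ravel(), "qx": arr.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        required = {"sex", "year", "age", "qx"}
        if not required.issubset(df.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        years = np.sort(df["year"].unique())
        ages = np.sort(df["age"].unique())
        q = {}
        for sex in SEXES:
            sub = df[df["sex"] == sex]
            pivot = sub.pivot_table(index="year", columns="age", values="qx")
            pivot = pivot.reindex(index=years, columns=ages)
            if pivot.isna().any().any():
                raise ValueError(f"life table not rectangular for sex {sex!r}")
            q[sex] = pivot.to_numpy(dtype=float)
        return cls(years=years, ages=ages, q=q)

    @classmethod
    def read_csv(cls, path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path))
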