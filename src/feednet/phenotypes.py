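"""Derived feed-efficiency phenotypes.

Residual feed intake (RFI) is the residual of an ordinary least squares
regression of daily energy intake on average daily gain and metabolic
mid-weight::

    dEI_i = beta0 + beta1 * ADG_i + beta2 * MMWT_i + e_i

where the residual e_i is the RFI of animal i: the part of its energy intake
not explained by its growth and maintenance requirement.  Negative RFI marks
an efficient animal (ate less than predicted), positive an inefficient one.

The test period runs from month 6 to month 9 of age.  dEI is total consumed
metabolizable energy divided by days on test; ADG is total gain divided by
days on test; MMWT is the mid-test body weight raised to the power 0.75
(the classical metabolic-weight exponent).  FCR is energy intake per kg gain.

The RFI regression is fitted with plain OLS (statsmodels) without fixed
effects; year and season enter later as fixed effects of the association
model, not here.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Metabolizable energy densities of the two ration components (MJ ME per kg
#: dry matter).
HAY_ENERGY_MJ_PER_KG = 9.0
CONCENTRATE_ENERGY_MJ_PER_KG = 11.3

#: Exponent of metabolic body weight.
METABOLIC_EXPONENT = 0.75


class CollinearDesignError(ValueError):
    """Raised when the RFI regressors are linearly dependent."""


def compute_dei(
    hay_kg_dm: float,
    concentrate_kg_dm: float,
    n_days: int,
    hay_energy: float = HAY_ENERGY_MJ_PER_KG,
    concentrate_energy: float = CONCENTRATE_ENERGY_MJ_PER_KG,
):
    """Daily energy intake in MJ ME from consumed feed masses (kg DM)."""
    hay_kg_dm = np.asarray(hay_kg_dm, dtype=float)
    concentrate_kg_dm = np.asarray(concentrate_kg_dm, dtype=float)
    if np.any(np.asarray(n_days) <= 0):
        raise ValueError("n_days must be positive")
    if np.any(hay_kg_dm < 0) or np.any(concentrate_kg_dm < 0):
        raise ValueError("feed masses must be non-negative")
    total = hay_kg_dm * hay_energy + concentrate_kg_dm * concentrate_energy
    return total / np.asarray(n_days, dtype=float)


def compute_adg(bw_start, bw_end, n_days):
    """Average daily gain in kg/day over the test period."""
    if np.any(np.asarray(n_days) <= 0):
        raise ValueError("n_days must be positive")
    return (np.asarray(bw_end, float) - np.asarray(bw_start, float)) / np.asarray(
        n_days, float
    )


def compute_mmwt(bw_start, total_gain):
    """Metabolic mid-weight: (start weight + half the gain) ** 0.75."""
    mid = np.asarray(bw_start, float) + np.asarray(total_gain, float) / 2.0
    if np.any(mid <= 0):
        raise ValueError("mid-test body weight must be positive")
    return mid**METABOLIC_EXPONENT


def compute_fcr(energy_intake, weight_gain):
    """Feed conversion ratio: MJ ME consumed per kg of gain.

    Requires positive gain; an animal without gain has no defined conversion
    ratio and should be flagged by the caller rather than silently dropped.
    Zero intake with positive gain yields 0.
    """
    energy_intake = np.asarray(energy_intake, float)
    weight_gain = np.asarray(weight_gain, float)
    if np.any(weight_gain <= 0):
        raise ValueError("weight gain must be positive to compute FCR")
    return energy_intake / weight_gain


def classify_efficiency(rfi) -> np.ndarray | str:
    """Sign-based efficiency label: negative RFI -> efficient.

    An exact zero sits on the dichotomy boundary and is labelled
    ``"boundary"`` rather than forced into either class.
    """
    arr = np.asarray(rfi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("RFI values must be finite")
    out = np.where(arr < 0, "efficient", np.where(arr > 0, "inefficient", "boundary"))
    if np.isscalar(rfi) or arr.ndim == 0:
        return str(out)
    return out


def assign_season(period_start: _dt.date, period_end: _dt.date) -> int:
    """Season in which an animal spent most of its test period.

    Season 1 = May to October, season 2 = November to April; the period is
    inclusive of both end dates.  A tie (equal day counts) is assigned to
    season 1.
    """
    if period_end < period_start:
        raise ValueError("empty test period")
    days1 = 0
    days2 = 0
    day = period_start
    one = _dt.timedelta(days=1)
    while day <= period_end:
        if 5 <= day.month <= 10:
            days1 += 1
        else:
            days2 += 1
        day += one
    return 1 if days1 >= days2 else 2


@dataclass
class RfiResults:
    """Fit of the RFI regression.

    Attributes
    ----------
    beta0, beta1, beta2
        Intercept (MJ ME), regression on ADG (MJ ME per kg/day) and on MMWT
        (MJ ME per kg^0.75).
    rfi
        Per-animal residuals (MJ ME), indexed by animal id; the RFI values.
    r_squared
        Coefficient of determination of the regression.
    excluded
        Animal ids dropped for missing dEI/ADG/MMWT (no imputation).
    """

    beta0: float
    beta1: float
    beta2: float
    rfi: pd.Series
    bse: pd.Series
    r_squared: float
    excluded: list = field(default_factory=list)
    _sm_results: object | None = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            [self.beta0, self.beta1, self.beta2],
            index=["Intercept", "ADG", "MMWT"],
        )

    def classify(self) -> pd.Series:
        """Efficient / inefficient / boundary label per animal."""
        return pd.Series(
            classify_efficiency(self.rfi.to_numpy()), index=self.rfi.index
        )

    def summary(self):
        return self._sm_results.summary()


class RfiModel:
    """OLS model of daily energy intake on gain and metabolic mid-weight.

    Parameters
    ----------
    dei, adg, mmwt : array-like
        Trait vectors in MJ ME/day, kg/day and kg^0.75.
    animal_ids : sequence, optional
        Row labels; defaults to a range index.

    Animals with any missing regressand/regressor are excluded from the fit
    and reported on the results object.
    """

    def __init__(self, dei, adg, mmwt, animal_ids=None):
        dei = np.asarray(dei, float)
        adg = np.asarray(adg, float)
        mmwt = np.asarray(mmwt, float)
        if animal_ids is None:
            animal_ids = np.arange(len(dei))
        self.animal_ids = pd.Index(animal_ids)
        ok = np.isfinite(dei) & np.isfinite(adg) & np.isfinite(mmwt)
        self.excluded = list(self.animal_ids[~ok])
        self.dei = dei[ok]
        self.adg = adg[ok]
        self.mmwt = mmwt[ok]
        self.index = self.animal_ids[ok]
        if len(self.dei) < 4:
            raise ValueError("need at least 4 complete animals for the RFI fit")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dei="dEI", adg="ADG", mmwt="MMWT"):
        return cls(df[dei], df[adg], df[mmwt], animal_ids=df.index)

    def fit(self) -> RfiResults:
        X = pd.DataFrame(
            {"Intercept": 1.0, "ADG": self.adg, "MMWT": self.mmwt},
            index=self.index,
        )
        self._check_collinearity(X)
        res = sm.OLS(pd.Series(self.dei, index=self.index, name="dEI"), X).fit()
        return RfiResults(
            beta0=float(res.params["Intercept"]),
            beta1=float(res.params["ADG"]),
            beta2=float(res.params["MMWT"]),
            rfi=res.resid.rename("RFI"),
            bse=res.bse,
            r_squared=float(res.rsquared),
            excluded=self.excluded,
            _sm_results=res,
        )

    @staticmethod
    def _check_collinearity(X: pd.DataFrame) -> None:
        mat = X.to_numpy()
        rank = np.linalg.matrix_rank(mat)
        if rank == mat.shape[1]:
            return
        # identify an offending column: one whose removal restores full rank
        for col in X.columns:
            sub = X.drop(columns=col).to_numpy()
            if np.linalg.matrix_rank(sub) == sub.shape[1] == rank:
                raise CollinearDesignError(
                    f"RFI design is singular; column {col!r} is linearly "
                    "dependent on the others"
                )
        raise CollinearDesignError("RFI design is singular")


def fit_rfi_model(table: pd.DataFrame, dei="dEI", adg="ADG", mmwt="MMWT") -> RfiResults:
    """Fit the RFI regression on a phenotype table (convenience wrapper)."""
    return RfiModel.from_dataframe(table, dei=dei, adg=adg, mmwt=mmwt).fit()


def derive_phenotypes(table: pd.DataFrame) -> tuple[pd.DataFrame, RfiResults]:
    """Augment a raw phenotype table with the derived efficiency traits.

    Expects columns ``hay_kg_dm``, ``concentrate_kg_dm``, ``bw_start``,
    ``bw_end``, ``n_days``.  Adds ``dEI``, ``ADG``, ``MMWT``, ``RFI``,
    ``FCR`` and ``efficiency``; returns the augmented table and the RFI fit.
    """
    out = table.copy()
    out["dEI"] = compute_dei(
        out["hay_kg_dm"].to_numpy(),
        out["concentrate_kg_dm"].to_numpy(),
        out["n_days"].to_numpy(),
    )
    gain = out["bw_end"].to_numpy() - out["bw_start"].to_numpy()
    out["ADG"] = compute_adg(
        out["bw_start"].to_numpy(), out["bw_end"].to_numpy(), out["n_days"].to_numpy()
    )
    out["MMWT"] = compute_mmwt(out["bw_start"].to_numpy(), gain)
    fit = fit_rfi_model(out)
    out["RFI"] = fit.rfi.reindex(out.index)
    out["FCR"] = np.where(
        gain > 0, out["dEI"].to_numpy() * out["n_days"].to_numpy() / np.where(gain > 0, gain, np.nan), np.nan
    )
    out["efficiency"] = pd.Series(
        np.where(
            out["RFI"].notna(),
            np.where(out["RFI"] < 0, "efficient",
                     np.where(out["RFI"] > 0, "inefficient", "boundary")),
            None,
        ),
        index=out.index,
    )
    return out, fit
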