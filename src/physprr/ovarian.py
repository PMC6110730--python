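"""Age-corpora model fitting and the relative rate of reproductive senescence.

Cumulative corpora counts grow linearly in age when the ovulation rate
is constant; a concave quadratic indicates a declining rate, i.e.
reproductive senescence.  Model choice is by AIC between an ordinary
least-squares line and quadratic, with the line as the null; species
whose better model explains almost nothing (adjusted R^2 <= 0.1) are
classified as uninformative ("none").

Ovarian activity m(x) is the derivative of the fitted corpora curve,
clipped at zero (a negative derivative is an artefact of the quadratic
form).  The relative rate of reproductive senescence rho compares the
decline of activity, normalized to 1 at the age of first ovulation,
with age normalized to [0, 1] over the observed adult span: rho = 1
means activity reaches zero exactly at the oldest observed age, rho > 1
means cessation strictly before it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm

from .datasets import CorporaDataset

#: adjusted-R^2 threshold below which corpora are deemed uninformative about age
ADJ_R2_FLOOR = 0.1

#: the quadratic must beat the linear null by more than this many AIC units;
#: models within 2 units are treated as indistinguishable and parsimony wins
AIC_PREFERENCE_MARGIN = 2.0


@dataclass
class OvarianFit:
    """A fitted age-corpora model for one species."""

    model_kind: str  # "none" | "linear" | "quadratic"
    beta0: float
    beta1: float
    beta2: Optional[float]  # None for linear
    aic_linear: float
    aic_quadratic: float
    adj_r2_best: float
    age_first_ovulation: float  # aB
    age_max: float  # aMax
    n_records: int

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "aic_linear": self.aic_linear,
            "aic_quadratic": self.aic_quadratic,
            "adj_r2_best": self.adj_r2_best,
            "age_first_ovulation": self.age_first_ovulation,
            "age_max": self.age_max,
            "n_records": self.n_records,
        }


@dataclass
class ActivitySchedule:
    """Age-specific ovarian activity (ovulations/year) on an ordered grid."""

    ages: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.ages.ndim != 1 or self.ages.shape != self.activity.shape:
            raise ValueError("ages and activity must be matching 1-d arrays")
        if len(self.ages) < 2:
            raise ValueError("schedule needs at least two grid points")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("age grid must be strictly increasing")
        if np.any(self.activity < 0):
            raise ValueError("activity must be non-negative (clip before constructing)")


def truncate_to_first_ovulation(dataset: CorporaDataset) -> CorporaDataset:
    """Restrict records to ages at or above the age of first ovulation.

    The age of first ovulation is the minimum age at which any record
    has a non-zero corpora count; records at exactly that age with zero
    corpora are retained (they inform the intercept).
    """
    if dataset.n == 0:
        raise ValueError("empty dataset")
    corpora = dataset.corpora
    if not np.any(corpora > 0):
        raise ValueError(f"{dataset.species}: all corpora counts are zero; no first ovulation")
    first_age = dataset.ages[corpora > 0].min()
    return dataset.subset(dataset.ages >= first_age)


def fit_corpora_models(dataset: CorporaDataset) -> OvarianFit:
    """OLS fits of corpora ~ age and corpora ~ age + age^2, selected by AIC.

    The linear model is the null: the quadratic is selected only when
    it beats the line by more than ``AIC_PREFERENCE_MARGIN`` AIC units
    (models within 2 units are indistinguishable and parsimony wins)
    AND is concave — a convex quadratic implies accelerating ovulation,
    which is not the senescence alternative, so the null stands.  If
    the selected model's adjusted R^2 is at or below ``ADJ_R2_FLOOR``
    the species is classified ``none`` (corpora uninformative about
    age).
    """
    ages = dataset.ages
    corpora = dataset.corpora.astype(float)
    if len(ages) < 4:
        raise ValueError("need at least 4 records to compare linear and quadratic models")
    if len(np.unique(ages)) < 3:
        raise ValueError("need at least 3 distinct ages (quadratic unidentifiable)")

    x_lin = sm.add_constant(ages)
    x_quad = sm.add_constant(np.column_stack([ages, ages**2]))
    lin = sm.OLS(corpora, x_lin).fit()
    quad = sm.OLS(corpora, x_quad).fit()

    if quad.aic < lin.aic - AIC_PREFERENCE_MARGIN and quad.params[2] < 0:
        best, kind = quad, "quadratic"
    else:
        best, kind = lin, "linear"
    adj_r2 = float(best.rsquared_adj)
    if adj_r2 <= ADJ_R2_FLOOR:
        kind = "none"

    if best is quad:
        beta0, beta1, beta2 = (float(b) for b in quad.params)
    else:
        beta0, beta1 = (float(b) for b in lin.params)
        beta2 = None
    return OvarianFit(
        model_kind=kind,
        beta0=beta0,
        beta1=beta1,
        beta2=beta2,
        aic_linear=float(lin.aic),
        aic_quadratic=float(quad.aic),
        adj_r2_best=adj_r2,
        age_first_ovulation=float(ages.min()),
        age_max=float(ages.max()),
        n_records=len(ages),
    )


def ovarian_activity(fit: OvarianFit, ages: Optional[np.ndarray] = None) -> ActivitySchedule:
    """Derivative of the fitted corpora curve, clipped at zero.

    m(x) = max(0, beta1 + 2 beta2 x) for a quadratic fit, max(0, beta1)
    for a linear one, evaluated on [aB, aMax] (default: a dense grid).
    """
    if fit.model_kind == "none":
        raise ValueError("no informative age-corpora relationship; activity undefined")
    if ages is None:
        ages = np.linspace(fit.age_first_ovulation, fit.age_max, 513)
    ages = np.asarray(ages, dtype=float)
    if fit.model_kind == "quadratic":
        m = fit.beta1 + 2.0 * fit.beta2 * ages
    else:
        m = np.full_like(ages, fit.beta1)
    return ActivitySchedule(ages, np.maximum(m, 0.0))


def relative_senescence_rate(
    fit: OvarianFit,
    dataset: Optional[CorporaDataset] = None,
    exclude_ids=None,
) -> float:
    """Relative rate of reproductive senescence rho.

    Activity is normalized to 1 at the age of first ovulation aB and
    age to [0, 1] over [aB, aMax]; rho is the magnitude of the slope of
    the normalized activity: rho = 2 |beta2| (aMax - aB) / m(aB).
    rho = 1 iff activity reaches zero exactly at aMax; rho > 1 iff
    ovarian activity ceases before the somatic lifespan ends.

    If ``exclude_ids`` is given, the model is refitted on the truncated
    dataset without those records first (outlier sensitivity check).
    """
    if exclude_ids:
        if dataset is None:
            raise ValueError("dataset required to refit without excluded records")
        refit_ds = truncate_to_first_ovulation(dataset.drop_ids(exclude_ids))
        fit = fit_corpora_models(refit_ds)
    if fit.model_kind != "quadratic":
        raise ValueError("rho is defined only for a quadratic (senescent) fit")
    if fit.beta2 is None or fit.beta2 >= 0:
        raise ValueError("rho requires a concave fit (beta2 < 0)")
    a_b, a_max = fit.age_first_ovulation, fit.age_max
    m_ab = fit.beta1 + 2.0 * fit.beta2 * a_b
    if m_ab <= 0:
        raise ValueError("activity at the age of first ovulation must be positive")
    return 2.0 * abs(fit.beta2) * (a_max - a_b) / m_ab
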