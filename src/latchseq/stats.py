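"""Inferential layer: latch-preference tests, rank tests, model competition.

* ``chisq_uniform_gof`` — chi-square goodness of fit of latch counts
  against uniform use of the four latch types.
* ``mann_whitney`` — Mann-Whitney U comparison of dissimilarity or
  diversity samples, reported in the W (rank-sum minus offset)
  convention, exact by enumeration for small tie-free samples.
* ``fit_binomial_glm`` / ``forward_stepwise`` / ``lrt`` /
  ``akaike_weights`` — binomial (logistic) GLMs for predictors of
  problem-solving success, competed by forward stepwise selection with
  small-sample-corrected AIC, likelihood-ratio tests and Akaike weights.

The GLM itself is fitted with statsmodels (IRLS); this module owns the
model-competition bookkeeping around it.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "ModelFit",
    "ModelComparison",
    "SeparationError",
    "chisq_uniform_gof",
    "mann_whitney",
    "fit_binomial_glm",
    "forward_stepwise",
    "lrt",
    "akaike_weights",
]


@dataclass(frozen=True)
class TestResult:
    """A hypothesis-test outcome with the quantities the report prints."""

    statistic: float
    p_value: float
    method: str
    df: int | None = None
    n1: int | None = None
    n2: int | None = None
    tie_correction_applied: bool = False

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "df": self.df,
            "n1": self.n1,
            "n2": self.n2,
            "tie_correction_applied": self.tie_correction_applied,
        }


class SeparationError(ValueError):
    """Perfect separation: one or more coefficients diverge."""


@dataclass
class ModelFit:
    """A fitted binomial GLM with the quantities model competition needs."""

    name: str
    predictors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper (Wald, +-1.96 SE)
    llf: float
    deviance: float
    k: int
    n: int
    aic: float
    aicc: float

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "predictors": list(self.predictors),
            "coefficients": {
                p: {
                    "beta": float(self.params[p]),
                    "se": float(self.bse[p]),
                    "ci_lower": float(self.conf_int.loc[p, "lower"]),
                    "ci_upper": float(self.conf_int.loc[p, "upper"]),
                }
                for p in self.params.index
            },
            "log_likelihood": self.llf,
            "deviance": self.deviance,
            "k": self.k,
            "n": self.n,
            "AIC": self.aic,
            "AICc": self.aicc,
        }


@dataclass
class ModelComparison:
    """The set of models visited by a stepwise search, ranked by AICc."""

    fits: list[ModelFit]
    selected: str
    steps: list[dict] = field(default_factory=list)

    @property
    def table(self) -> pd.DataFrame:
        aicc = np.array([f.aicc for f in self.fits])
        delta = aicc - aicc.min()
        w = akaike_weights(aicc)
        return pd.DataFrame(
            {
                "model": [f.name for f in self.fits],
                "k": [f.k for f in self.fits],
                "AICc": aicc,
                "delta_AICc": delta,
                "weight": w,
            }
        ).sort_values("AICc", kind="stable").reset_index(drop=True)


def chisq_uniform_gof(counts) -> TestResult:
    """Chi-square goodness of fit of category counts against uniformity.

    ``chi2 = sum (O_i - E)^2 / E`` with ``E = n / #categories`` and
    ``df = #categories - 1``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two categories")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("all counts are zero")
    stat, p = sps.chisquare(counts)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        df=counts.size - 1,
        method="chi-square goodness of fit (uniform)",
    )


def mann_whitney(
    x, y, alternative: str = "two-sided", exact_max_n: int = 12
) -> TestResult:
    """Mann-Whitney U test reported in the W convention.

    The statistic is the rank sum of ``x`` minus ``n1 (n1 + 1) / 2``
    (identical to the U statistic of the first sample, and to the W that
    R's ``wilcox.test`` prints). The p-value is exact by enumeration when
    ``n1 + n2 <= exact_max_n`` and there are no ties, otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (x.size + y.size) <= exact_max_n and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(x.size),
        n2=int(y.size),
        method=f"Mann-Whitney U ({method})",
        tie_correction_applied=has_ties and not use_exact,
    )


def _design_matrix(
    X: pd.DataFrame, predictors: tuple[str, ...]
) -> pd.DataFrame:
    """Intercept plus dummy-coded predictor columns."""
    if predictors:
        sub = X[list(predictors)]
        sub = pd.get_dummies(sub, drop_first=True, dtype=float)
    else:
        sub = pd.DataFrame(index=X.index)
    sub = sub.astype(float)
    return sm.add_constant(sub, has_constant="add")


def fit_binomial_glm(
    X: pd.DataFrame,
    y,
    predictors: tuple[str, ...] | None = None,
    name: str | None = None,
) -> ModelFit:
    """Fit a logistic-link binomial GLM by IRLS and compute AIC / AICc.

    Categorical predictors are dummy-coded (first level as reference).
    Wald 95% confidence intervals are ``beta +- 1.96 SE``. ``AICc = AIC +
    2 k (k + 1) / (n - k - 1)`` requires ``n > k + 1``. Perfect separation
    raises :class:`SeparationError` naming the diverging coefficients.
    """
    y = np.asarray(y, dtype=float)
    if predictors is None:
        predictors = tuple(X.columns)
    design = _design_matrix(X, predictors)
    n, k = design.shape
    if n <= k:
        raise ValueError(f"n = {n} too small for {k} parameters")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        try:
            res = model.fit(maxiter=50, tol=1e-8)
        except Exception as e:  # statsmodels raises on hopeless separation
            raise SeparationError(f"GLM fit failed: {e}") from e
    sep_warned = any("separation" in str(w.message).lower() for w in caught)
    diverging = res.params[np.abs(res.params) > 15].index.tolist()
    if sep_warned or diverging:
        raise SeparationError(
            "perfect separation detected; diverging coefficients: "
            f"{diverging or 'flagged by fitter'}"
        )
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined: n = {n} <= k + 1 = {k + 1}"
        )
    aic = 2 * k - 2 * res.llf
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    ci = pd.DataFrame(
        {
            "lower": res.params - 1.96 * res.bse,
            "upper": res.params + 1.96 * res.bse,
        }
    )
    return ModelFit(
        name=name or ("null" if not predictors else " + ".join(predictors)),
        predictors=tuple(predictors),
        params=res.params,
        bse=res.bse,
        conf_int=ci,
        llf=float(res.llf),
        deviance=float(res.deviance),
        k=k,
        n=n,
        aic=float(aic),
        aicc=float(aicc),
    )


def lrt(fit_null: ModelFit, fit_full: ModelFit) -> TestResult:
    """Likelihood-ratio test of nested binomial GLMs.

    ``LRT = 2 (l_full - l_null) = deviance_null - deviance_full`` on
    ``k_full - k_null`` degrees of freedom. Tiny negative statistics from
    IRLS round-off are clipped to zero.
    """
    if fit_full.k <= fit_null.k:
        raise ValueError(
            "models are not nested: full model must estimate more "
            f"parameters ({fit_full.k} <= {fit_null.k})"
        )
    stat = max(0.0, fit_null.deviance - fit_full.deviance)
    df = fit_full.k - fit_null.k
    p = float(sps.chi2.sf(stat, df)) if stat > 0 else 1.0
    return TestResult(
        statistic=stat, p_value=p, df=df, method="likelihood-ratio test"
    )


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights: ``w_m = exp(-delta_m / 2) / sum_j exp(-delta_j / 2)``."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one criterion value")
    delta = a - a.min()
    w = np.exp(-delta / 2)
    return w / w.sum()


def forward_stepwise(
    X: pd.DataFrame,
    y,
    candidates: list[str] | None = None,
    criterion: str = "aicc",
) -> ModelComparison:
    """Greedy forward model competition from the intercept-only model.

    At each step every remaining candidate is added to the current model;
    the candidate giving the largest deviance reduction (ties broken by
    input order) is retained iff it lowers the selection criterion
    (AICc by default, AIC selectable), otherwise the search stops. The
    returned comparison holds every model on the visited path — including
    the final rejected step, so the evidence against it is on record —
    with delta-criterion values and Akaike weights.
    """
    if candidates is None:
        candidates = list(X.columns)
    if not candidates:
        raise ValueError("need at least one candidate predictor")
    if criterion not in ("aicc", "aic"):
        raise ValueError(f"unknown criterion {criterion!r}")

    def crit(f: ModelFit) -> float:
        return f.aicc if criterion == "aicc" else f.aic

    current = fit_binomial_glm(X, y, predictors=(), name="null")
    fits = [current]
    steps: list[dict] = []
    remaining = list(candidates)
    while remaining:
        trial_fits: list[ModelFit] = []
        for c in remaining:
            try:
                trial_fits.append(
                    fit_binomial_glm(
                        X, y, predictors=current.predictors + (c,)
                    )
                )
            except SeparationError:
                trial_fits.append(None)  # type: ignore[arg-type]
        best_i, best = None, None
        for i, f in enumerate(trial_fits):
            if f is None:
                continue
            if best is None or f.deviance < best.deviance - 1e-12:
                best_i, best = i, f
        if best is None:
            break
        step = {
            "added": remaining[best_i],
            "deviance_reduction": current.deviance - best.deviance,
            "criterion_before": crit(current),
            "criterion_after": crit(best),
            "lrt_vs_previous": lrt(current, best).as_dict(),
            "accepted": crit(best) < crit(current),
        }
        steps.append(step)
        fits.append(best)
        if not step["accepted"]:
            break
        remaining.pop(best_i)
        current = best
    return ModelComparison(fits=fits, selected=current.name, steps=steps)
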