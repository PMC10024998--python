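"""Beta regression of per-sample prediction accuracy on exposure time.

IPA values are means of 0/1 indicators and therefore live on [0, 1] with
mass at the endpoints.  Before regression they are compressed into the
open interval by the Smithson-Verkuilen transform

    IPA_beta = (IPA * (n - 1) + 0.5) / n,

where n is the number of observations entering the regression.  The
response is then modeled as Beta(mu * phi, (1 - mu) * phi) with
logit(mu) = b0 + b1 * week and constant precision phi, fitted by maximum
likelihood (via statsmodels' BetaModel).  A random-walk Metropolis sampler
with weakly informative normal priors is available for a Bayesian reading
of the same model; on well-behaved data its posterior means agree with the
ML estimates to within a standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .exceptions import NumericalError, ValidationError


def ipa_beta_transform(ipa, n: int):
    """Compress [0, 1] accuracies into (0, 1): (ipa * (n - 1) + 0.5) / n."""
    ipa = np.asarray(ipa, dtype=float)
    if n < 1:
        raise ValidationError("n must be >= 1")
    if np.any((ipa < 0) | (ipa > 1)):
        raise ValidationError("IPA values must lie in [0, 1]")
    return (ipa * (n - 1) + 0.5) / n


@dataclass
class BetaRegressionResults:
    """ML fit of the logit-link, constant-precision beta regression."""

    params: np.ndarray        # (intercept, slope) on the logit scale
    bse: np.ndarray
    conf_int_: np.ndarray     # (2, 2): rows = params, cols = lo/hi (95%)
    phi: float
    phi_se: float
    llf: float
    nobs: int
    converged: bool
    param_names: tuple[str, str] = ("intercept", "exposure_week")

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slope(self) -> float:
        return float(self.params[1])

    def conf_int(self) -> np.ndarray:
        return self.conf_int_

    def predict(self, weeks) -> np.ndarray:
        """Fitted mean accuracy (in (0, 1)) at the given exposure weeks."""
        weeks = np.asarray(weeks, dtype=float)
        return expit(self.params[0] + self.params[1] * weeks)

    def summary(self) -> str:
        lines = [
            "Beta regression (logit link, ML)",
            "=" * 56,
            f"observations: {self.nobs}    log-likelihood: {self.llf:.3f}"
            f"    converged: {self.converged}",
            "-" * 56,
            f"{'term':>14s}{'coef':>10s}{'se':>10s}{'[0.025':>10s}{'0.975]':>10s}",
        ]
        for name, p, se, (lo, hi) in zip(
            self.param_names, self.params, self.bse, self.conf_int_
        ):
            lines.append(f"{name:>14s}{p:10.4f}{se:10.4f}{lo:10.4f}{hi:10.4f}")
        lines.append(f"{'precision phi':>14s}{self.phi:10.3f}{self.phi_se:10.3f}")
        return "\n".join(lines)


def _beta_loglik(y: np.ndarray, x: np.ndarray, b0: float, b1: float, phi: float) -> float:
    mu = expit(b0 + b1 * x)
    a = mu * phi
    b = (1.0 - mu) * phi
    return float(
        np.sum(
            gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y)
        )
    )


class BetaRegression:
    """Beta regression model: response in (0, 1) on one numeric predictor.

    Build from arrays, or from a tidy DataFrame with
    :meth:`from_dataframe`.  ``fit()`` returns
    :class:`BetaRegressionResults`; ``sample_posterior()`` runs the
    optional Metropolis sampler.
    """

    def __init__(self, endog, exog):
        y = np.asarray(endog, dtype=float)
        x = np.asarray(exog, dtype=float)
        if y.ndim != 1 or x.ndim != 1 or y.size != x.size:
            raise ValidationError("endog and exog must be 1-D of equal length")
        if y.size < 10:
            raise ValidationError("need at least 10 observations")
        if np.any((y <= 0) | (y >= 1)):
            raise ValidationError(
                "responses must lie strictly in (0, 1); apply ipa_beta_transform first"
            )
        self.endog, self.exog = y, x

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str = "ipa",
        predictor: str = "exposure_week",
        transform_n: int | None = None,
    ) -> "BetaRegression":
        """Construct from a tidy frame, optionally applying the endpoint transform.

        With ``transform_n`` given (or defaulting to the number of rows),
        the response column is passed through :func:`ipa_beta_transform`
        first — the natural path for raw IPA values.
        """
        sub = df[[response, predictor]].dropna()
        y = sub[response].to_numpy(dtype=float)
        if transform_n is not None or np.any((y <= 0) | (y >= 1)):
            n = transform_n if transform_n is not None else len(y)
            y = ipa_beta_transform(y, n)
        return cls(y, sub[predictor].to_numpy(dtype=float))

    def fit(self) -> BetaRegressionResults:
        from statsmodels.othermod.betareg import BetaModel
        import statsmodels.api as sm

        exog = sm.add_constant(self.exog)
        model = BetaModel(self.endog, exog)
        with np.errstate(all="ignore"):
            res = model.fit(disp=False)
        params = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(params)):
            raise NumericalError("beta regression produced non-finite estimates")
        converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
        bse = np.asarray(res.bse, dtype=float)
        ci = np.asarray(res.conf_int(), dtype=float)
        # last parameter is log-precision (log link)
        phi = float(np.exp(params[-1]))
        phi_se = float(phi * bse[-1])  # delta method
        return BetaRegressionResults(
            params=params[:2],
            bse=bse[:2],
            conf_int_=ci[:2],
            phi=phi,
            phi_se=phi_se,
            llf=float(res.llf),
            nobs=int(self.endog.size),
            converged=converged,
        )

    def sample_posterior(
        self,
        n_draws: int = 4000,
        burn: int = 1000,
        seed: int = 0,
        prior_sd: float = 5.0,
        start: BetaRegressionResults | None = None,
    ) -> dict:
        """Random-walk Metropolis for (b0, b1, log phi) with N(0, prior_sd^2)
        priors on the coefficients and N(log 10, 3^2) on log phi.

        Returns draws and posterior means; proposal scales follow the ML
        standard errors.
        """
        rng = np.random.default_rng(seed)
        ml = start if start is not None else self.fit()
        theta = np.array([ml.intercept, ml.slope, np.log(ml.phi)])
        step = np.array([max(ml.bse[0], 1e-3), max(ml.bse[1], 1e-3),
                         max(ml.phi_se / max(ml.phi, 1e-8), 1e-3)])
        y, x = self.endog, self.exog

        def logpost(t):
            ll = _beta_loglik(y, x, t[0], t[1], np.exp(t[2]))
            lp = (
                -0.5 * (t[0] ** 2 + t[1] ** 2) / prior_sd**2
                - 0.5 * ((t[2] - np.log(10.0)) ** 2) / 9.0
            )
            return ll + lp

        lp = logpost(theta)
        draws = np.empty((n_draws, 3))
        accepted = 0
        for i in range(n_draws):
            prop = theta + rng.normal(0.0, step)
            lp_prop = logpost(prop)
            if np.log(rng.uniform()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                accepted += 1
            draws[i] = theta
        kept = draws[burn:]
        return {
            "draws": kept,
            "mean": kept.mean(axis=0),
            "sd": kept.std(axis=0, ddof=1),
            "acceptance_rate": accepted / n_draws,
            "param_names": ("intercept", "exposure_week", "log_phi"),
        }


def fit_ipa_regressions(
    ipa_table: pd.DataFrame,
    metadata: pd.DataFrame,
    transform_n: int | None = None,
) -> pd.DataFrame:
    """Per-species beta regressions of IPA on exposure week.

    Joins the rdMCCV IPA table with sample metadata, transforms IPA, and
    fits one regression per species over its exposed samples (week 0-6).
    Returns a tidy frame of estimates; species with too few exposed
    samples or failed fits are reported with NaN estimates and a reason.
    """
    merged = ipa_table.merge(metadata, on="sample_id", how="inner")
    rows = []
    for sp, grp in merged.groupby("species"):
        sub = grp.dropna(subset=["exposure_week"])
        row = {"species": sp, "n": len(sub)}
        if len(sub) < 10:
            row.update(slope=np.nan, reason="fewer than 10 exposed samples")
            rows.append(row)
            continue
        n_tr = transform_n if transform_n is not None else len(sub)
        try:
            fit = BetaRegression(
                ipa_beta_transform(sub["ipa"].to_numpy(), n_tr),
                sub["exposure_week"].to_numpy(dtype=float),
            ).fit()
        except (NumericalError, ValidationError) as exc:
            row.update(slope=np.nan, reason=str(exc))
            rows.append(row)
            continue
        (lo_i, hi_i), (lo_s, hi_s) = fit.conf_int()
        row.update(
            intercept=fit.intercept,
            slope=fit.slope,
            slope_se=float(fit.bse[1]),
            slope_lo=lo_s,
            slope_hi=hi_s,
            phi=fit.phi,
            converged=fit.converged,
            reason="",
        )
        rows.append(row)
    return pd.DataFrame(rows)
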