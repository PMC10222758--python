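"""GLM normalization of heterogeneous morphological parameters.

Each of the ~501 CalMorph parameters lives on its own scale and
distribution family (continuous, positive, proportion-valued, or a ratio
of counted cells).  To make them comparable, every parameter is fitted
with a family-appropriate generalized linear model with strain as the only
factor and a designated reference strain as the intercept, and each
sample or strain is re-expressed as a Wald Z-value — its standardized
deviation from the reference (or from its parent strain).

Families and links: gaussian/identity, gamma/log, beta/logit (joint ML of
mean and precision), binomial/logit (observed trial counts as variance
weights when known, else quasi-binomial).  The gaussian path is a
closed-form least-squares solve, vectorized across parameters; it is
numerically identical to a per-parameter OLS fit.

Two Z modes:

``per_strain``
    Z = (eta_s - eta_b) / SE of the contrast — the Wald test of strain s
    against baseline b from the fitted coefficient covariance.
``per_replicate``
    Z_i = (y_i - mu_b) / sd_Y(mu_b) — each replicate's deviation from the
    fitted baseline-strain mean, standardized by the family's plug-in
    single-observation SD at that mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import LineageDesign
from .io import MorphologyMatrix


class GLMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# strain-factor fits


@dataclass
class GLMFit:
    """A fitted per-parameter GLM with strain as the factor.

    ``coefficients`` are on the link scale: ``Intercept`` is the reference
    strain, the other entries are contrasts strain-minus-reference.
    ``link_means``/``response_means`` give each strain's fitted linear
    predictor and mean; ``obs_sd`` the plug-in SD of one observation at
    that strain's fitted mean.
    """

    parameter: str
    family: str
    coefficients: pd.Series
    covariance: pd.DataFrame
    converged: bool
    degenerate: bool
    deviance: float
    llf: float
    scale: float
    link_means: pd.Series
    response_means: pd.Series
    obs_sd: pd.Series
    n_obs: int
    counts: pd.Series

    def contrast(self, strain: str, baseline: str) -> tuple[float, float]:
        """(estimate, SE) of the link-scale contrast strain - baseline."""
        if strain == baseline:
            return 0.0, 0.0
        ref = self.coefficients.index[0]  # "Intercept"

        def key(s: str) -> Optional[str]:
            return None if s == self._ref_strain else f"strain[{s}]"

        ks, kb = key(strain), key(baseline)
        est = 0.0
        var = 0.0
        if ks is not None:
            est += self.coefficients[ks]
            var += self.covariance.loc[ks, ks]
        if kb is not None:
            est -= self.coefficients[kb]
            var += self.covariance.loc[kb, kb]
        if ks is not None and kb is not None:
            var -= 2.0 * self.covariance.loc[ks, kb]
        return float(est), float(np.sqrt(max(var, 0.0)))

    def wald_z(self, strain: str, baseline: str) -> float:
        """Wald Z of the contrast; 0 for an exactly-null degenerate contrast
        (identical groups), NaN when the SE is 0 but the estimate is not."""
        est, se = self.contrast(strain, baseline)
        if se == 0.0:
            return 0.0 if est == 0.0 else np.nan
        return est / se

    @property
    def _ref_strain(self) -> str:
        return self.link_means.index[0]


def _family_obs_sd(family: str, mu: np.ndarray, scale: float,
                   precision: Optional[float] = None,
                   trials: Optional[float] = None) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if family == "gaussian":
        return np.full_like(mu, np.sqrt(scale))
    if family == "gamma":
        return np.sqrt(scale) * mu
    if family == "beta":
        assert precision is not None
        return np.sqrt(mu * (1.0 - mu) / (1.0 + precision))
    if family == "binomial":
        v = mu * (1.0 - mu)
        if trials is not None:
            return np.sqrt(v * scale / trials)
        return np.sqrt(v * scale)
    raise GLMError(f"unknown family {family!r}")


def fit_parameter_glm(
    values: Sequence[float],
    strain_labels: Sequence[str],
    family: str,
    reference: str,
    trials: Optional[float] = None,
) -> GLMFit:
    """ML fit of ``value ~ strain`` with ``reference`` as the intercept.

    Missing values are dropped pairwise.  A parameter whose non-missing
    values are all identical is flagged ``degenerate`` (estimable mean,
    no usable dispersion) rather than rejected.
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(strain_labels, dtype=object)
    keep = np.isfinite(y)
    y, labels = y[keep], labels[keep]
    strains_present = list(dict.fromkeys(labels))
    if reference not in strains_present:
        raise GLMError(f"reference strain {reference!r} has no observations")
    strains = [reference] + [s for s in strains_present if s != reference]
    if len(strains) < 2:
        raise GLMError("need >= 2 strains with observations")
    counts = pd.Series({s: int(np.sum(labels == s)) for s in strains})
    if (counts < 2).any():
        warnings.warn(
            f"strains with < 2 replicates: "
            f"{list(counts.index[counts < 2])}", stacklevel=2
        )
    _check_support(y, family, parameter=None, labels=labels)

    coef_index = ["Intercept"] + [f"strain[{s}]" for s in strains[1:]]
    X = np.zeros((len(y), len(strains)))
    X[:, 0] = 1.0
    for j, s in enumerate(strains[1:], start=1):
        X[:, j] = (labels == s).astype(float)

    degenerate = bool(np.ptp(y) == 0.0)

    if family == "gaussian":
        means = np.array([y[labels == s].mean() for s in strains])
        fitted = means[0] + X[:, 1:] @ (means[1:] - means[0])
        ssr = float(np.sum((y - fitted) ** 2))
        dof = len(y) - len(strains)
        scale = ssr / dof if dof > 0 else np.nan
        xtx_inv = np.linalg.inv(X.T @ X)
        cov = scale * xtx_inv
        coefs = np.concatenate([[means[0]], means[1:] - means[0]])
        s2_ml = ssr / len(y) if len(y) else np.nan
        llf = (
            -0.5 * len(y) * (np.log(2 * np.pi * s2_ml) + 1.0)
            if s2_ml > 0 else np.inf
        )
        eta = pd.Series(means, index=strains)
        mu = eta.copy()
        obs_sd = pd.Series(
            _family_obs_sd("gaussian", mu.to_numpy(), scale), index=strains
        )
        return GLMFit(
            parameter="", family=family,
            coefficients=pd.Series(coefs, index=coef_index),
            covariance=pd.DataFrame(cov, index=coef_index, columns=coef_index),
            converged=True, degenerate=degenerate,
            deviance=ssr, llf=float(llf), scale=float(scale),
            link_means=eta, response_means=mu, obs_sd=obs_sd,
            n_obs=len(y), counts=counts,
        )

    precision: Optional[float] = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "gamma":
            model = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log()))
            res = model.fit()
            params, cov = res.params, res.cov_params()
            converged = bool(res.converged)
            deviance, llf, scale = res.deviance, res.llf, float(res.scale)
        elif family == "beta":
            from statsmodels.othermod.betareg import BetaModel

            model = BetaModel(y, X)
            res = model.fit(disp=False)
            converged = bool(res.mle_retvals.get("converged", True))
            k = X.shape[1]
            params = res.params[:k]
            cov = np.asarray(res.cov_params())[:k, :k]
            precision = float(np.exp(res.params[k]))  # log-link precision
            deviance, llf, scale = np.nan, float(res.llf), 1.0
        elif family == "binomial":
            if trials is not None:
                w = np.full(len(y), float(trials))
                res = sm.GLM(y, X, family=sm.families.Binomial(),
                             var_weights=w).fit()
                scale = 1.0
            else:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(scale="X2")
                scale = float(res.scale)
            params, cov = res.params, res.cov_params()
            converged = bool(res.converged)
            deviance, llf = res.deviance, res.llf
        else:
            raise GLMError(f"unknown family {family!r}")

    params = np.asarray(params, dtype=float)
    cov = np.asarray(cov, dtype=float)
    eta_vals = params[0] + np.concatenate([[0.0], params[1:]])
    eta = pd.Series(eta_vals, index=strains)
    if family == "gamma":
        mu = np.exp(eta)
    else:
        mu = pd.Series(stats.logistic.cdf(eta.to_numpy()), index=strains)
    obs_sd = pd.Series(
        _family_obs_sd(family, np.asarray(mu, dtype=float), scale,
                       precision=precision, trials=trials),
        index=strains,
    )
    return GLMFit(
        parameter="", family=family,
        coefficients=pd.Series(params, index=coef_index),
        covariance=pd.DataFrame(cov, index=coef_index, columns=coef_index),
        converged=converged, degenerate=degenerate,
        deviance=float(deviance) if np.isfinite(deviance) else np.nan,
        llf=float(llf), scale=float(scale),
        link_means=eta, response_means=pd.Series(np.asarray(mu), index=strains),
        obs_sd=obs_sd, n_obs=len(y), counts=counts,
    )


def _check_support(y: np.ndarray, family: str, parameter: Optional[str],
                   labels: Optional[np.ndarray] = None) -> None:
    bad = None
    if family == "gamma":
        bad = y <= 0
    elif family == "beta":
        bad = (y <= 0) | (y >= 1)
    elif family == "binomial":
        bad = (y < 0) | (y > 1)
    if bad is not None and bad.any():
        i = int(np.argmax(bad))
        where = f" (sample {labels[i]!r})" if labels is not None else ""
        pname = f" {parameter!r}" if parameter else ""
        raise GLMError(
            f"value {y[i]!r} outside {family} support for parameter{pname}{where}"
        )


# ---------------------------------------------------------------------------
# Z matrices


@dataclass
class ZMatrix:
    """Wald Z-values per sample (or strain) per parameter.

    ``mode`` is ``per_replicate`` or ``per_strain``; ``baseline`` is
    ``global_reference`` or ``parent_strain``.  ``excluded`` lists
    parameters dropped as degenerate (zero variance) or non-converged.
    """

    values: pd.DataFrame
    mode: str
    baseline: str
    reference: str
    excluded: tuple[str, ...] = ()
    strains: Optional[pd.Series] = None

    @property
    def parameter_names(self) -> list[str]:
        return list(self.values.columns)

    def usable(self) -> pd.DataFrame:
        """Columns with no missing values (the PCA-ready subset)."""
        keep = [c for c in self.values.columns
                if c not in self.excluded and not self.values[c].isna().any()]
        return self.values[keep]

    def strain_means(self) -> "ZMatrix":
        """Collapse a per-replicate matrix to strain-level mean Z rows."""
        if self.mode != "per_replicate":
            raise GLMError("strain_means requires a per_replicate matrix")
        assert self.strains is not None
        grouped = self.values.groupby(self.strains, sort=False).mean()
        grouped.index.name = "strain"
        return ZMatrix(grouped, "per_strain", self.baseline, self.reference,
                       self.excluded)


def _baseline_strain(design: LineageDesign, strain: str, baseline: str) -> str:
    if baseline == "global_reference":
        return design.reference
    parent = design.parent_of[strain]
    return parent if parent is not None else strain


def compute_z_matrix(
    data: MorphologyMatrix,
    design: LineageDesign,
    family_map: Mapping[str, str],
    mode: str = "per_replicate",
    baseline: str = "global_reference",
    trials: Optional[Mapping[str, float]] = None,
) -> ZMatrix:
    """Standardize every parameter into Wald Z-values.

    ``baseline='global_reference'`` contrasts every strain against the
    design's reference strain (the study intercept); ``'parent_strain'``
    contrasts each strain against its immediate parent (original strains,
    having no parent, are centered on their own mean).
    """
    if mode not in ("per_replicate", "per_strain"):
        raise GLMError(f"unknown mode {mode!r}")
    if baseline not in ("global_reference", "parent_strain"):
        raise GLMError(f"unknown baseline {baseline!r}")
    trials = dict(trials or {})
    missing_fam = [p for p in data.parameter_names if p not in family_map]
    if missing_fam:
        raise GLMError(f"no family for parameters: {missing_fam[:5]}")

    strain_of = data.strains
    strain_order = [s for s in design.strains if (strain_of == s).any()]
    excluded: list[str] = []
    cols: dict[str, np.ndarray] = {}
    if mode == "per_replicate":
        out_index = data.values.index
    else:
        out_index = pd.Index(strain_order, name="strain")

    for pname in data.parameter_names:
        y = data.values[pname]
        try:
            fit = fit_parameter_glm(
                y.to_numpy(), strain_of.to_numpy(), family_map[pname],
                design.reference, trials=trials.get(pname),
            )
        except GLMError as exc:
            if "support" in str(exc):
                raise
            excluded.append(pname)
            cols[pname] = np.full(len(out_index), np.nan)
            continue
        if fit.degenerate or not fit.converged:
            excluded.append(pname)
            cols[pname] = np.full(len(out_index), np.nan)
            continue
        low_n = set(fit.counts.index[fit.counts < 2])
        if low_n:
            warnings.warn(
                f"parameter {pname!r}: strains {sorted(low_n)} have < 2 "
                "replicates; their Z is set to missing", stacklevel=2
            )
        if mode == "per_strain":
            z = np.full(len(strain_order), np.nan)
            for i, s in enumerate(strain_order):
                b = _baseline_strain(design, s, baseline)
                if s in low_n or b in low_n:
                    continue
                if s == b:
                    z[i] = 0.0
                    continue
                est, se = fit.contrast(s, b)
                z[i] = est / se if se > 0 else np.nan
            cols[pname] = z
        else:
            z = np.full(len(out_index), np.nan)
            yv = y.to_numpy(dtype=float)
            for i, (sid, s) in enumerate(zip(data.values.index, strain_of)):
                if not np.isfinite(yv[i]) or s in low_n:
                    continue
                b = _baseline_strain(design, s, baseline)
                if b in low_n or b not in fit.response_means.index:
                    continue
                sd = fit.obs_sd[b]
                if not sd > 0:
                    continue
                z[i] = (yv[i] - fit.response_means[b]) / sd
            cols[pname] = z

    values = pd.DataFrame(cols, index=out_index)
    strains_out = strain_of.copy() if mode == "per_replicate" else None
    return ZMatrix(values, mode, baseline, design.reference,
                   tuple(excluded), strains_out)


# ---------------------------------------------------------------------------
# design-matrix fits (shared by the step-effect and HMA tests)


@dataclass
class DesignFit:
    """A GLM fitted against an arbitrary design matrix, with per-column
    Wald statistics and an omnibus test against the intercept-only model."""

    params: pd.Series
    bse: pd.Series
    z: pd.Series
    p: pd.Series
    covariance: pd.DataFrame
    converged: bool
    scale: float
    llf: float
    deviance: float
    lrt_stat: float
    lrt_p: float
    lrt_df: int


def fit_design_glm(
    y: np.ndarray,
    X: pd.DataFrame,
    family: str,
    trials: Optional[float] = None,
) -> DesignFit:
    """Fit ``y ~ X`` for one parameter and test the full model against the
    intercept-only null.

    The omnibus statistic is the exact-likelihood LRT for gaussian and
    beta (and weighted binomial), and the scaled-deviance quasi-LRT
    (D0 - D1)/phi for gamma and quasi-binomial; all are referred to a
    chi-square with df = number of non-intercept columns.
    """
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    Xv = X.to_numpy(dtype=float)[keep]
    names = list(X.columns)
    n, k = Xv.shape
    df = k - 1
    _check_support(y, family, parameter=None)

    if family == "gaussian":
        return _gaussian_design_fit(y, Xv, names)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "gamma":
            fam = sm.families.Gamma(sm.families.links.Log())
            res = sm.GLM(y, Xv, family=fam).fit()
            res0 = sm.GLM(y, np.ones((n, 1)), family=fam).fit()
            scale = float(res.scale)
            lrt = (res0.deviance - res.deviance) / scale
            converged = bool(res.converged and res0.converged)
            params, cov = res.params, res.cov_params()
            llf, deviance = float(res.llf), float(res.deviance)
        elif family == "beta":
            from statsmodels.othermod.betareg import BetaModel

            res = BetaModel(y, Xv).fit(disp=False)
            res0 = BetaModel(y, np.ones((n, 1))).fit(disp=False)
            lrt = 2.0 * (res.llf - res0.llf)
            converged = bool(res.mle_retvals.get("converged", True)
                             and res0.mle_retvals.get("converged", True))
            params = res.params[:k]
            cov = np.asarray(res.cov_params())[:k, :k]
            scale, llf, deviance = 1.0, float(res.llf), np.nan
        elif family == "binomial":
            fam = sm.families.Binomial()
            if trials is not None:
                w = np.full(n, float(trials))
                res = sm.GLM(y, Xv, family=fam, var_weights=w).fit()
                res0 = sm.GLM(y, np.ones((n, 1)), family=fam, var_weights=w).fit()
                scale = 1.0
                lrt = res0.deviance - res.deviance
            else:
                res = sm.GLM(y, Xv, family=fam).fit(scale="X2")
                res0 = sm.GLM(y, np.ones((n, 1)), family=fam).fit(scale="X2")
                scale = float(res.scale)
                lrt = (res0.deviance - res.deviance) / scale
            converged = bool(res.converged and res0.converged)
            params, cov = res.params, res.cov_params()
            llf, deviance = float(res.llf), float(res.deviance)
        else:
            raise GLMError(f"unknown family {family!r}")

    params = pd.Series(np.asarray(params, dtype=float), index=names)
    cov = pd.DataFrame(np.asarray(cov, dtype=float), index=names, columns=names)
    bse = pd.Series(np.sqrt(np.maximum(np.diag(cov), 0.0)), index=names)
    zvals = params / bse.replace(0.0, np.nan)
    pvals = pd.Series(2.0 * stats.norm.sf(np.abs(zvals)), index=names)
    lrt = float(max(lrt, 0.0))
    lrt_p = float(stats.chi2.sf(lrt, df)) if df > 0 else 1.0
    return DesignFit(params, bse, zvals, pvals, cov, converged, scale,
                     llf, deviance, lrt, lrt_p, df)


def _gaussian_design_fit(y: np.ndarray, Xv: np.ndarray,
                         names: list[str]) -> DesignFit:
    n, k = Xv.shape
    xtx_inv = np.linalg.pinv(Xv.T @ Xv)
    beta = xtx_inv @ Xv.T @ y
    resid = y - Xv @ beta
    ssr = float(resid @ resid)
    dof = n - k
    scale = ssr / dof if dof > 0 else np.nan
    cov = scale * xtx_inv
    ssr0 = float(np.sum((y - y.mean()) ** 2))
    lrt = n * np.log(ssr0 / ssr) if ssr > 0 else np.inf
    s2_ml = ssr / n
    llf = -0.5 * n * (np.log(2 * np.pi * s2_ml) + 1.0) if s2_ml > 0 else np.inf
    params = pd.Series(beta, index=names)
    covdf = pd.DataFrame(cov, index=names, columns=names)
    bse = pd.Series(np.sqrt(np.maximum(np.diag(cov), 0.0)), index=names)
    zvals = params / bse.replace(0.0, np.nan)
    pvals = pd.Series(2.0 * stats.norm.sf(np.abs(zvals)), index=names)
    df = k - 1
    lrt_p = float(stats.chi2.sf(lrt, df)) if df > 0 else 1.0
    return DesignFit(params, bse, zvals, pvals, covdf, True, float(scale),
                     float(llf), ssr, float(max(lrt, 0.0)), lrt_p, df)


def gaussian_design_batch(
    Y: pd.DataFrame, X: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Vectorized OLS of every column of ``Y`` against ``X``.

    Returns (coefficients, Wald z, omnibus LRT statistic, LRT p) with one
    row/entry per column of Y.  Requires complete columns; identical to
    :func:`fit_design_glm` per column up to floating-point roundoff.
    """
    Xv = X.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)
    if np.isnan(Yv).any():
        raise GLMError("gaussian_design_batch requires complete columns")
    n, k = Xv.shape
    xtx_inv = np.linalg.pinv(Xv.T @ Xv)
    B = xtx_inv @ Xv.T @ Yv                      # k x m
    resid = Yv - Xv @ B
    ssr = np.sum(resid**2, axis=0)
    dof = n - k
    scale = ssr / dof
    se = np.sqrt(np.outer(np.maximum(np.diag(xtx_inv), 0.0), scale))
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = B / se
    ssr0 = np.sum((Yv - Yv.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrt = n * np.log(ssr0 / ssr)
    lrt = np.where(ssr > 0, np.maximum(lrt, 0.0), np.inf)
    lrt_p = stats.chi2.sf(lrt, k - 1)
    cols = Y.columns
    coefs = pd.DataFrame(B.T, index=cols, columns=X.columns)
    zdf = pd.DataFrame(Z.T, index=cols, columns=X.columns)
    return coefs, zdf, pd.Series(lrt, index=cols), pd.Series(lrt_p, index=cols)
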