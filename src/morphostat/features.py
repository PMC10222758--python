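"""Two-step successive PCA: naming the parameters behind each leading PC.

Step one decomposes the strain-level mean Z-matrix by covariance PCA and
keeps the leading components (90% cumulative variance in the study, eight
PCs).  Each morphological parameter is then screened against each kept
PC's scores by Pearson correlation with a Benjamini-Hochberg FDR gate per
PC.  Step two re-decomposes, within each PC's correlated parameter set,
the Z-values of the reference strain's replicates alone, and keeps as
*representative* the parameters significantly correlated with the leading
second-step components (uncorrelation t-test, Bonferroni-corrected over
the tested set).

The second step uses replicate-level variation of a single strain, so it
separates parameters that co-vary through shared cell biology from
parameters that merely respond to the same strain contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glm import ZMatrix
from .pca import PCAError, PCSpace, pca_covariance, select_pcs

logger = logging.getLogger(__name__)


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p of the exact t-test of zero Pearson correlation
    (t = r sqrt((n-2)/(1-r^2)), n-2 df)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    if n <= 2:
        return np.full_like(r, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.isfinite(t), p, 0.0)  # |r| == 1 -> p = 0


def first_step_pca(
    z_strain_means: Union[ZMatrix, pd.DataFrame],
    variance_threshold: float = 0.90,
) -> PCSpace:
    """Covariance PCA of strain-level mean Z-values (one row per strain)."""
    return pca_covariance(z_strain_means, threshold=variance_threshold)


def screen_correlated(
    space: PCSpace,
    z: Union[ZMatrix, pd.DataFrame],
    fdr_level: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per selected PC: parameters significantly correlated with its scores.

    Pearson correlation of every parameter's Z column against the PC
    score vector, two-sided uncorrelation test, Benjamini-Hochberg FDR
    within each PC.  Constant parameter columns are excluded (correlation
    undefined) with a log entry.
    """
    X = z.usable() if isinstance(z, ZMatrix) else z
    if not X.index.equals(space.scores.index):
        raise PCAError("scores and Z-matrix rows are not aligned")
    n = len(X)
    sd = X.std(axis=0, ddof=1)
    constant = list(sd.index[sd == 0.0])
    if constant:
        logger.warning(
            "screen_correlated: %d constant parameter(s) excluded: %s",
            len(constant), constant[:5],
        )
    cols = [c for c in X.columns if c not in constant]
    Xc = X[cols] - X[cols].mean(axis=0)
    out: dict[str, pd.DataFrame] = {}
    for pc in space.component_names[: space.n_selected]:
        s = space.scores[pc] - space.scores[pc].mean()
        denom = np.sqrt((Xc**2).sum(axis=0) * (s**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc.T @ s) / denom
        p = correlation_pvalue(r.to_numpy(), n)
        rej, q, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
        df = pd.DataFrame(
            {"parameter": cols, "r": r.to_numpy(), "p": p, "q": q,
             "selected": rej}
        )
        out[pc] = df[df["selected"]].drop(columns="selected").reset_index(
            drop=True)
    return out


def second_step_pca(
    correlated_set: Sequence[str],
    reference_replicate_z: Union[ZMatrix, pd.DataFrame],
    alpha: float = 0.01,
    variance_threshold: float = 0.60,
) -> pd.DataFrame:
    """Representative parameters of one correlated set.

    Covariance PCA of the reference strain's replicate Z-values restricted
    to the set; a parameter is representative when its correlation with
    any retained second-step PC (components covering ``variance_threshold``
    of the variance) rejects the zero-correlation null at ``alpha`` after
    Bonferroni correction over the set size.

    Returns one row per parameter: best |r|, its component, Bonferroni p,
    representative flag.  A singleton set is trivially representative.
    """
    params = list(correlated_set)
    if not params:
        raise PCAError("correlated set is empty")
    Z = (reference_replicate_z.usable()
         if isinstance(reference_replicate_z, ZMatrix)
         else reference_replicate_z)
    missing = [p for p in params if p not in Z.columns]
    if missing:
        raise PCAError(f"parameters absent from reference Z: {missing[:5]}")
    if len(Z) < 3:
        raise PCAError("need >= 3 reference replicates")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if len(params) == 1:
        logger.warning(
            "second_step_pca: singleton set %r is trivially representative",
            params[0],
        )
        return pd.DataFrame(
            {"parameter": params, "component": ["PC1"], "r": [1.0],
             "p_bonferroni": [0.0], "representative": [alpha > 0.0],
             "degenerate": [True]}
        )

    sub = Z[params]
    space = pca_covariance(sub, threshold=variance_threshold)
    n = len(sub)
    kept = space.component_names[: space.n_selected]
    m = len(params)
    best_r = pd.Series(0.0, index=params)
    best_pc = pd.Series("", index=params)
    best_p = pd.Series(1.0, index=params)
    Xc = sub - sub.mean(axis=0)
    for pc in kept:
        s = space.scores[pc] - space.scores[pc].mean()
        denom = np.sqrt((Xc**2).sum(axis=0) * (s**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc.T @ s) / denom
        p = np.minimum(correlation_pvalue(r.to_numpy(), n) * m, 1.0)
        better = p < best_p.to_numpy()
        best_r[better] = r[better]
        best_p[better] = p[better]
        best_pc[better] = pc
    return pd.DataFrame(
        {"parameter": params, "component": best_pc.to_numpy(),
         "r": best_r.to_numpy(), "p_bonferroni": best_p.to_numpy(),
         "representative": best_p.to_numpy() < alpha,
         "degenerate": False}
    )


@dataclass
class FeatureReport:
    """Per first-step PC: correlated and representative parameters."""

    space: PCSpace
    correlated: dict[str, pd.DataFrame]
    representative: dict[str, pd.DataFrame]
    variance_covered_first: float
    variance_covered_second: dict[str, float]

    def representative_names(self, pc: str) -> list[str]:
        df = self.representative.get(pc)
        if df is None or df.empty:
            return []
        return list(df.loc[df["representative"], "parameter"])

    def to_json_dict(self) -> dict:
        return {
            "n_selected": self.space.n_selected,
            "variance_covered_first": self.variance_covered_first,
            "per_pc": {
                pc: {
                    "correlated": list(self.correlated.get(pc, pd.DataFrame(
                        columns=["parameter"]))["parameter"]),
                    "representative": self.representative_names(pc),
                    "variance_covered_second":
                        self.variance_covered_second.get(pc),
                }
                for pc in self.space.component_names[: self.space.n_selected]
            },
        }


def extract_features(
    z_strain_means: Union[ZMatrix, pd.DataFrame],
    reference_replicate_z: Union[ZMatrix, pd.DataFrame],
    variance_threshold: float = 0.90,
    fdr_level: float = 0.05,
    alpha: float = 0.01,
    second_variance_threshold: float = 0.60,
) -> FeatureReport:
    """The full two-step pipeline: first PCA, correlation screen, second
    PCA per correlated set."""
    space = first_step_pca(z_strain_means, variance_threshold)
    correlated = screen_correlated(space, z_strain_means, fdr_level)
    representative: dict[str, pd.DataFrame] = {}
    cov2: dict[str, float] = {}
    for pc, df in correlated.items():
        params = list(df["parameter"])
        if not params:
            representative[pc] = pd.DataFrame(
                columns=["parameter", "component", "r", "p_bonferroni",
                         "representative", "degenerate"])
            continue
        rep = second_step_pca(params, reference_replicate_z, alpha,
                              second_variance_threshold)
        representative[pc] = rep
        if len(params) > 1:
            Z = (reference_replicate_z.usable()
                 if isinstance(reference_replicate_z, ZMatrix)
                 else reference_replicate_z)
            sub_space = pca_covariance(Z[params],
                                       threshold=second_variance_threshold)
            cov2[pc] = float(
                np.cumsum(sub_space.explained_variance_ratio)
                [sub_space.n_selected - 1]
            )
        else:
            cov2[pc] = 1.0
    covered = float(
        np.cumsum(space.explained_variance_ratio)[space.n_selected - 1]
    )
    return FeatureReport(space, correlated, representative, covered, cov2)
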