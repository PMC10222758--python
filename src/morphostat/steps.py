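"""Per-parameter breeding-step effect detection and cross-background
sharing summaries.

For every morphological parameter a family-appropriate GLM is fitted
against the lineage's cumulative-step design matrix, so each
(background, step) coefficient is the parent -> derivative change.
Detection is two-staged, mirroring the screening structure of the study:

1. an omnibus likelihood-ratio test of the full step model against the
   intercept-only model, Benjamini-Hochberg FDR across parameters;
2. for parameters passing stage 1, per-step Wald tests, Benjamini-
   Hochberg FDR across all (parameter x step) hypotheses.

A parameter-step pair is *detected* only if both gates pass; its
direction is the sign of the Wald Z.

The direction-aware Venn summary then asks, for one breeding step, in
which subset of genetic backgrounds each parameter changed.  Parameters
whose direction agrees across the backgrounds where they are detected
count once, in that subset's region; a parameter whose direction reverses
between backgrounds is counted once per direction — once in the subset of
backgrounds where it went up and once in the subset where it went down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .design import LineageDesign
from .glm import GLMError, fit_design_glm, gaussian_design_batch
from .io import MorphologyMatrix

logger = logging.getLogger(__name__)


@dataclass
class StepEffectTable:
    """Detection results per (parameter, background, step).

    ``effects`` has columns z, sign, p, q, detected; ``omnibus`` has the
    per-parameter screen (lrt statistic, p, q, model_significant,
    converged).  Non-converged parameters carry no detections.
    """

    effects: pd.DataFrame
    omnibus: pd.DataFrame
    fdr_level: float

    def detected(self) -> pd.DataFrame:
        return self.effects[self.effects["detected"]]

    def n_model_significant(self) -> int:
        return int(self.omnibus["model_significant"].sum())

    def n_parameters_detected(self) -> int:
        """Parameters with at least one detected breeding step."""
        return self.detected()["parameter"].nunique()


def detect_step_effects(
    data: MorphologyMatrix,
    design: LineageDesign,
    family_map: Mapping[str, str],
    fdr_level: float = 0.05,
    trials: Optional[Mapping[str, float]] = None,
) -> StepEffectTable:
    """Two-stage FDR-controlled detection of breeding-step effects."""
    if not 0.0 < fdr_level < 1.0:
        raise ValueError("fdr_level must be in (0, 1)")
    trials = dict(trials or {})
    missing = [p for p in data.parameter_names if p not in family_map]
    if missing:
        raise GLMError(f"no family for parameters: {missing[:5]}")
    counts = data.replicate_counts()
    if (counts < 2).any():
        raise GLMError("every strain needs >= 2 replicates")

    X = design.design_matrix(list(data.strains))
    step_cols = [c for c in X.columns if c.startswith("step[")]
    step_keys = {
        c: tuple(c[len("step["):-1].split(":")) for c in step_cols
    }

    gaussian_complete = [
        p for p in data.parameter_names
        if family_map[p] == "gaussian" and not data.values[p].isna().any()
        and data.values[p].nunique() > 1
    ]
    others = [p for p in data.parameter_names if p not in gaussian_complete]

    omni_rows: dict[str, dict] = {}
    zrows: list[dict] = []

    if gaussian_complete:
        Y = data.values[gaussian_complete]
        coefs, zdf, lrt, lrt_p = gaussian_design_batch(Y, X)
        for p in gaussian_complete:
            omni_rows[p] = {
                "lrt_stat": float(lrt[p]), "lrt_p": float(lrt_p[p]),
                "converged": True,
            }
            for c in step_cols:
                bg, st = step_keys[c]
                zrows.append({"parameter": p, "background": bg, "step": st,
                              "estimate": float(coefs.loc[p, c]),
                              "z": float(zdf.loc[p, c])})

    for p in others:
        y = data.values[p].to_numpy(dtype=float)
        finite = y[np.isfinite(y)]
        if len(finite) == 0 or np.ptp(finite) == 0.0:
            omni_rows[p] = {"lrt_stat": np.nan, "lrt_p": np.nan,
                            "converged": False}
            logger.warning("parameter %r is degenerate; excluded", p)
            continue
        try:
            fit = fit_design_glm(y, X, family_map[p], trials=trials.get(p))
        except (GLMError, np.linalg.LinAlgError) as exc:
            if isinstance(exc, GLMError) and "support" in str(exc):
                raise
            omni_rows[p] = {"lrt_stat": np.nan, "lrt_p": np.nan,
                            "converged": False}
            logger.warning("parameter %r failed to fit: %s", p, exc)
            continue
        omni_rows[p] = {"lrt_stat": fit.lrt_stat, "lrt_p": fit.lrt_p,
                        "converged": fit.converged}
        if not fit.converged:
            logger.warning("parameter %r: GLM did not converge; excluded", p)
            continue
        for c in step_cols:
            bg, st = step_keys[c]
            zrows.append({"parameter": p, "background": bg, "step": st,
                          "estimate": float(fit.params[c]),
                          "z": float(fit.z[c])})

    omnibus = pd.DataFrame.from_dict(omni_rows, orient="index")
    omnibus.index.name = "parameter"
    omnibus = omnibus.loc[[p for p in data.parameter_names
                           if p in omni_rows]]
    ok = omnibus["converged"] & omnibus["lrt_p"].notna()
    omnibus["lrt_q"] = np.nan
    omnibus["model_significant"] = False
    if ok.any():
        rej, q, _, _ = multipletests(omnibus.loc[ok, "lrt_p"],
                                     alpha=fdr_level, method="fdr_bh")
        omnibus.loc[ok, "lrt_q"] = q
        omnibus.loc[ok, "model_significant"] = rej

    effects = pd.DataFrame(zrows)
    if len(effects) == 0:
        effects = pd.DataFrame(
            columns=["parameter", "background", "step", "estimate", "z",
                     "p", "q", "sign", "detected"]
        )
        return StepEffectTable(effects, omnibus, fdr_level)
    from scipy import stats as _st

    effects["p"] = 2.0 * _st.norm.sf(np.abs(effects["z"]))
    effects["q"] = np.nan
    effects["detected"] = False
    passed = set(omnibus.index[omnibus["model_significant"]])
    stage2 = effects["parameter"].isin(passed) & effects["p"].notna()
    if stage2.any():
        rej, q, _, _ = multipletests(effects.loc[stage2, "p"],
                                     alpha=fdr_level, method="fdr_bh")
        effects.loc[stage2, "q"] = q
        effects.loc[stage2, "detected"] = rej
    effects["sign"] = np.where(
        effects["detected"], np.sign(effects["z"]).astype(int), 0
    ).astype(int)
    # z exactly 0 cannot be directional; drop such detections from regions
    effects.loc[effects["sign"] == 0, "detected"] &= False
    return StepEffectTable(effects, omnibus, fdr_level)


# ---------------------------------------------------------------------------
# direction-aware Venn


@dataclass
class VennSummary:
    """Region counts of a direction-aware Venn for one breeding step.

    ``region_counts`` maps (backgrounds-subset, direction) to the number
    of parameters detected with that direction in exactly that subset.
    ``regions()`` collapses directions into plain subset counts (what a
    drawn Venn diagram shows); ``total`` is the sum over all regions,
    counting direction-reversed parameters once per direction.
    """

    step: str
    backgrounds: tuple[str, ...]
    region_counts: dict[tuple[tuple[str, ...], int], int]

    @property
    def total(self) -> int:
        return sum(self.region_counts.values())

    def regions(self) -> dict[tuple[str, ...], int]:
        out: dict[tuple[str, ...], int] = {}
        for (subset, _sign), n in self.region_counts.items():
            out[subset] = out.get(subset, 0) + n
        return out

    def count(self, subset: Sequence[str]) -> int:
        key = tuple(sorted(subset))
        return self.regions().get(key, 0)

    def to_json_dict(self) -> dict:
        return {
            "step": self.step,
            "backgrounds": list(self.backgrounds),
            "regions": [
                {"backgrounds": list(subset), "direction": sign, "count": n}
                for (subset, sign), n in sorted(self.region_counts.items())
            ],
            "total": self.total,
        }


def direction_venn(
    effects: StepEffectTable,
    step: str,
    backgrounds: Sequence[str],
) -> VennSummary:
    """Direction-aware sharing of detected parameters across backgrounds.

    For each parameter, collect the backgrounds where it is detected at
    ``step`` together with the sign there.  Backgrounds sharing a sign
    form one region contribution; a sign reversal therefore contributes
    the parameter to two disjoint regions (the "counted twice" rule).
    """
    backgrounds = tuple(backgrounds)
    if not backgrounds:
        raise ValueError("backgrounds must be non-empty")
    det = effects.detected()
    det = det[(det["step"] == step) & det["background"].isin(backgrounds)]
    region_counts: dict[tuple[tuple[str, ...], int], int] = {}
    for param, grp in det.groupby("parameter"):
        for sign in (1, -1):
            subset = tuple(sorted(grp.loc[grp["sign"] == sign, "background"]))
            if subset:
                key = (subset, sign)
                region_counts[key] = region_counts.get(key, 0) + 1
    return VennSummary(step, backgrounds, region_counts)
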