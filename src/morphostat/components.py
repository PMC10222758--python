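"""Sake brewing-component analysis.

Two views of the 21-component x 8-strain x 3-replicate table: per-
component Tukey HSD multiple comparisons with the conventional asterisk
marks (* p < 0.05, ** p < 0.01), and a covariance PCA of strain-level
means with each sample projected into the same space and per-background
trajectory vectors from the original strain to its edited derivative.

Components carry incommensurable units (sake meter value, %, ppm, mg/L),
so by default each component is standardized to unit strain-mean variance
before the PCA; covariance PCA on raw mixed units would be dominated by
whichever component happens to have the largest numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .design import LineageDesign, STEP_ORDER
from .io import ComponentTable
from .pca import PCSpace, pca_covariance

logger = logging.getLogger(__name__)


def _mark(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def tukey_components(table: ComponentTable) -> pd.DataFrame:
    """Tukey HSD on the one-way strain layout, per component.

    Returns one row per (component, strain pair): mean difference,
    studentized-range p-value, and asterisk mark.  Components with zero
    pooled within-strain variance get NaN p-values and a log entry.
    """
    strains = list(dict.fromkeys(table.strains))
    if len(strains) < 2:
        raise ValueError("need >= 2 strains")
    counts = table.strains.value_counts()
    if (counts < 2).any():
        raise ValueError("every strain needs >= 2 replicates")
    rows = []
    for comp in table.component_names:
        groups = [
            table.values.loc[(table.strains == s).to_numpy(), comp].to_numpy()
            for s in strains
        ]
        pooled_var = np.mean([g.var(ddof=1) for g in groups])
        degenerate = pooled_var == 0.0
        if degenerate:
            logger.warning(
                "tukey_components: component %r has zero within-strain "
                "variance; p-values undefined", comp,
            )
        else:
            res = stats.tukey_hsd(*groups)
        for i in range(len(strains)):
            for j in range(i + 1, len(strains)):
                diff = float(groups[i].mean() - groups[j].mean())
                p = np.nan if degenerate else float(res.pvalue[i, j])
                rows.append(
                    {"component": comp, "strain_a": strains[i],
                     "strain_b": strains[j], "mean_difference": diff,
                     "p": p, "mark": _mark(p)}
                )
    return pd.DataFrame(rows)


@dataclass
class ComponentPCA:
    """PCA of strain-mean component profiles, with per-sample projections
    and original -> edited trajectory vectors per background."""

    space: PCSpace                 # fitted on strain means
    sample_scores: pd.DataFrame    # every replicate projected
    trajectories: pd.DataFrame     # background, from, to, d_PC1, d_PC2, ...
    standardized: bool


def pca_components(
    table: ComponentTable,
    design: Optional[LineageDesign] = None,
    standardize: bool = True,
    threshold: float = 0.90,
    n_trajectory_components: int = 2,
) -> ComponentPCA:
    """Covariance PCA of the strain-level component means.

    Strain means are computed first (one row per strain); components are
    optionally scaled to unit strain-mean SD.  Samples are projected with
    the same centering, scaling and loadings.  When a lineage design is
    given, a trajectory vector is reported for each background from its
    original strain to its terminal edited strain present in the table.
    """
    means = table.values.groupby(table.strains, sort=False).mean()
    if len(means) < 2:
        raise ValueError("need >= 2 strains")
    scale = means.std(axis=0, ddof=1) if standardize else pd.Series(
        1.0, index=means.columns)
    zero = scale.index[scale == 0.0]
    if len(zero):
        logger.warning(
            "pca_components: %d constant component(s) dropped: %s",
            len(zero), list(zero[:5]),
        )
        means = means.drop(columns=zero)
        scale = scale.drop(index=zero)
    space = pca_covariance(means / scale, threshold=threshold)
    samples_scaled = table.values[means.columns] / scale
    sample_scores = space.transform(samples_scaled)

    rows = []
    if design is not None:
        kcomp = min(n_trajectory_components, len(space.component_names))
        pcs = space.component_names[:kcomp]
        strains_present = set(means.index)
        for bg in design.backgrounds():
            orig = design.strain_at(bg, "original")
            if orig not in strains_present:
                continue
            terminal = orig
            for st in STEP_ORDER[1:]:
                s = design.strain_at(bg, st)
                if s is not None and s in strains_present:
                    terminal = s
            vec = (space.scores.loc[terminal, pcs]
                   - space.scores.loc[orig, pcs])
            row = {"background": bg, "from": orig, "to": terminal}
            row.update({f"d_{pc}": float(vec[pc]) for pc in pcs})
            rows.append(row)
    trajectories = pd.DataFrame(rows)
    return ComponentPCA(space, sample_scores, trajectories, standardize)
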