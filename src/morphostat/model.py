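"""Model/Results facade over the phenotyping pipeline.

:class:`StrainMorphologyModel` is built from a morphology table plus a
lineage design and, on :meth:`~StrainMorphologyModel.fit`, runs the whole
chain — GLM Wald-Z normalization, covariance PCA of the Z-matrix,
holistic morphological abnormality (HMA) with its gamma-ANOVA step tests,
two-stage FDR step-effect detection with direction-aware Venn summaries,
and two-step successive PCA feature extraction — returning a
:class:`StrainMorphologyResults` that carries every intermediate table
and a ``summary()``.

:class:`SakeComponentModel` does the same for brewing-component tables
(Tukey comparisons and trajectory PCA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .components import ComponentPCA, pca_components, tukey_components
from .design import EDIT_STEPS, LineageDesign
from .features import FeatureReport, extract_features
from .glm import ZMatrix, compute_z_matrix
from .hma import HMATestResult, hma_distance, test_hma
from .io import ComponentTable, MorphologyMatrix
from .pca import PCSpace, pca_covariance
from .steps import StepEffectTable, VennSummary, detect_step_effects, direction_venn


class StrainMorphologyModel:
    """High-dimensional morphological phenotyping of a breeding lineage.

    Parameters
    ----------
    data
        Samples x parameters morphology table with strain labels.
    design
        The breeding lineage (parents, steps, backgrounds, reference).
    families
        Distribution family per parameter (gaussian/gamma/beta/binomial).
    trials
        Optional trial counts for binomial (cell-ratio) parameters.
    """

    def __init__(
        self,
        data: MorphologyMatrix,
        design: LineageDesign,
        families: Mapping[str, str],
        trials: Optional[Mapping[str, float]] = None,
    ) -> None:
        self.data = data
        self.design = design
        self.families = dict(families)
        self.trials = dict(trials or {})

    @classmethod
    def from_csv(cls, morphology_path, lineage_path, families_path
                 ) -> "StrainMorphologyModel":
        from . import io

        data = io.read_morphology(morphology_path)
        design = io.read_lineage(lineage_path)
        families, trials = io.read_family_map(families_path)
        return cls(data, design, families, trials)

    def fit(
        self,
        variance_threshold: float = 0.90,
        fdr_level: float = 0.05,
        alpha: float = 0.01,
        second_variance_threshold: float = 0.60,
        hma_test: str = "wald",
    ) -> "StrainMorphologyResults":
        """Run the full pipeline at the study's default thresholds."""
        z_ref = compute_z_matrix(
            self.data, self.design, self.families,
            mode="per_replicate", baseline="global_reference",
            trials=self.trials,
        )
        space = pca_covariance(z_ref, threshold=variance_threshold)
        k = space.n_selected
        labels = list(self.data.strains.loc[space.scores.index])
        distances = hma_distance(space, k, self.design.reference, labels)
        hma_tests = test_hma(distances, labels, self.design,
                             fdr_level=fdr_level, test=hma_test)

        step_table = detect_step_effects(
            self.data, self.design, self.families, fdr_level=fdr_level,
            trials=self.trials,
        )
        venns = {
            st: direction_venn(step_table, st, self.design.backgrounds())
            for st in EDIT_STEPS
            if any(s == st for _, s in self.design.step_columns())
        }

        z_parent = compute_z_matrix(
            self.data, self.design, self.families,
            mode="per_replicate", baseline="parent_strain",
            trials=self.trials,
        )
        zsm = z_parent.strain_means().usable()
        ref_mask = (z_parent.strains == self.design.reference).to_numpy()
        ref_z = z_parent.values.loc[ref_mask]
        common = [c for c in zsm.columns if not ref_z[c].isna().any()
                  and ref_z[c].std(ddof=1) > 0]
        features = extract_features(
            zsm[common], ref_z[common],
            variance_threshold=variance_threshold,
            fdr_level=fdr_level, alpha=alpha,
            second_variance_threshold=second_variance_threshold,
        )
        return StrainMorphologyResults(
            model=self, z_reference=z_ref, z_parent=z_parent, space=space,
            hma=distances, hma_tests=hma_tests, step_effects=step_table,
            venns=venns, features=features,
            variance_threshold=variance_threshold, fdr_level=fdr_level,
            alpha=alpha,
        )


@dataclass
class StrainMorphologyResults:
    """Everything the morphological phenotyping pipeline computes."""

    model: StrainMorphologyModel
    z_reference: ZMatrix
    z_parent: ZMatrix
    space: PCSpace
    hma: pd.Series
    hma_tests: HMATestResult
    step_effects: StepEffectTable
    venns: dict[str, VennSummary]
    features: FeatureReport
    variance_threshold: float
    fdr_level: float
    alpha: float

    @property
    def n_pcs(self) -> int:
        return self.space.n_selected

    def hma_by_strain(self) -> pd.DataFrame:
        labels = self.model.data.strains.loc[self.hma.index]
        return (
            pd.DataFrame({"strain": labels, "hma": self.hma})
            .groupby("strain", sort=False)["hma"]
            .agg(["mean", "median", "std", "count"])
        )

    def summary(self) -> str:
        d = self.model.design
        lines = [
            "Strain morphology phenotyping",
            "=" * 45,
            f"samples: {len(self.model.data.sample_ids)}   "
            f"parameters: {len(self.model.data.parameter_names)}   "
            f"strains: {len(d.strains)}",
            f"reference strain: {d.reference}",
            f"excluded parameters (degenerate/non-converged): "
            f"{len(self.z_reference.excluded)}",
            "",
            f"morphospace: {self.n_pcs} PCs reach "
            f"{self.variance_threshold:.0%} of the Z-value variance",
            "",
            f"omnibus-significant parameters (LRT, FDR {self.fdr_level}): "
            f"{self.step_effects.n_model_significant()}",
            f"parameters with >= 1 detected step (Wald, FDR "
            f"{self.fdr_level}): {self.step_effects.n_parameters_detected()}",
            "",
            "HMA step tests "
            f"({self.hma_tests.test}, FDR {self.fdr_level}):",
        ]
        t = self.hma_tests.table
        for _, row in t.iterrows():
            star = " *" if row["significant"] else ""
            lines.append(
                f"  {row['parent']:>9s} -> {row['derivative']:<9s} "
                f"log-ratio {row['estimate']:+.3f}  q={row['q']:.3g}{star}"
            )
        lines.append("")
        for st, v in self.venns.items():
            lines.append(
                f"Venn {st}: {v.total} direction-aware region counts across "
                f"{len(v.backgrounds)} backgrounds"
            )
        return "\n".join(lines)


class SakeComponentModel:
    """Brewing-component analysis: Tukey comparisons + trajectory PCA."""

    def __init__(self, table: ComponentTable,
                 design: Optional[LineageDesign] = None) -> None:
        self.table = table
        self.design = design

    @classmethod
    def from_csv(cls, components_path, lineage_path=None
                 ) -> "SakeComponentModel":
        from . import io

        table = io.read_components(components_path)
        design = io.read_lineage(lineage_path) if lineage_path else None
        return cls(table, design)

    def fit(self, standardize: bool = True) -> "SakeComponentResults":
        tukey = tukey_components(self.table)
        pca = pca_components(self.table, self.design, standardize=standardize)
        return SakeComponentResults(self, tukey, pca)


@dataclass
class SakeComponentResults:
    model: SakeComponentModel
    tukey: pd.DataFrame
    pca: ComponentPCA

    def summary(self) -> str:
        evr = self.pca.space.explained_variance_ratio
        n_sig = int((self.tukey["mark"] != "").sum())
        lines = [
            "Sake component analysis",
            "=" * 45,
            f"components: {len(self.model.table.component_names)}   "
            f"samples: {len(self.model.table.values)}",
            f"Tukey-marked strain pairs (any component): {n_sig} of "
            f"{len(self.tukey)}",
            f"PC1 {evr[0]:.2%}, PC2 {evr[1]:.2%} "
            f"(cumulative {evr[:2].sum():.2%})",
        ]
        for _, row in self.pca.trajectories.iterrows():
            pcs = [c for c in self.pca.trajectories.columns
                   if c.startswith("d_")]
            vec = ", ".join(f"{c[2:]} {row[c]:+.2f}" for c in pcs)
            lines.append(f"  {row['from']} -> {row['to']}: {vec}")
        return "\n".join(lines)
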