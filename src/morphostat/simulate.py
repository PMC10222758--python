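"""Synthetic morphology and brewing-component data with known ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes: heterogeneous per-parameter distribution families (gaussian,
gamma, beta, binomial-proportion), strain effects planted on the GLM
linear-predictor (link) scale that inherit additively down each breeding
lineage, correlated parameter blocks induced by a shared latent gaussian
factor through each family's quantile function (a gaussian copula, so the
marginal family is preserved), and unbalanced replicate counts.

Randomness is hierarchical: the global seed is combined with a stable hash
of each parameter name (and each block id) into an independent substream,
so adding a parameter never perturbs the values of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .design import LineageDesign, EDIT_STEPS
from .io import ComponentTable, MorphologyMatrix

FAMILIES = ("gaussian", "gamma", "beta", "binomial")

#: link functions per family (the scale on which effects are specified)
LINKS = {"gaussian": "identity", "gamma": "log", "beta": "logit", "binomial": "logit"}


class EffectError(ValueError):
    """Raised for planted effects referencing unknown strains/parameters or
    pushing a mean outside the family's support."""


@dataclass(frozen=True)
class ParameterSpec:
    """One morphological parameter: its distribution family, baseline mean
    (family-native scale), dispersion, and optional correlated-block id.

    ``dispersion`` is family-appropriate: variance (gaussian), shape
    (gamma), precision (beta), or trial count (binomial).
    """

    name: str
    family: str
    baseline: float
    dispersion: float
    block_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r} for {self.name!r}")
        if not self.dispersion > 0:
            raise ValueError(f"dispersion must be > 0 for {self.name!r}")
        if self.family == "gamma" and not self.baseline > 0:
            raise ValueError(f"gamma baseline must be > 0 for {self.name!r}")
        if self.family in ("beta", "binomial") and not 0 < self.baseline < 1:
            raise ValueError(f"{self.family} baseline must be in (0,1) for {self.name!r}")
        if self.family == "binomial" and self.dispersion < 1:
            raise ValueError(f"binomial trial count must be >= 1 for {self.name!r}")


@dataclass(frozen=True)
class PlantedEffects:
    """Ground-truth strain effects: (strain, parameter, link-scale shift).

    A shift planted on a strain is inherited by every descendant of that
    strain (effects compose additively on the link scale down the chain).
    """

    entries: tuple[tuple[str, str, float], ...]

    def __init__(self, entries: Sequence[tuple[str, str, float]] = ()) -> None:
        entries = tuple((s, p, float(d)) for s, p, d in entries)
        keys = [(s, p) for s, p, _ in entries]
        if len(set(keys)) != len(keys):
            raise EffectError("duplicate (strain, parameter) pair in effects")
        object.__setattr__(self, "entries", entries)

    def validate(self, design: LineageDesign, parameters: Sequence[str]) -> None:
        params = set(parameters)
        for s, p, _ in self.entries:
            if s not in design.strains:
                raise EffectError(f"effect references unknown strain {s!r}")
            if p not in params:
                raise EffectError(f"effect references unknown parameter {p!r}")

    def cumulative_shift(self, design: LineageDesign, strain: str, parameter: str
                         ) -> float:
        chain = set(design.chain(strain))
        return sum(d for s, p, d in self.entries if p == parameter and s in chain)


# ---------------------------------------------------------------------------
# seeding


def _substream(seed: int, kind: str, key: str) -> np.random.Generator:
    tag = zlib.crc32(f"{kind}:{key}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


# ---------------------------------------------------------------------------
# family marginals


def _link_mean(spec: ParameterSpec, shift: float) -> float:
    """Baseline composed with a link-scale shift, mapped back to the mean."""
    if spec.family == "gaussian":
        return spec.baseline + shift
    if spec.family == "gamma":
        mu = float(np.exp(np.log(spec.baseline) + shift))
        if not np.isfinite(mu) or mu <= 0:
            raise EffectError(f"gamma mean left support for {spec.name!r}")
        return mu
    mu = float(expit(logit(spec.baseline) + shift))
    if not 0.0 < mu < 1.0:
        raise EffectError(
            f"{spec.family} mean pushed outside (0,1) for {spec.name!r} "
            f"(shift {shift:+g})"
        )
    return mu


def _from_uniform(spec: ParameterSpec, mu: float, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF transform of uniforms into the family at mean ``mu``."""
    if spec.family == "gaussian":
        return stats.norm.ppf(u, loc=mu, scale=np.sqrt(spec.dispersion))
    if spec.family == "gamma":
        shape = spec.dispersion
        return stats.gamma.ppf(u, a=shape, scale=mu / shape)
    if spec.family == "beta":
        phi = spec.dispersion
        return stats.beta.ppf(u, a=mu * phi, b=(1.0 - mu) * phi)
    n = int(round(spec.dispersion))
    return stats.binom.ppf(u, n, mu) / n  # stored as a proportion


# ---------------------------------------------------------------------------
# morphology generation


def generate_morphology(
    specs: Sequence[ParameterSpec],
    design: LineageDesign,
    replicates: Mapping[str, int],
    effects: PlantedEffects = PlantedEffects(),
    block_correlation: float = 0.0,
    seed: int = 0,
) -> MorphologyMatrix:
    """Draw a samples x parameters morphology table.

    Each strain's mean is its baseline plus the cumulative link-scale shift
    inherited along its lineage chain.  Parameters sharing a ``block_id``
    share a per-sample latent gaussian factor with loading
    sqrt(block_correlation), giving latent correlation ~ block_correlation
    while keeping the marginal family exact.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    names = [sp.name for sp in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate parameter names in specs")
    if not 0.0 <= block_correlation < 1.0:
        raise ValueError("block_correlation must be in [0, 1)")
    for s in design.strains:
        if replicates.get(s, 0) < 2:
            raise ValueError(f"strain {s!r} needs >= 2 replicates")
    effects.validate(design, names)

    sample_ids: list[str] = []
    sample_strains: list[str] = []
    for s in design.strains:
        for r in range(replicates[s]):
            sample_ids.append(f"{s}_r{r + 1:02d}")
            sample_strains.append(s)
    n = len(sample_ids)

    block_factors: dict[int, np.ndarray] = {}
    for sp in specs:
        if sp.block_id is not None and sp.block_id not in block_factors:
            block_factors[sp.block_id] = _substream(
                seed, "block", str(sp.block_id)
            ).standard_normal(n)

    strain_index = pd.Series(sample_strains, index=sample_ids)
    columns: dict[str, np.ndarray] = {}
    rho = float(block_correlation)
    for sp in specs:
        eps = _substream(seed, "param", sp.name).standard_normal(n)
        if sp.block_id is not None and rho > 0:
            z = np.sqrt(rho) * block_factors[sp.block_id] + np.sqrt(1 - rho) * eps
        else:
            z = eps
        u = stats.norm.cdf(z)
        col = np.empty(n)
        for strain in design.strains:
            mu = _link_mean(sp, effects.cumulative_shift(design, strain, sp.name))
            mask = (strain_index == strain).to_numpy()
            col[mask] = _from_uniform(sp, mu, u[mask])
        columns[sp.name] = col

    values = pd.DataFrame(columns, index=pd.Index(sample_ids, name="sample"))
    return MorphologyMatrix(values, strain_index.rename("strain"))


# ---------------------------------------------------------------------------
# component generation


def generate_components(
    design: LineageDesign,
    n_components: int = 21,
    replicates: int = 3,
    effects: PlantedEffects = PlantedEffects(),
    seed: int = 0,
    strains: Optional[Sequence[str]] = None,
    baselines: Optional[Sequence[float]] = None,
    noise_sd: float = 1.0,
) -> ComponentTable:
    """Draw a brewing-component table: gaussian noise around strain means.

    By default uses every strain in the design; the study layout passes the
    4 original + 4 terminal edited strains (24 samples = 8 strains x 3
    replicates).  Effects are identity-scale shifts that inherit down the
    lineage like morphology effects.  ``noise_sd = 0`` yields exact strain
    means (useful for degenerate fixtures).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    strains = list(strains) if strains is not None else list(design.strains)
    unknown = set(strains) - set(design.strains)
    if unknown:
        raise EffectError(f"unknown strains: {sorted(unknown)}")
    comp_names = [f"comp{j + 1:02d}" for j in range(n_components)]
    effects.validate(design, comp_names)
    if baselines is None:
        baselines = [10.0 + j for j in range(n_components)]
    if len(baselines) != n_components:
        raise ValueError("baselines length must equal n_components")

    rows = []
    ids = []
    strain_col = []
    rep_col = []
    for s in strains:
        for r in range(replicates):
            ids.append(f"{s}_c{r + 1}")
            strain_col.append(s)
            rep_col.append(str(r + 1))
    cols = {}
    for j, cname in enumerate(comp_names):
        noise = _substream(seed, "component", cname).standard_normal(len(ids))
        vals = np.empty(len(ids))
        for i, s in enumerate(strain_col):
            mu = baselines[j] + effects.cumulative_shift(design, s, cname)
            vals[i] = mu + noise_sd * noise[i]
        cols[cname] = vals
    idx = pd.Index(ids, name="sample")
    return ComponentTable(
        pd.DataFrame(cols, index=idx),
        pd.Series(strain_col, index=idx, name="strain"),
        pd.Series(rep_col, index=idx, name="replicate"),
    )


# ---------------------------------------------------------------------------
# default parameter census


def default_parameter_specs(
    n_gaussian: int = 254,
    n_gamma: int = 123,
    n_beta: int = 93,
    n_binomial: int = 31,
    block_size: int = 6,
    n_blocks: int = 40,
) -> list[ParameterSpec]:
    """A CalMorph-sized parameter census (501 parameters by default).

    The true family of each CalMorph parameter is not public; this census
    splits the 501 columns across the four families in fixed proportions
    and groups the first ``n_blocks * block_size`` continuous parameters
    into correlated blocks, mimicking the grouped covariance of real
    morphological measurements (size, shape and nuclear parameters move
    together).  Baselines and dispersions are fixed, family-typical values.
    """
    specs: list[ParameterSpec] = []
    counter = 0

    def block_for(i: int) -> Optional[int]:
        b = i // block_size
        return b if b < n_blocks else None

    for i in range(n_gaussian):
        specs.append(
            ParameterSpec(f"C{101 + i}_A", "gaussian", 0.0, 1.0, block_for(counter))
        )
        counter += 1
    for i in range(n_gamma):
        specs.append(
            ParameterSpec(f"D{101 + i}_A", "gamma", 1.0, 20.0, block_for(counter))
        )
        counter += 1
    for i in range(n_beta):
        specs.append(ParameterSpec(f"A{101 + i}_A", "beta", 0.3, 50.0, None))
    for i in range(n_binomial):
        specs.append(ParameterSpec(f"A{201 + i}_C", "binomial", 0.3, 100.0, None))
    return specs


def family_map(specs: Sequence[ParameterSpec]) -> dict[str, str]:
    return {sp.name: sp.family for sp in specs}


def trials_map(specs: Sequence[ParameterSpec]) -> dict[str, int]:
    """Trial counts of the binomial parameters (cell counts per sample)."""
    return {
        sp.name: int(round(sp.dispersion))
        for sp in specs
        if sp.family == "binomial"
    }
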