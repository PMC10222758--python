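"""Tabular containers and readers/writers.

Formats are deliberately plain: UTF-8 CSV with '.' decimals for data
tables (the convention of CalMorph exports), YAML or JSON for lineage and
run configuration, JSON for result manifests and sidecars.  Writers are
exact inverses of readers on valid inputs.

Missing values: morphology parameter columns may be missing per sample
(CalMorph emits NA for parameters that need a minimum cell count).
Statistics downstream drop missing pairs per parameter; nothing is ever
imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .design import LineageDesign, LineageError

PathLike = Union[str, Path]


class TableFormatError(ValueError):
    """Raised for a malformed input table."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class MorphologyMatrix:
    """Samples x parameters morphology table with strain labels.

    ``values`` is indexed by sample ID with one column per morphological
    parameter; ``strains`` is a parallel Series mapping sample ID to strain
    label.  NaN marks a missing measurement.
    """

    values: pd.DataFrame
    strains: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.strains = self.strains.astype(str)
        if not self.values.index.equals(self.strains.index):
            raise TableFormatError("sample index of values and strains differ")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise TableFormatError(f"duplicate sample ID {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise TableFormatError(f"duplicate parameter name {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def strain_labels(self) -> list[str]:
        return list(self.strains)

    def replicate_counts(self) -> pd.Series:
        return self.strains.value_counts()

    def subset_strains(self, keep: Sequence[str]) -> "MorphologyMatrix":
        mask = self.strains.isin(list(keep))
        return MorphologyMatrix(self.values.loc[mask], self.strains.loc[mask])


@dataclass
class ComponentTable:
    """Brewing-component measurements: samples x components, with strain
    labels and replicate IDs (21 components, 8 strains x 3 replicates in
    the study)."""

    values: pd.DataFrame
    strains: pd.Series
    replicates: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not (
            self.values.index.equals(self.strains.index)
            and self.values.index.equals(self.replicates.index)
        ):
            raise TableFormatError("component table indexes are not aligned")
        if self.values.isna().any().any():
            raise TableFormatError("component table contains missing values")
        if self.values.shape[1] < 2:
            raise TableFormatError("need at least 2 components")

    @property
    def component_names(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# morphology CSV

_ID_COL = "sample"
_STRAIN_COL = "strain"


def read_morphology(path: PathLike) -> MorphologyMatrix:
    """Read a CalMorph-style CSV: sample ID, strain label, then one column
    per parameter.  Empty cells become NaN; duplicate sample IDs or
    parameter columns are rejected."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != [_ID_COL, _STRAIN_COL]:
        raise TableFormatError(
            f"morphology CSV must start with columns {_ID_COL!r},{_STRAIN_COL!r}; "
            f"got {list(df.columns[:2])}"
        )
    cols = list(df.columns[2:])
    seen: set[str] = set()
    for c in cols:
        base = c.split(".")[0] if c.split(".")[-1].isdigit() else c
        if base in seen:
            raise TableFormatError(f"duplicate parameter column {base!r}")
        seen.add(base)
    values = {}
    for c in cols:
        raw = df[c].mask(df[c].isin(["", "NA"]))
        try:
            values[c] = pd.to_numeric(raw).to_numpy()
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"non-numeric cell in parameter column {c!r}") from exc
    vals = pd.DataFrame(values, index=pd.Index(df[_ID_COL], name=_ID_COL))
    strains = pd.Series(list(df[_STRAIN_COL]), index=vals.index, name=_STRAIN_COL)
    return MorphologyMatrix(vals, strains)


def write_morphology(data: MorphologyMatrix, path: PathLike) -> None:
    out = data.values.copy()
    out.insert(0, _STRAIN_COL, data.strains)
    out.index.name = _ID_COL
    out.to_csv(path, na_rep="")


# ---------------------------------------------------------------------------
# component CSV


def read_components(path: PathLike) -> ComponentTable:
    df = pd.read_csv(path)
    need = [_ID_COL, _STRAIN_COL, "replicate"]
    if list(df.columns[:3]) != need:
        raise TableFormatError(f"component CSV must start with columns {need}")
    idx = pd.Index(df[_ID_COL].astype(str), name=_ID_COL)
    values = df[df.columns[3:]].astype(float).set_axis(idx)
    strains = pd.Series(list(df[_STRAIN_COL].astype(str)), index=idx, name=_STRAIN_COL)
    reps = pd.Series(list(df["replicate"].astype(str)), index=idx, name="replicate")
    return ComponentTable(values, strains, reps)


def write_components(table: ComponentTable, path: PathLike) -> None:
    out = table.values.copy()
    out.insert(0, "replicate", table.replicates)
    out.insert(0, _STRAIN_COL, table.strains)
    out.index.name = _ID_COL
    out.to_csv(path)


# ---------------------------------------------------------------------------
# lineage YAML/JSON


def read_lineage(path: PathLike) -> LineageDesign:
    """Read a lineage design from YAML or JSON.

    Expected keys: ``strains`` (list), ``parent`` (map, null for
    originals), ``step`` (map), ``background`` (map), ``reference``.
    """
    text = Path(path).read_text(encoding="utf-8")
    spec = yaml.safe_load(text)
    if not isinstance(spec, dict):
        raise TableFormatError("lineage file must contain a mapping")
    try:
        strains = spec["strains"]
        parent = spec["parent"]
        step = spec["step"]
        background = spec["background"]
        reference = spec["reference"]
    except KeyError as exc:
        raise TableFormatError(f"lineage file missing key {exc.args[0]!r}") from exc
    try:
        return LineageDesign(strains, parent, step, background, reference)
    except LineageError:
        raise


def write_lineage(design: LineageDesign, path: PathLike) -> None:
    doc = {
        "strains": list(design.strains),
        "parent": dict(design.parent_of),
        "step": dict(design.step_of),
        "background": dict(design.background_of),
        "reference": design.reference,
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, default_flow_style=False),
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Z-matrix CSV + JSON sidecar


def write_z(z: "ZMatrix", path: PathLike) -> None:  # noqa: F821
    path = Path(path)
    z.values.to_csv(path, na_rep="")
    meta = {
        "reference": z.reference,
        "mode": z.mode,
        "baseline": z.baseline,
        "excluded": list(z.excluded),
        "variance_estimator": "plug-in",
    }
    if z.strains is not None:
        meta["strains"] = {str(k): str(v) for k, v in z.strains.items()}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_z(path: PathLike) -> "ZMatrix":  # noqa: F821
    from .glm import ZMatrix

    path = Path(path)
    values = pd.read_csv(path, index_col=0)
    meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    strains = meta.get("strains")
    return ZMatrix(
        values=values,
        mode=meta["mode"],
        baseline=meta["baseline"],
        reference=meta["reference"],
        excluded=tuple(meta.get("excluded", ())),
        strains=pd.Series({k: strains[k] for k in values.index.astype(str)})
        if strains else None,
    )


# ---------------------------------------------------------------------------
# family map YAML


def write_family_map(families: Mapping[str, str],
                     trials: Optional[Mapping[str, float]],
                     path: PathLike) -> None:
    doc = {"families": dict(families),
           "trials": {k: float(v) for k, v in (trials or {}).items()}}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True),
                          encoding="utf-8")


def read_family_map(path: PathLike) -> tuple[dict[str, str], dict[str, float]]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict) or "families" not in doc:
        raise TableFormatError("family map file must contain a 'families' map")
    return dict(doc["families"]), dict(doc.get("trials") or {})


# ---------------------------------------------------------------------------
# planted-effect ground truth sidecar


def write_effects(effects: "PlantedEffects", path: PathLike) -> None:  # noqa: F821
    doc = [
        {"strain": s, "parameter": p, "shift": float(d)}
        for (s, p, d) in effects.entries
    ]
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_effects(path: PathLike) -> "PlantedEffects":  # noqa: F821
    from .simulate import PlantedEffects

    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return PlantedEffects([(e["strain"], e["parameter"], e["shift"]) for e in doc])
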