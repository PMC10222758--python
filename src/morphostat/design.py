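"""Breeding-lineage designs for pedigreed strain panels.

A :class:`LineageDesign` records, for every strain in a breeding study, its
genetic background (the original pedigreed isolate it descends from), its
breeding step, and its immediate parent.  One strain is the global
*reference* (the intercept strain of all GLM contrasts).  The study this
package models edits four sake-yeast backgrounds (K6, K7, K9, K10) through
four successive genome-editing steps (GE01 -> GE21 -> GE31 -> GE41), with
K7 as the reference.

The lineage also owns the ANOVA *design matrix*: cumulative step indicators
along each background's chain, so each step column's coefficient is the
parent -> derivative increment on the linear-predictor scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Canonical breeding-step order. "original" is the unedited isolate.
STEP_ORDER: tuple[str, ...] = ("original", "GE01", "GE21", "GE31", "GE41")

#: Steps that correspond to an actual editing event (all but "original").
EDIT_STEPS: tuple[str, ...] = STEP_ORDER[1:]


class LineageError(ValueError):
    """Raised for an inconsistent lineage specification."""


@dataclass(frozen=True)
class LineageDesign:
    """Strain pedigree: parent links, breeding steps, backgrounds, reference.

    Parameters
    ----------
    strains
        All strain labels, in a stable order.
    parent_of
        Immediate parent per strain; ``None`` for original strains.
    step_of
        Breeding step per strain, one of :data:`STEP_ORDER`.
    background_of
        Genetic-background label per strain.
    reference
        The intercept strain of all global contrasts (K7 in the study).
    """

    strains: tuple[str, ...]
    parent_of: Mapping[str, Optional[str]]
    step_of: Mapping[str, str]
    background_of: Mapping[str, str]
    reference: str

    def __init__(
        self,
        strains: Sequence[str],
        parent_of: Mapping[str, Optional[str]],
        step_of: Mapping[str, str],
        background_of: Mapping[str, str],
        reference: str,
    ) -> None:
        object.__setattr__(self, "strains", tuple(strains))
        object.__setattr__(self, "parent_of", dict(parent_of))
        object.__setattr__(self, "step_of", dict(step_of))
        object.__setattr__(self, "background_of", dict(background_of))
        object.__setattr__(self, "reference", reference)
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        strains = set(self.strains)
        if len(strains) != len(self.strains):
            raise LineageError("duplicate strain labels")
        if self.reference not in strains:
            raise LineageError(f"reference strain {self.reference!r} not in strains")
        for m, name in (
            (self.parent_of, "parent_of"),
            (self.step_of, "step_of"),
            (self.background_of, "background_of"),
        ):
            missing = strains - set(m)
            if missing:
                raise LineageError(f"{name} missing entries for {sorted(missing)}")
        for s, st in self.step_of.items():
            if st not in STEP_ORDER:
                raise LineageError(f"unknown step {st!r} for strain {s!r}")
        for s, p in self.parent_of.items():
            if self.step_of[s] == "original":
                if p is not None:
                    raise LineageError(f"original strain {s!r} must have no parent")
            else:
                if p is None:
                    raise LineageError(f"non-original strain {s!r} has no parent")
                if p not in strains:
                    raise LineageError(f"parent {p!r} of {s!r} is not a known strain")
                if self.background_of[p] != self.background_of[s]:
                    raise LineageError(
                        f"strain {s!r} and parent {p!r} differ in background"
                    )
        # acyclicity: every chain must terminate at an original strain
        for s in self.strains:
            self.chain(s)

    # -- navigation ------------------------------------------------------

    def chain(self, strain: str) -> list[str]:
        """Lineage chain from the original strain down to ``strain``."""
        out: list[str] = []
        cur: Optional[str] = strain
        seen: set[str] = set()
        while cur is not None:
            if cur in seen:
                raise LineageError(f"cyclic parentage at strain {cur!r}")
            seen.add(cur)
            out.append(cur)
            cur = self.parent_of[cur]
        if self.step_of[out[-1]] != "original":
            raise LineageError(
                f"chain of {strain!r} terminates at non-original {out[-1]!r}"
            )
        return out[::-1]

    def backgrounds(self) -> list[str]:
        """Background labels, reference background first, then sorted."""
        ref_bg = self.background_of[self.reference]
        rest = sorted({b for b in self.background_of.values()} - {ref_bg})
        return [ref_bg] + rest

    def originals(self) -> list[str]:
        return [s for s in self.strains if self.step_of[s] == "original"]

    def strain_at(self, background: str, step: str) -> Optional[str]:
        """Strain of ``background`` at ``step``, or None if absent."""
        for s in self.strains:
            if self.background_of[s] == background and self.step_of[s] == step:
                return s
        return None

    def step_pairs(self) -> list[tuple[str, str, str, str]]:
        """All (background, step, parent, derivative) edit events present."""
        out = []
        for s in self.strains:
            if self.step_of[s] != "original":
                out.append(
                    (self.background_of[s], self.step_of[s], self.parent_of[s], s)
                )
        out.sort(key=lambda t: (t[0] != self.background_of[self.reference], t[0],
                                STEP_ORDER.index(t[1])))
        return out

    def n_parent_links(self) -> int:
        return sum(p is not None for p in self.parent_of.values())

    # -- design matrix ---------------------------------------------------

    def step_columns(self) -> list[tuple[str, str]]:
        """Ordered (background, step) keys of the cumulative step columns."""
        return [(bg, st) for bg, st, _, _ in self.step_pairs()]

    def design_matrix(self, strain_labels: Sequence[str]) -> pd.DataFrame:
        """Cumulative-step ANOVA design matrix for the given sample strains.

        Columns: ``Intercept`` (the reference strain), one background
        indicator per non-reference background (the original-strain
        offset), and one cumulative indicator per (background, step) edit
        event — 1 for the edited strain *and all its descendants*, so the
        coefficient estimates the parent -> derivative increment.
        """
        labels = list(strain_labels)
        unknown = set(labels) - set(self.strains)
        if unknown:
            raise LineageError(f"unknown strains in data: {sorted(unknown)}")
        ref_bg = self.background_of[self.reference]
        cols: dict[str, np.ndarray] = {
            "Intercept": np.ones(len(labels), dtype=float)
        }
        for bg in self.backgrounds():
            if bg == ref_bg:
                continue
            cols[f"bg[{bg}]"] = np.array(
                [float(self.background_of[s] == bg) for s in labels]
            )
        for bg, st in self.step_columns():
            idx = STEP_ORDER.index(st)
            vals = []
            for s in labels:
                vals.append(
                    float(
                        self.background_of[s] == bg
                        and STEP_ORDER.index(self.step_of[s]) >= idx
                    )
                )
            cols[f"step[{bg}:{st}]"] = np.asarray(vals)
        return pd.DataFrame(cols, index=pd.Index(labels, name="strain"))


def study_design(
    backgrounds: Sequence[str] = ("K7", "K6", "K9", "K10"),
    steps: Sequence[str] = EDIT_STEPS,
    reference: str = "K7",
) -> LineageDesign:
    """The default breeding design: each background edited through ``steps``.

    With the defaults this is the 20-strain study layout — four pedigreed
    sake-yeast backgrounds each carried through four successive
    genome-editing steps, with K7 as the global reference strain.
    """
    strains: list[str] = []
    parent_of: dict[str, Optional[str]] = {}
    step_of: dict[str, str] = {}
    background_of: dict[str, str] = {}
    for bg in backgrounds:
        prev = bg
        strains.append(bg)
        parent_of[bg] = None
        step_of[bg] = "original"
        background_of[bg] = bg
        for st in steps:
            name = f"{bg}{st}"
            strains.append(name)
            parent_of[name] = prev
            step_of[name] = st
            background_of[name] = bg
            prev = name
    return LineageDesign(strains, parent_of, step_of, background_of, reference)


def study_replicates(design: LineageDesign, reference_n: int = 37,
                     reference_derivative_n: int = 6, other_n: int = 5
                     ) -> dict[str, int]:
    """Replicate counts of the study: 37 for the reference strain, 6 for its
    derivatives, 5 for every other strain."""
    ref_bg = design.background_of[design.reference]
    out = {}
    for s in design.strains:
        if s == design.reference:
            out[s] = reference_n
        elif design.background_of[s] == ref_bg:
            out[s] = reference_derivative_n
        else:
            out[s] = other_n
    return out
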