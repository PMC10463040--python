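"""Anchored any-of composite screening rules ("mnemonics") and their ranking.

A rule is an *anchor* symptom (chest pain, the guideline-designated primary
ACS symptom) combined with a non-empty set of *secondary* symptoms: the rule
is positive when the anchor is present AND at least one secondary is present.
Candidate secondaries are symptoms whose univariable odds ratio for the
outcome exceeds a threshold (strictly > 1.0 by default).

Under missing data the rule is three-valued per visit (witness semantics):

* positive  — anchor present and some secondary recorded present;
* negative  — anchor absent, or anchor present and ALL secondaries recorded
  absent;
* unrecorded — anchor unrecorded, or anchor present with no positive witness
  and at least one secondary unrecorded (a negative cannot be proven).

A *strict* mode requiring every component symptom to be recorded is provided
for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .cohort import CohortTable
from .metrics import DiagnosticProfile

__all__ = [
    "CompositeRule",
    "RankedMnemonics",
    "select_candidate_symptoms",
    "enumerate_mnemonics",
    "rank_mnemonics",
]


@dataclass(frozen=True)
class CompositeRule:
    """Anchor + any-of secondary set; positive iff anchor AND >=1 secondary."""

    anchor: str
    secondaries: tuple[str, ...]
    label: str = ""
    strict: bool = False  # require all component symptoms recorded

    def __post_init__(self) -> None:
        secs = tuple(sorted(set(self.secondaries)))
        object.__setattr__(self, "secondaries", secs)
        if not secs:
            raise ValueError("rule needs at least one secondary symptom")
        if self.anchor in secs:
            raise ValueError(f"anchor {self.anchor!r} cannot also be a secondary")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.anchor}+any({'|'.join(secs)})"
            )

    def evaluate(self, cohort: CohortTable) -> pd.Series:
        """Tri-state rule outcome per row as a nullable-boolean Series."""
        unknown = [s for s in (self.anchor, *self.secondaries)
                   if s not in cohort.symptom_names]
        if unknown:
            raise KeyError(f"unknown symptom(s): {unknown}")
        df = cohort.df
        anchor = df[self.anchor]
        sec = df[list(self.secondaries)]
        any_present = sec.eq(True).fillna(False).any(axis=1)
        # NA must not count toward "all absent": a negative needs every
        # secondary recorded absent
        all_absent = sec.eq(False).fillna(False).all(axis=1)
        all_recorded = sec.notna().all(axis=1)

        anchor_present = anchor.eq(True).fillna(False)
        anchor_absent = anchor.eq(False).fillna(False)

        positive = anchor_present & any_present
        negative = anchor_absent | (anchor_present & all_absent)
        out = pd.Series(pd.NA, index=df.index, dtype="boolean")
        out[negative.astype(bool)] = False
        out[positive.astype(bool)] = True
        if self.strict:
            evaluable = anchor.notna() & all_recorded
            out[~evaluable] = pd.NA
        return out


@dataclass(frozen=True)
class RankedMnemonics:
    """Rules ordered by the selection criteria, with the criteria recorded."""

    entries: tuple[tuple[CompositeRule, DiagnosticProfile], ...]
    or_threshold: float
    specificity_floor: float
    all_excluded: bool = False


def select_candidate_symptoms(
    profiles: dict[str, DiagnosticProfile], threshold: float = 1.0
) -> list[str]:
    """Symptoms whose OR point estimate is strictly above ``threshold``.

    Sorted by OR descending (the anchor will typically be first).  Selection
    is on the point estimate; CI-based selection is deliberately not the
    default.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    chosen = [(name, p.odds_ratio.point) for name, p in profiles.items()
              if p.odds_ratio.point > threshold]
    chosen.sort(key=lambda t: (-t[1], t[0]))
    return [name for name, _ in chosen]


def enumerate_mnemonics(
    anchor: str,
    candidates: Sequence[str],
    min_size: int,
    max_size: int | None = None,
    strict: bool = False,
) -> list[CompositeRule]:
    """All anchored rules whose secondary set is a candidate subset of size
    in ``[min_size, max_size]``, ordered by size descending then
    lexicographically (deterministic)."""
    candidates = sorted(set(candidates))
    if anchor in candidates:
        raise ValueError("candidates must exclude the anchor")
    if max_size is None:
        max_size = len(candidates)
    if min_size < 1 or min_size > len(candidates):
        raise ValueError(
            f"min_size {min_size} out of range for {len(candidates)} candidates"
        )
    if max_size < min_size:
        raise ValueError("max_size < min_size")
    rules = []
    for size in range(min(max_size, len(candidates)), min_size - 1, -1):
        for subset in combinations(candidates, size):
            rules.append(CompositeRule(anchor, subset, strict=strict))
    return rules


def rank_mnemonics(
    evaluated: Sequence[tuple[CompositeRule, DiagnosticProfile]],
    specificity_floor: float = 0.5,
    or_threshold: float = 1.0,
) -> RankedMnemonics:
    """Rank rules for adoption: drop those below the specificity floor, then
    sort by OR descending, ties by sensitivity descending, then fewer
    secondaries, then label.

    The floor operationalizes "acceptable specificity": a screening mnemonic
    that sends more than half of all non-ACS visits to the ER is considered
    an undue burden.
    """
    if not evaluated:
        raise ValueError("no evaluated rules supplied")
    kept = [(r, p) for r, p in evaluated
            if p.specificity.point >= specificity_floor]
    kept.sort(key=lambda rp: (
        -rp[1].odds_ratio.point,
        -rp[1].sensitivity.point,
        len(rp[0].secondaries),
        rp[0].label,
    ))
    return RankedMnemonics(
        entries=tuple(kept),
        or_threshold=or_threshold,
        specificity_floor=specificity_floor,
        all_excluded=not kept,
    )
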