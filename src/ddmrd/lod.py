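"""Limit of detection, specificity and reproducibility analysis.

The LOD design escalates replicate counts as the dilution deepens (few
replicates where detection is certain, many where single molecules are
being chased). A replicate scores positive when its positive-droplet count
reaches the detection floor; the *maximum sensitivity* is the most dilute
point such that it and every less-dilute point keep at least 75% of
replicates positive (the cumulative reading of "up to this level").

Reproducibility between duplicate measurements is judged on the log scale:
a pair is reproducible when the two concentrations fall within one order
of magnitude, |log10(a) - log10(b)| < 1. This deliberately is not "same
integer decade", which would call 9.9 vs 10.1 irreproducible. Pairs where
both members are zero are reproducible; zero-vs-positive pairs are counted
as a separate "discordant detection" category rather than forced through
the log rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .classify import ClassificationRules
from .errors import ValidationError
from .io import BACKGROUND_ROLES, DropletWell


@dataclass
class DilutionPoint:
    """One dilution point: nominal label (as a fraction), expected template
    molecules per replicate well, and the replicate wells."""

    label: float
    expected_copies_per_well: float
    wells: list[DropletWell]


@dataclass
class DilutionExperiment:
    points: list[DilutionPoint]
    design_name: str = ""

    def __post_init__(self) -> None:
        labels = [p.label for p in self.points]
        if len(set(labels)) != len(labels):
            raise ValidationError("DilutionExperiment: duplicate dilution labels")
        for p in self.points:
            if not p.wells:
                raise ValidationError(
                    f"DilutionExperiment: point {p.label} has no wells"
                )


@dataclass
class PositivityRow:
    label: float
    n_replicates: int
    n_positive_replicates: int

    @property
    def fraction_positive(self) -> float:
        return self.n_positive_replicates / self.n_replicates

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive_replicates <= self.n_replicates:
            raise ValidationError(
                f"positivity row {self.label}: {self.n_positive_replicates} positive "
                f"of {self.n_replicates}"
            )


@dataclass
class PositivityTable:
    """Replicate positivity per dilution point, least dilute first."""

    rows: list[PositivityRow] = field(default_factory=list)

    @classmethod
    def from_counts(
        cls, counts: Sequence[tuple[float, int, int]]
    ) -> "PositivityTable":
        """Build from (label, n_replicates, n_positive) triples."""
        rows = [PositivityRow(l, n, k) for l, n, k in counts]
        rows.sort(key=lambda r: -r.label)
        return cls(rows=rows)


def positivity_by_dilution(
    experiment: DilutionExperiment, rules: ClassificationRules
) -> PositivityTable:
    """Score replicate positivity per dilution point.

    A replicate is positive when its positive-droplet count is at least
    ``rules.min_positive_droplets_detected``. Rows are ordered by
    decreasing dilution label (least dilute first).
    """
    if not experiment.points:
        raise ValidationError("positivity_by_dilution: empty experiment")
    rows = [
        PositivityRow(
            label=p.label,
            n_replicates=len(p.wells),
            n_positive_replicates=sum(
                1
                for w in p.wells
                if w.k_positive >= rules.min_positive_droplets_detected
            ),
        )
        for p in experiment.points
    ]
    rows.sort(key=lambda r: -r.label)
    return PositivityTable(rows=rows)


def max_sensitivity(
    table: PositivityTable, min_fraction: float = 0.75
) -> float | None:
    """Most dilute point with cumulatively >= ``min_fraction`` positivity.

    Walking from the least dilute point down, returns the last label before
    the positivity fraction first drops below ``min_fraction``; ``None``
    when even the least dilute point fails.
    """
    if not table.rows:
        raise ValidationError("max_sensitivity: empty table")
    best: float | None = None
    for row in table.rows:
        if row.fraction_positive >= min_fraction:
            best = row.label
        else:
            break
    return best


@dataclass
class SpecificitySummary:
    n_replicates_tested: int
    n_false_positive: int

    @property
    def specificity(self) -> float:
        return 1.0 - self.n_false_positive / self.n_replicates_tested


def specificity_summary(wells: Sequence[DropletWell]) -> SpecificitySummary:
    """Count false-positive replicates among background wells.

    A replicate is a false positive when any droplet is positive. Input
    must consist solely of background roles (NTC, healthy donor,
    Ph-negative control); sample wells are rejected.
    """
    if not wells:
        raise ValidationError("specificity_summary: no background wells")
    bad = [w.well_id for w in wells if w.role not in BACKGROUND_ROLES]
    if bad:
        raise ValidationError(
            f"specificity_summary: non-background wells in input: {bad}"
        )
    n_fp = sum(1 for w in wells if w.k_positive > 0)
    return SpecificitySummary(n_replicates_tested=len(wells), n_false_positive=n_fp)


@dataclass
class PairComparison:
    a: float
    b: float
    category: str  # reproducible | not_reproducible | discordant_detection
    delta_log10: float | None


@dataclass
class ReproducibilityReport:
    pairs: list[PairComparison]
    n_reproducible: int
    n_not_reproducible: int
    n_discordant_detection: int

    @property
    def fraction_reproducible(self) -> float:
        """Fraction reproducible among pairs where the log rule applies
        (discordant-detection pairs are reported, not averaged in)."""
        denom = self.n_reproducible + self.n_not_reproducible
        return self.n_reproducible / denom if denom else float("nan")


def reproducibility_check(
    paired_estimates: Sequence[tuple[float, float]]
) -> ReproducibilityReport:
    """Flag each duplicate pair as within-one-log reproducible or not.

    Zero/zero pairs are reproducible; zero/positive pairs go to the
    ``discordant_detection`` category. Negative concentrations are
    rejected.
    """
    comparisons: list[PairComparison] = []
    for a, b in paired_estimates:
        if a < 0 or b < 0:
            raise ValidationError(f"reproducibility_check: negative concentration ({a}, {b})")
        if a == 0 and b == 0:
            comparisons.append(PairComparison(a, b, "reproducible", 0.0))
        elif a == 0 or b == 0:
            comparisons.append(PairComparison(a, b, "discordant_detection", None))
        else:
            d = abs(math.log10(a) - math.log10(b))
            cat = "reproducible" if d < 1.0 else "not_reproducible"
            comparisons.append(PairComparison(a, b, cat, d))
    return ReproducibilityReport(
        pairs=comparisons,
        n_reproducible=sum(1 for c in comparisons if c.category == "reproducible"),
        n_not_reproducible=sum(1 for c in comparisons if c.category == "not_reproducible"),
        n_discordant_detection=sum(
            1 for c in comparisons if c.category == "discordant_detection"
        ),
    )
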