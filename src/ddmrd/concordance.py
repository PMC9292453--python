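"""Paired comparison of Q-RT-PCR and ddPCR MRD calls.

Cross-tabulates paired POS / PNQ / NEG calls (rows: ddPCR, columns:
Q-RT-PCR), and derives:

- overall concordance: percent of samples on the diagonal;
- quantifiability recovery: among samples the reference method could not
  quantify (PNQ or NEG), the percent that ddPCR quantified;
- an exact paired (McNemar) test on quantifiable-vs-not, appropriate
  because the two calls are made on the same samples;
- the Pearson correlation of quantitative values for diagnostic samples.

Percentages are reported as exact floats; :func:`round_half_away` provides
the round-half-away-from-zero convention at one decimal or to integers,
since reports conventionally mix both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .io import MrdClass

#: Row/column order of the cross-tab.
CLASS_ORDER: tuple[str, ...] = ("POS", "PNQ", "NEG")


@dataclass
class CrosstabResult:
    """3x3 paired-classification counts; rows ddPCR, columns Q-RT-PCR."""

    counts: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValidationError("CrosstabResult: counts must be 3x3")
        if (self.counts < 0).any():
            raise ValidationError("CrosstabResult: negative count")
        if self.n_total != int(self.counts.sum()):
            raise ValidationError("CrosstabResult: n_total != sum of counts")


def _class_index(label: str | MrdClass) -> int:
    name = label.value if isinstance(label, MrdClass) else str(label)
    try:
        return CLASS_ORDER.index(name)
    except ValueError:
        raise ValidationError(
            f"unknown class label {name!r}; expected one of {CLASS_ORDER}"
        ) from None


def crosstab(pairs: Sequence[tuple[str, str]]) -> CrosstabResult:
    """Count (qrtpcr_class, ddpcr_class) pairs into the 3x3 table."""
    counts = np.zeros((3, 3), dtype=int)
    for qrt, dd in pairs:
        counts[_class_index(dd), _class_index(qrt)] += 1
    return CrosstabResult(counts=counts, n_total=int(counts.sum()))


def overall_concordance(ct: CrosstabResult) -> float:
    """Percent of samples with identical calls (trace / total x 100)."""
    if ct.n_total == 0:
        raise ValidationError("overall_concordance: empty table")
    return 100.0 * float(np.trace(ct.counts)) / ct.n_total


def quantifiability_recovery(ct: CrosstabResult) -> float:
    """Percent of reference-unquantifiable samples (PNQ or NEG by Q-RT-PCR)
    that ddPCR called POS (quantifiable)."""
    denom = int(ct.counts[:, 1].sum() + ct.counts[:, 2].sum())
    if denom == 0:
        raise ValidationError("quantifiability_recovery: no PNQ/NEG reference samples")
    recovered = int(ct.counts[0, 1] + ct.counts[0, 2])
    return 100.0 * recovered / denom


def discordant_quantifiable(ct: CrosstabResult) -> tuple[int, int]:
    """Discordant pair counts after collapsing to quantifiable (POS) vs not.

    Returns ``(b, c)``: b = ddPCR-only quantifiable, c = reference-only
    quantifiable.
    """
    b = int(ct.counts[0, 1] + ct.counts[0, 2])
    c = int(ct.counts[1, 0] + ct.counts[2, 0])
    return b, c


def mcnemar_exact(ct: CrosstabResult) -> float:
    """Two-sided exact McNemar test on quantifiable-vs-not.

    With b and c the discordant counts, the p-value is
    ``min(1, 2 P(X <= min(b, c)))`` for ``X ~ Binomial(b + c, 1/2)``;
    b + c = 0 gives p = 1.
    """
    b, c = discordant_quantifiable(ct)
    n = b + c
    if n == 0:
        return 1.0
    return min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))


def chi2_quantifiable(ct: CrosstabResult) -> float:
    """Secondary, unpaired check: chi-square on pooled quantifiable
    proportions of the two methods. The paired exact test is the primary
    analysis; this ignores the pairing."""
    q_ref = int(ct.counts[:, 0].sum())
    q_dd = int(ct.counts[0, :].sum())
    n = ct.n_total
    table = np.array([[q_ref, n - q_ref], [q_dd, n - q_dd]])
    return float(stats.chi2_contingency(table, correction=True).pvalue)


def pearson_correlation(pairs: Sequence[tuple[float, float]]) -> float:
    """Sample Pearson correlation of paired quantitative values.

    Requires at least 3 pairs and nonzero variance in both coordinates.
    For samples carrying two fusion-transcript isoforms, the convention is
    one pair per transcript.
    """
    if len(pairs) < 3:
        raise ValidationError("pearson_correlation: need at least 3 pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson_correlation: zero variance in one coordinate")
    return float(stats.pearsonr(x, y).statistic)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (1.25 -> 1.3 at one decimal), the
    convention used in clinical reports; banker's rounding would disagree
    on exact halves."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
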