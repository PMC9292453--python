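"""Poisson partition quantification.

Template molecules are distributed into droplets at random, so the count of
molecules per droplet is Poisson. With ``k`` positive of ``n`` accepted
droplets, the mean copies per droplet is recovered by the occupancy
inversion

.. math:: \\hat\\lambda = -\\ln(1 - k/n)

and the concentration is ``lambda_hat / Vd`` with ``Vd`` the droplet volume
in microliters. Replicates of the same sample are merged by pooling droplet
counts (sum of k, sum of n) *before* inversion — at trace concentrations
this is what buys the extra depth, since the pooled partition count behaves
like one giant well.

The 95% interval is the exact Clopper–Pearson binomial interval on the
positive fraction, pushed through the monotone map ``lambda = -ln(1-p)``.
Exactness matters here because the MRD regime lives at k of 0–5, where
normal approximations collapse.

MRD results are expressed as [copies/ul of the target gene] / [copies/ul of
the control gene] x 100, the conventional BCR-ABL1/ABL1 percent scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ControlInadequateError, ValidationError
from .io import DropletWell, MrdClass, Target

logger = logging.getLogger(__name__)

#: Nominal droplet volume of the QX200 system, in microliters (0.85 nL).
DEFAULT_DROPLET_VOLUME_UL = 8.5e-4

#: Minimum accepted droplets for a well to enter analysis.
DEFAULT_MIN_DROPLETS = 9000


@dataclass
class QuantResult:
    """Merged Poisson quantification of one sample/target.

    ``saturated`` flags k == n (every droplet positive): the occupancy
    inversion has no finite estimate there and ``lambda_hat``,
    ``concentration`` and ``ci_high`` are ``inf`` rather than a clipped
    number.
    """

    lambda_hat: float
    concentration: float
    ci_low: float
    ci_high: float
    k_merged: int
    n_merged: int
    n_wells: int
    saturated: bool
    qc_pass: bool
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL
    ci_level: float = 0.95


class ThresholdCall(NamedTuple):
    k_positive: int
    n_accepted: int
    threshold: float


def call_droplets(amplitudes: Sequence[float], k_sigma: float = 5.0) -> ThresholdCall:
    """Call positive droplets from fluorescence amplitudes.

    The threshold is set automatically at ``median + k_sigma * sigma_MAD``
    of the background (negative) mode, where ``sigma_MAD`` is the
    MAD-based robust spread. The background statistics are re-estimated
    once on the sub-threshold droplets so that a heavy positive cluster
    cannot drag the first-pass median upward. The threshold used is
    returned for audit.

    Raises
    ------
    ValidationError
        On fewer than 100 droplets — too few to estimate the background.
    """
    amp = np.asarray(amplitudes, dtype=float)
    if amp.size < 100:
        raise ValidationError(
            f"call_droplets: {amp.size} amplitudes; need >= 100 to estimate background"
        )
    threshold = _background_threshold(amp, k_sigma)
    # one refinement pass on the putative background only
    below = amp[amp <= threshold]
    if below.size >= 100:
        threshold = _background_threshold(below, k_sigma)
    k = int(np.count_nonzero(amp > threshold))
    return ThresholdCall(k_positive=k, n_accepted=int(amp.size), threshold=float(threshold))


def _background_threshold(amp: np.ndarray, k_sigma: float) -> float:
    center = float(np.median(amp))
    sigma = 1.4826 * float(np.median(np.abs(amp - center)))
    if sigma == 0.0:
        sigma = float(np.std(amp)) or 1.0
    return center + k_sigma * sigma


def qc_filter(
    wells: Sequence[DropletWell], min_droplets: int = DEFAULT_MIN_DROPLETS
) -> tuple[list[DropletWell], list[DropletWell]]:
    """Split wells into (accepted, rejected) by the droplet-count QC rule.

    The boundary is inclusive: a well with exactly ``min_droplets`` accepted
    droplets passes. Every rejection is logged with its reason.
    """
    accepted, rejected = [], []
    for w in wells:
        if w.n_accepted >= min_droplets:
            accepted.append(w)
        else:
            rejected.append(w)
            logger.info(
                "QC reject well %s: n_accepted=%d < %d",
                w.well_id, w.n_accepted, min_droplets,
            )
    return accepted, rejected


def merge_replicates(wells: Sequence[DropletWell]) -> tuple[int, int]:
    """Pool droplet counts across replicate wells: (sum k, sum n).

    All wells must share sample_id and target. Quantifying the pooled
    counts is definitionally the merged estimate.
    """
    if not wells:
        raise ValidationError("merge_replicates: empty replicate group")
    targets = {w.target for w in wells}
    if len(targets) > 1:
        raise ValidationError(f"merge_replicates: mixed targets {sorted(t.value for t in targets)}")
    samples = {w.sample_id for w in wells}
    if len(samples) > 1:
        raise ValidationError(f"merge_replicates: mixed samples {sorted(samples)}")
    return sum(w.k_positive for w in wells), sum(w.n_accepted for w in wells)


def poisson_quantify(
    k: int,
    n: int,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    ci_level: float = 0.95,
    n_wells: int = 1,
    qc_pass: bool = True,
) -> QuantResult:
    """Invert the Poisson occupancy model on pooled droplet counts.

    Parameters
    ----------
    k, n
        Positive and accepted droplet counts (possibly merged).
    droplet_volume
        Droplet volume in microliters.
    ci_level
        Coverage of the Clopper–Pearson interval (default 0.95).
    """
    if n <= 0:
        raise ValidationError("poisson_quantify: n must be positive")
    if not 0 <= k <= n:
        raise ValidationError(f"poisson_quantify: k={k} outside [0, n={n}]")
    if droplet_volume <= 0:
        raise ValidationError("poisson_quantify: droplet_volume must be positive")
    p_low, p_high = _clopper_pearson(k, n, ci_level)
    ci_low = -math.log1p(-p_low) / droplet_volume
    saturated = k == n
    if saturated:
        lam = math.inf
        conc = math.inf
        ci_high = math.inf
    else:
        lam = -math.log1p(-k / n)
        conc = lam / droplet_volume
        ci_high = -math.log1p(-p_high) / droplet_volume
    return QuantResult(
        lambda_hat=lam,
        concentration=conc,
        ci_low=ci_low,
        ci_high=ci_high,
        k_merged=int(k),
        n_merged=int(n),
        n_wells=n_wells,
        saturated=saturated,
        qc_pass=qc_pass,
        droplet_volume=droplet_volume,
        ci_level=ci_level,
    )


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def quantify_wells(
    wells: Sequence[DropletWell],
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    ci_level: float = 0.95,
) -> QuantResult:
    """Merge a QC-passed replicate group and quantify it."""
    k, n = merge_replicates(wells)
    return poisson_quantify(
        k, n, droplet_volume=droplet_volume, ci_level=ci_level, n_wells=len(wells)
    )


@dataclass
class MrdMeasurement:
    """Target and control quantifications for one sample, plus the MRD ratio.

    ``dilution_factor`` records any cDNA predilution (e.g. 5 for 1:5). It
    cancels from the ratio when target and control come from the same
    dilution, so it is recorded for audit but never multiplied in.
    ``mrd_class`` is filled by :func:`ddmrd.classify.classify`.
    """

    sample_id: str
    target: Target
    target_result: QuantResult
    control_result: QuantResult
    ratio: float | None = None
    dilution_factor: float = 1.0
    mrd_class: MrdClass | None = None

    def __post_init__(self) -> None:
        if self.ratio is None:
            try:
                self.ratio = mrd_ratio(self.target_result, self.control_result)
            except ControlInadequateError:
                self.ratio = None


def quantify_plate(
    wells: Sequence[DropletWell],
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    ci_level: float = 0.95,
    dilution_factor: float = 1.0,
) -> list[MrdMeasurement]:
    """QC-filter sample wells, merge replicates per (sample, target) and
    pair each fusion-transcript quantification with its ABL1 control.

    Control wells that failed droplet-count QC leave ``qc_pass`` False on
    the control result, which downstream makes the ratio undefined and the
    sample non-evaluable rather than silently negative.
    """
    from .io import Role  # local import to keep module header lean

    sample_wells = [w for w in wells if w.role is Role.SAMPLE]
    accepted, _ = qc_filter(sample_wells, min_droplets)
    by_sample: dict[str, dict[Target, list[DropletWell]]] = {}
    for w in accepted:
        by_sample.setdefault(w.sample_id, {}).setdefault(w.target, []).append(w)
    out: list[MrdMeasurement] = []
    for sample_id in sorted(by_sample):
        groups = by_sample[sample_id]
        ctrl_wells = groups.get(Target.CONTROL_ABL1)
        if ctrl_wells:
            control = quantify_wells(ctrl_wells, droplet_volume, ci_level)
        else:
            control = poisson_quantify(0, 1, droplet_volume, ci_level, qc_pass=False)
        for target in (Target.P190, Target.P210):
            if target not in groups:
                continue
            tres = quantify_wells(groups[target], droplet_volume, ci_level)
            out.append(
                MrdMeasurement(
                    sample_id=sample_id,
                    target=target,
                    target_result=tres,
                    control_result=control,
                    dilution_factor=dilution_factor,
                )
            )
    return out


def mrd_ratio(target: QuantResult, control: QuantResult) -> float:
    """(C_target / C_control) x 100, the BCR-ABL1/ABL1 percent scale.

    Raises
    ------
    ControlInadequateError
        If the control gene failed QC or has zero concentration — the ratio
        is undefined, not zero.
    """
    if not control.qc_pass:
        raise ControlInadequateError("control gene failed QC; ratio undefined")
    if control.concentration <= 0 or control.saturated:
        raise ControlInadequateError(
            "control gene concentration is zero or saturated; ratio undefined"
        )
    return 100.0 * target.concentration / control.concentration
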