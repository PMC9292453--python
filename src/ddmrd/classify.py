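"""Run validation and POS / PNQ / NEG MRD classification.

Interpretation follows EuroMRD-style digital-PCR practice, parameterized
because consortium thresholds evolve: a sample is *detected* at
``min_positive_droplets_detected`` merged positive droplets (default 1) and
*quantifiable* at ``min_positive_droplets_quantifiable`` (default 3, the
usual >= 3 positive partitions convention). A sample whose control gene is
below ``min_control_copies`` cannot be quantified (PNQ if detected) nor
confidently negative (NEG_not_evaluable if undetected).

A run is only interpretable when its plate controls behave: no positive
droplets in NTC / healthy-donor / Ph-negative wells beyond
``max_background_positive`` (default 0 — the assay showed no background at
all in validation) and every plasmid positive-control well amplifying.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ConfigurationError
from .io import BACKGROUND_ROLES, DropletWell, MrdClass, Role
from .quantify import MrdMeasurement

logger = logging.getLogger(__name__)


@dataclass
class ClassificationRules:
    """Thresholds driving POS/PNQ/NEG calls and run validation.

    min_control_copies is a floor, in copies/ul, on the control-gene
    concentration for a sample to be evaluable.
    """

    min_positive_droplets_quantifiable: int = 3
    min_positive_droplets_detected: int = 1
    min_control_copies: float = 1.0
    max_background_positive: int = 0

    def __post_init__(self) -> None:
        if self.min_positive_droplets_detected > self.min_positive_droplets_quantifiable:
            raise ConfigurationError(
                "min_positive_droplets_detected must not exceed "
                "min_positive_droplets_quantifiable"
            )
        if self.min_positive_droplets_detected < 1:
            raise ConfigurationError("min_positive_droplets_detected must be >= 1")
        if self.min_control_copies < 0 or self.max_background_positive < 0:
            raise ConfigurationError("thresholds must be non-negative")
        if self.max_background_positive > 0:
            warnings.warn(
                "max_background_positive > 0: classification thresholds assume a "
                "background-free assay and should be re-derived",
                stacklevel=2,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassificationRules":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown rule keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "min_positive_droplets_quantifiable": self.min_positive_droplets_quantifiable,
                    "min_positive_droplets_detected": self.min_positive_droplets_detected,
                    "min_control_copies": self.min_control_copies,
                    "max_background_positive": self.max_background_positive,
                },
                sort_keys=False,
            ),
            encoding="utf-8",
        )


@dataclass
class RunValidation:
    run_id: str
    ntc_positive_droplets: int
    donor_positive_droplets: int
    plasmid_controls_positive: bool
    valid: bool
    messages: list[str] = field(default_factory=list)


def validate_run(
    wells: Sequence[DropletWell],
    rules: ClassificationRules,
    run_id: str = "run",
) -> RunValidation:
    """Check plate controls; an invalid run blocks classification.

    Background wells (NTC, healthy donor, Ph-negative control) must show at
    most ``max_background_positive`` positive droplets in total, and every
    plasmid-standard well must be positive. At least one NTC is required —
    a plate without one is a configuration error, not an invalid run.
    """
    ntc = [w for w in wells if w.role is Role.NTC]
    if not ntc:
        raise ConfigurationError("validate_run: no NTC well on the plate")
    messages: list[str] = []
    ntc_pos = sum(w.k_positive for w in ntc)
    donor_pos = sum(
        w.k_positive
        for w in wells
        if w.role in (Role.HEALTHY_DONOR, Role.PH_NEGATIVE_CONTROL)
    )
    background_total = ntc_pos + donor_pos
    for w in wells:
        if w.role in BACKGROUND_ROLES and w.k_positive > 0:
            messages.append(
                f"background well {w.well_id} ({w.role.value}) has "
                f"{w.k_positive} positive droplets"
            )
    plasmid = [w for w in wells if w.role is Role.PLASMID_STANDARD]
    plasmid_ok = all(
        w.k_positive >= rules.min_positive_droplets_detected for w in plasmid
    )
    for w in plasmid:
        if w.k_positive < rules.min_positive_droplets_detected:
            messages.append(f"plasmid standard well {w.well_id} did not amplify")
    valid = background_total <= rules.max_background_positive and plasmid_ok
    return RunValidation(
        run_id=run_id,
        ntc_positive_droplets=ntc_pos,
        donor_positive_droplets=donor_pos,
        plasmid_controls_positive=plasmid_ok,
        valid=valid,
        messages=messages,
    )


def classify(measurement: MrdMeasurement, rules: ClassificationRules) -> MrdClass:
    """Assign POS / PNQ / NEG from merged droplet counts.

    Deterministic rule, monotone in the merged target positive count:

    - target k below the detection floor: NEG when the control gene is
      adequate, NEG_not_evaluable when it is not;
    - detected but below the quantifiability floor, or control inadequate:
      PNQ;
    - otherwise POS, with the ratio reported.

    The class is also written back onto ``measurement.mrd_class``.
    """
    k = measurement.target_result.k_merged
    ctrl = measurement.control_result
    control_ok = (
        ctrl.qc_pass
        and not ctrl.saturated
        and ctrl.concentration >= rules.min_control_copies
    )
    if k < rules.min_positive_droplets_detected:
        cls = MrdClass.NEG if control_ok else MrdClass.NEG_NOT_EVALUABLE
    elif k < rules.min_positive_droplets_quantifiable or not control_ok:
        cls = MrdClass.PNQ
    else:
        cls = MrdClass.POS
    measurement.mrd_class = cls
    return cls
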