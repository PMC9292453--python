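"""Synthetic droplet-level data with the statistical structure the
analysis assumes.

A well is ~20,000 droplets of 0.85 nL; at concentration ``C`` copies/ul of
the reaction, each droplet holds at least one template molecule with
probability ``1 - exp(-C * Vd)`` (Poisson occupancy), so positive-droplet
counts are Binomial(n, 1 - exp(-C*Vd)). Rare false-positive "rain" is an
independent per-droplet flip (default rate 0: the validated assay showed
no background). Two-cluster fluorescence amplitudes are optional and
Gaussian, separable by construction.

At the single-molecule scale of LOD experiments, wells are built
molecule-first: the number of template molecules in a replicate is
Poisson(m), a Binomial(., rho) thinning models the fraction of the
reaction that actually ends up in read droplets (droplet generation never
reads the whole 20 ul), and the surviving molecules are scattered into
droplets, so two molecules can share one.

The cohort generator emulates a follow-up population with a mix of true
MRD levels and a threshold-plus-Poisson-detection model of the comparator
Q-RT-PCR call; it is plumbing for end-to-end pipeline checks, not a model
of any real instrument.

All randomness flows through explicit seeds; there is no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import DropletWell, Role, Target
from .lod import DilutionExperiment, DilutionPoint

#: True-level classes a cohort sample can belong to.
COHORT_LEVELS = ("high", "low_quantifiable", "trace", "zero")

#: True target/control fraction ranges (log10) for each cohort level.
_LEVEL_LOG10_RANGES = {
    "high": (-3.0, -1.5),
    "low_quantifiable": (-4.0, -3.0),
    "trace": (-5.0, -4.0),
}


@dataclass
class SimulationConfig:
    """Knobs of the droplet simulator.

    droplet_volume is in microliters (default 8.5e-4, i.e. 0.85 nL).
    partitioned_fraction is the fraction of the reaction's template
    molecules that end up in read droplets. Amplitude clusters must be
    separable: pos_mean > neg_mean + 6 * neg_sd.
    """

    n_droplets_mean: float = 20000.0
    n_droplets_sd: float = 1500.0
    droplet_volume: float = 8.5e-4
    partitioned_fraction: float = 0.8
    rain_rate: float = 0.0
    amplitude_neg_mean: float = 1000.0
    amplitude_neg_sd: float = 50.0
    amplitude_pos_mean: float = 8000.0
    amplitude_pos_sd: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.droplet_volume <= 0:
            raise ConfigurationError("droplet_volume must be positive")
        if not 0 <= self.rain_rate < 1:
            raise ConfigurationError("rain_rate must be in [0, 1)")
        if not 0 < self.partitioned_fraction <= 1:
            raise ConfigurationError("partitioned_fraction must be in (0, 1]")
        if self.n_droplets_mean <= 0:
            raise ConfigurationError("n_droplets_mean must be positive")
        if self.amplitude_pos_mean <= self.amplitude_neg_mean + 6 * self.amplitude_neg_sd:
            raise ConfigurationError(
                "amplitude clusters not separable: need pos_mean > neg_mean + 6*neg_sd"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw_n_droplets(config: SimulationConfig, rng: np.random.Generator) -> int:
    n = int(round(rng.normal(config.n_droplets_mean, config.n_droplets_sd)))
    return max(1, n)


def _amplitudes(
    n: int, k: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    amp = rng.normal(config.amplitude_neg_mean, config.amplitude_neg_sd, size=n)
    if k:
        pos_idx = rng.choice(n, size=k, replace=False)
        amp[pos_idx] = rng.normal(config.amplitude_pos_mean, config.amplitude_pos_sd, size=k)
    return amp


def simulate_well(
    concentration: float,
    config: SimulationConfig,
    role: Role = Role.SAMPLE,
    target: Target = Target.P190,
    well_id: str = "W01",
    sample_id: str = "S1",
    replicate_group: str = "",
    with_amplitudes: bool = False,
    rng: np.random.Generator | None = None,
) -> DropletWell:
    """Simulate one well at ``concentration`` copies/ul of the reaction.

    Each droplet is positive independently with probability
    ``1 - exp(-concentration * droplet_volume)``; a negative droplet is
    then flipped positive with probability ``rain_rate``. With ``rng``
    unset, a fresh generator from ``config.seed`` makes repeated calls
    with identical inputs bit-identical.
    """
    if concentration < 0:
        raise ValidationError("simulate_well: concentration must be >= 0")
    if rng is None:
        rng = config.rng()
    n = _draw_n_droplets(config, rng)
    p_occ = -math.expm1(-concentration * config.droplet_volume)
    p_eff = p_occ + (1.0 - p_occ) * config.rain_rate
    k = int(rng.binomial(n, p_eff))
    return DropletWell(
        well_id=well_id,
        sample_id=sample_id,
        target=target,
        role=role,
        replicate_group=replicate_group,
        n_accepted=n,
        k_positive=k,
        amplitudes=_amplitudes(n, k, config, rng) if with_amplitudes else None,
    )


def simulate_dilution_series(
    base_concentration: float,
    dilution_factors: Sequence[float],
    replicates_per_point: int,
    config: SimulationConfig,
    target: Target = Target.P190,
    sample_id: str = "DIL",
) -> list[list[DropletWell]]:
    """Simulate a dilution series: one replicate group per factor.

    ``dilution_factors`` must be strictly decreasing within (0, 1]; wells
    at factor f sit at ``base_concentration * f`` and record the nominal
    factor in their replicate_group.
    """
    if base_concentration <= 0:
        raise ValidationError("simulate_dilution_series: base_concentration must be > 0")
    if not dilution_factors:
        raise ValidationError("simulate_dilution_series: empty dilution_factors")
    factors = list(dilution_factors)
    if any(not 0 < f <= 1 for f in factors):
        raise ValidationError("dilution_factors must lie in (0, 1]")
    if any(b >= a for a, b in zip(factors, factors[1:])):
        raise ValidationError("dilution_factors must be strictly decreasing")
    if replicates_per_point < 1:
        raise ValidationError("replicates_per_point must be >= 1")
    rng = config.rng()
    groups: list[list[DropletWell]] = []
    for i, f in enumerate(factors):
        group = [
            simulate_well(
                base_concentration * f,
                config,
                target=target,
                well_id=f"D{i:02d}R{r:02d}",
                sample_id=sample_id,
                replicate_group=f"dil_{f:g}",
                rng=rng,
            )
            for r in range(replicates_per_point)
        ]
        groups.append(group)
    return groups


def simulate_lod_experiment(
    copies_per_well: Sequence[float],
    replicates: Sequence[int],
    config: SimulationConfig,
    labels: Sequence[float] | None = None,
    target: Target = Target.P190,
    design_name: str = "replicate_escalation",
) -> DilutionExperiment:
    """Simulate a replicate-escalation LOD experiment, molecule-first.

    Per replicate: the number of template molecules present is
    Poisson(m); Binomial(., partitioned_fraction) of them land in read
    droplets; the survivors are scattered into droplets (collisions
    allowed) and rain may add false positives. ``labels`` default to the
    m values themselves.
    """
    if len(copies_per_well) != len(replicates):
        raise ValidationError(
            "simulate_lod_experiment: copies_per_well and replicates differ in length"
        )
    if any(m < 0 for m in copies_per_well):
        raise ValidationError("simulate_lod_experiment: copies_per_well must be >= 0")
    if labels is None:
        labels = list(copies_per_well)
    elif len(labels) != len(copies_per_well):
        raise ValidationError("simulate_lod_experiment: labels length mismatch")
    rng = config.rng()
    points: list[DilutionPoint] = []
    for i, (m, n_rep, label) in enumerate(zip(copies_per_well, replicates, labels)):
        wells = []
        for r in range(n_rep):
            n = _draw_n_droplets(config, rng)
            molecules = int(rng.poisson(m))
            in_droplets = int(rng.binomial(molecules, config.partitioned_fraction))
            if in_droplets:
                k = len(np.unique(rng.integers(0, n, size=in_droplets)))
            else:
                k = 0
            if config.rain_rate > 0:
                k += int(rng.binomial(n - k, config.rain_rate))
            wells.append(
                DropletWell(
                    well_id=f"L{i:02d}R{r:02d}",
                    sample_id=f"LOD_{label:g}",
                    target=target,
                    role=Role.PLASMID_STANDARD,
                    replicate_group=f"lod_{label:g}",
                    n_accepted=n,
                    k_positive=k,
                )
            )
        points.append(
            DilutionPoint(label=float(label), expected_copies_per_well=float(m), wells=wells)
        )
    return DilutionExperiment(points=points, design_name=design_name)


@dataclass
class CohortSpec:
    """Design of a synthetic paired-method follow-up cohort.

    class_mix gives the proportions of true MRD levels (high /
    low_quantifiable / trace / zero) and must sum to 1.
    qrtpcr_quant_limit is the target/control *fraction* below which the
    comparator cannot quantify (default 1e-4, i.e. 0.01 on the x100
    scale); below it, detection succeeds with probability
    ``1 - exp(-qrtpcr_detect_prob_per_copy * copies_sampled)``.
    """

    n_samples: int = 88
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "high": 0.11,
            "low_quantifiable": 0.25,
            "trace": 0.37,
            "zero": 0.27,
        }
    )
    qrtpcr_quant_limit: float = 1e-4
    qrtpcr_detect_prob_per_copy: float = 0.5
    qrtpcr_control_copies: float = 1e5
    ddpcr_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ConfigurationError("n_samples must be >= 0")
        unknown = set(self.class_mix) - set(COHORT_LEVELS)
        if unknown:
            raise ConfigurationError(f"unknown cohort levels {sorted(unknown)}")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_mix must sum to 1")
        if self.qrtpcr_quant_limit <= 0:
            raise ConfigurationError("qrtpcr_quant_limit must be > 0")


@dataclass
class CohortSample:
    sample_id: str
    level: str
    true_fraction: float  # target/control, not x100
    control_concentration: float  # copies/ul
    qrtpcr_class: str
    wells: list[DropletWell]


def simulate_cohort(
    spec: CohortSpec, config: SimulationConfig
) -> tuple[pd.DataFrame, list[CohortSample]]:
    """Simulate a paired cohort: per sample, ddPCR target+control wells,
    the true ratio, and a comparator Q-RT-PCR call.

    Returns a truth table (DataFrame) and the per-sample well groups.
    Reproducible from ``spec.seed`` alone; ``config.seed`` is ignored here
    so one seed governs the whole cohort.
    """
    rng = np.random.default_rng(spec.seed)
    levels = list(spec.class_mix)
    probs = np.array([spec.class_mix[l] for l in levels])
    samples: list[CohortSample] = []
    rows = []
    for i in range(spec.n_samples):
        sid = f"FU{i + 1:03d}"
        level = str(rng.choice(levels, p=probs))
        if level == "zero":
            frac = 0.0
        else:
            lo, hi = _LEVEL_LOG10_RANGES[level]
            frac = 10.0 ** rng.uniform(lo, hi)
        control_conc = 10.0 ** rng.uniform(1.5, 2.5)
        target_conc = frac * control_conc
        qrt = _qrtpcr_call(frac, spec, rng)
        wells = []
        for r in range(spec.ddpcr_replicates):
            wells.append(
                simulate_well(
                    target_conc, config,
                    target=Target.P190, well_id=f"{sid}_T{r}", sample_id=sid,
                    replicate_group="target", rng=rng,
                )
            )
            wells.append(
                simulate_well(
                    control_conc, config,
                    target=Target.CONTROL_ABL1, well_id=f"{sid}_C{r}", sample_id=sid,
                    replicate_group="control", rng=rng,
                )
            )
        samples.append(CohortSample(sid, level, frac, control_conc, qrt, wells))
        rows.append(
            {
                "sample_id": sid,
                "level": level,
                "true_fraction": frac,
                "true_ratio_pct": 100.0 * frac,
                "control_copies_per_ul": control_conc,
                "qrtpcr_class": qrt,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "level", "true_fraction", "true_ratio_pct",
            "control_copies_per_ul", "qrtpcr_class",
        ],
    )
    return truth, samples


def _qrtpcr_call(fraction: float, spec: CohortSpec, rng: np.random.Generator) -> str:
    if fraction >= spec.qrtpcr_quant_limit:
        return "POS"
    if fraction <= 0:
        return "NEG"
    copies = fraction * spec.qrtpcr_control_copies
    p_detect = -math.expm1(-spec.qrtpcr_detect_prob_per_copy * copies)
    return "PNQ" if rng.random() < p_detect else "NEG"


def make_reference_fixtures(output_dir) -> dict:
    """Write the bundled reference tables as CSV files (see
    :mod:`ddmrd.datasets`)."""
    from . import datasets

    return datasets.write_fixture_files(output_dir)
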