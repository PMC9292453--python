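"""Reading and writing well tables, plate layouts and results.

The well CSV dialect is modeled on QuantaSoft-style exports but fixed to one
locale: comma separator, header row, UTF-8, ``.`` decimal. Columns::

    well_id, sample_id, target, role, replicate_group, n_accepted, k_positive

Per-droplet fluorescence amplitudes, when present, live in a separate
long-format CSV (``well_id, amplitude``) because wells without amplitudes
are the common case and droplet-level tables are four orders of magnitude
larger than well-level ones.

Plate layouts are YAML or JSON mapping ``well_id`` to sample metadata.
Native instrument binaries (.qlp) are out of scope.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

WELL_COLUMNS = [
    "well_id",
    "sample_id",
    "target",
    "role",
    "replicate_group",
    "n_accepted",
    "k_positive",
]
_REQUIRED_COLUMNS = ["well_id", "target", "n_accepted", "k_positive"]


class Target(str, enum.Enum):
    """Assay target: a BCR/ABL1 fusion-transcript isoform or the ABL1 control gene."""

    P190 = "p190"
    P210 = "p210"
    CONTROL_ABL1 = "control_ABL1"


class Role(str, enum.Enum):
    """What a well contains, from the plate layout."""

    SAMPLE = "sample"
    NTC = "NTC"
    HEALTHY_DONOR = "healthy_donor"
    PLASMID_STANDARD = "plasmid_standard"
    PH_NEGATIVE_CONTROL = "ph_negative_control"


BACKGROUND_ROLES = frozenset(
    {Role.NTC, Role.HEALTHY_DONOR, Role.PH_NEGATIVE_CONTROL}
)


class MrdClass(str, enum.Enum):
    """MRD interpretation of a sample.

    ``NEG_NOT_EVALUABLE`` marks target-undetected samples whose control gene
    was inadequate: reporting them as plain NEG would be false reassurance.
    """

    POS = "POS"
    PNQ = "PNQ"
    NEG = "NEG"
    NEG_NOT_EVALUABLE = "NEG_not_evaluable"


@dataclass
class DropletWell:
    """One well's droplet counts plus sample metadata.

    Parameters
    ----------
    n_accepted
        Accepted droplets read by the instrument.
    k_positive
        Droplets called positive for the well's target.
    amplitudes
        Optional per-droplet fluorescence (a.u.); length must equal
        ``n_accepted`` when present.
    """

    well_id: str
    sample_id: str
    target: Target
    role: Role
    replicate_group: str
    n_accepted: int
    k_positive: int
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.target = Target(self.target)
        self.role = Role(self.role)
        self.n_accepted = int(self.n_accepted)
        self.k_positive = int(self.k_positive)
        if self.n_accepted < 0:
            raise ValidationError(f"well {self.well_id}: n_accepted < 0")
        if not 0 <= self.k_positive <= self.n_accepted:
            raise ValidationError(
                f"well {self.well_id}: k_positive={self.k_positive} outside "
                f"[0, n_accepted={self.n_accepted}]"
            )
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if len(self.amplitudes) != self.n_accepted:
                raise ValidationError(
                    f"well {self.well_id}: {len(self.amplitudes)} amplitudes "
                    f"for {self.n_accepted} accepted droplets"
                )


@dataclass
class WellMeta:
    sample_id: str
    target: Target
    role: Role = Role.SAMPLE
    replicate_group: str = ""


@dataclass
class PlateLayout:
    """Mapping well_id -> sample metadata for one run."""

    run_id: str
    wells: dict[str, WellMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for well_id, meta in self.wells.items():
            if not isinstance(meta, WellMeta):
                self.wells[well_id] = WellMeta(
                    sample_id=meta["sample_id"],
                    target=Target(meta["target"]),
                    role=Role(meta.get("role", "sample")),
                    replicate_group=str(meta.get("replicate_group", "")),
                )


def read_layout(path: str | Path) -> PlateLayout:
    """Read a plate layout from YAML (``.yaml``/``.yml``) or JSON."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "wells" not in raw:
        raise FormatError(f"{path}: layout must be a mapping with a 'wells' key")
    wells = raw["wells"]
    if len(set(wells)) != len(wells):  # dict keys are unique by construction
        raise FormatError(f"{path}: duplicate well_ids")
    try:
        return PlateLayout(run_id=str(raw.get("run_id", path.stem)), wells=dict(wells))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad layout entry: {exc}") from exc


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    path = Path(path)
    raw = {
        "run_id": layout.run_id,
        "wells": {
            wid: {
                "sample_id": m.sample_id,
                "target": m.target.value,
                "role": m.role.value,
                "replicate_group": m.replicate_group,
            }
            for wid, m in layout.wells.items()
        },
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(raw, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=False), encoding="utf-8")


def read_wells(
    path: str | Path,
    layout: PlateLayout | None = None,
    strict: bool = True,
) -> list[DropletWell]:
    """Read a well-level droplet CSV.

    Rows are validated against the droplet-count invariants; metadata from
    ``layout`` fills or overrides the CSV's sample/target/role columns.
    With ``strict=False`` malformed rows are logged (with 1-based data line
    numbers) and skipped instead of raising; rows are never dropped silently.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    wells: list[DropletWell] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        well_id = rec["well_id"]
        meta = layout.wells.get(well_id) if layout is not None else None
        try:
            wells.append(
                DropletWell(
                    well_id=well_id,
                    sample_id=(meta.sample_id if meta else rec.get("sample_id", "") or ""),
                    target=Target(meta.target if meta else rec["target"]),
                    role=Role(meta.role if meta else rec.get("role", "") or "sample"),
                    replicate_group=(
                        meta.replicate_group if meta else rec.get("replicate_group", "") or ""
                    ),
                    n_accepted=int(rec["n_accepted"]),
                    k_positive=int(rec["k_positive"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"{path} line {i}: {exc}")
    if problems:
        for msg in problems:
            logger.warning("rejected row: %s", msg)
        if strict:
            raise ValidationError("; ".join(problems))
    return wells


def write_wells(wells: Iterable[DropletWell], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "well_id": w.well_id,
                "sample_id": w.sample_id,
                "target": w.target.value,
                "role": w.role.value,
                "replicate_group": w.replicate_group,
                "n_accepted": w.n_accepted,
                "k_positive": w.k_positive,
            }
            for w in wells
        ],
        columns=WELL_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_amplitudes(wells: Iterable[DropletWell], path: str | Path) -> None:
    """Write per-droplet amplitudes in long format (well_id, amplitude)."""
    frames = [
        pd.DataFrame({"well_id": w.well_id, "amplitude": w.amplitudes})
        for w in wells
        if w.amplitudes is not None
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["well_id", "amplitude"])
    )
    out.to_csv(path, index=False, float_format="%.6g")


def read_amplitudes(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    if not {"well_id", "amplitude"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns well_id, amplitude")
    return {
        wid: grp["amplitude"].to_numpy(dtype=float)
        for wid, grp in df.groupby("well_id", sort=False)
    }


def attach_amplitudes(
    wells: Sequence[DropletWell], amplitudes: Mapping[str, np.ndarray]
) -> None:
    """Attach long-format amplitudes to wells in place (lengths validated)."""
    for w in wells:
        if w.well_id in amplitudes:
            amp = np.asarray(amplitudes[w.well_id], dtype=float)
            if len(amp) != w.n_accepted:
                raise ValidationError(
                    f"well {w.well_id}: {len(amp)} amplitudes for "
                    f"{w.n_accepted} accepted droplets"
                )
            w.amplitudes = amp


RESULT_COLUMNS = [
    "sample_id",
    "target",
    "k_merged",
    "n_merged",
    "target_copies_per_ul",
    "target_ci_low",
    "target_ci_high",
    "control_copies_per_ul",
    "control_ci_low",
    "control_ci_high",
    "ratio_pct",
    "mrd_class",
    "dilution_factor",
    "droplet_volume_ul",
]


def write_results(results: Sequence, path: str | Path) -> None:
    """Write merged quantification results, one row per sample.

    ``results`` is a sequence of :class:`ddmrd.quantify.MrdMeasurement`.
    Numbers are serialized to 6 significant digits; column order is fixed.
    """
    if not results:
        raise ValidationError("write_results: empty result set")
    rows = []
    for m in results:
        t, c = m.target_result, m.control_result
        rows.append(
            {
                "sample_id": m.sample_id,
                "target": m.target.value,
                "k_merged": t.k_merged,
                "n_merged": t.n_merged,
                "target_copies_per_ul": t.concentration,
                "target_ci_low": t.ci_low,
                "target_ci_high": t.ci_high,
                "control_copies_per_ul": c.concentration,
                "control_ci_low": c.ci_low,
                "control_ci_high": c.ci_high,
                "ratio_pct": m.ratio if m.ratio is not None else np.nan,
                "mrd_class": m.mrd_class.value if m.mrd_class is not None else "",
                "dilution_factor": m.dilution_factor,
                "droplet_volume_ul": t.droplet_volume,
            }
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing result columns {missing}")
    return df


def read_class_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read paired method calls: CSV with columns qrtpcr_class, ddpcr_class."""
    df = pd.read_csv(path, dtype=str)
    if not {"qrtpcr_class", "ddpcr_class"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns qrtpcr_class, ddpcr_class")
    return list(zip(df["qrtpcr_class"], df["ddpcr_class"]))
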