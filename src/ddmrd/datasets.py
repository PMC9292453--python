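"""Bundled reference tables from the assay-validation study.

Three small tables, transcribed verbatim, drive worked examples, the
``reproduce`` command and the regression tests:

- ``DIAGNOSTIC_TABLE``: paired Q-RT-PCR vs ddPCR values (BCR-ABL1/ABL1
  x 100 per ul) for 10 diagnostic samples; one sample (DX4) carries both
  the p190 and p210 transcript, hence 11 value pairs.
- ``FOLLOWUP_CROSSTAB``: the 3x3 cross-classification of 88 follow-up
  samples (rows ddPCR, columns Q-RT-PCR; order POS, PNQ, NEG).
- ``LOD_POSITIVITY``: replicate positivity of the dilution-series LOD
  experiment, label -> (replicates, positives).

``REFERENCE_VALUES`` holds the headline statistics reported for these
tables, used by ``reproduce`` to flag pass/fail.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .concordance import CrosstabResult, crosstab
from .lod import PositivityTable

#: (sample_id, transcript, qrtpcr, ddpcr) — ratio scale (target/control) x 100.
DIAGNOSTIC_TABLE: list[tuple[str, str, float, float]] = [
    ("DX1", "p210", 109.3, 78.0),
    ("DX2", "p210", 126.9, 109.0),
    ("DX3", "p190", 71.86, 84.0),
    ("DX4", "p190", 0.08, 0.05),
    ("DX4", "p210", 85.61, 87.98),
    ("DX5", "p190", 81.0, 71.0),
    ("DX6", "p210", 103.0, 80.0),
    ("DX7", "p190", 75.0, 88.0),
    ("DX8", "p210", 103.6, 77.0),
    ("DX9", "p190", 67.5, 79.0),
    ("DX10", "p190", 63.6, 64.0),
]

#: rows ddPCR (POS, PNQ, NEG) x columns Q-RT-PCR (POS, PNQ, NEG); n = 88.
FOLLOWUP_CROSSTAB: list[list[int]] = [
    [10, 29, 7],
    [0, 13, 4],
    [0, 12, 13],
]

#: dilution label (fraction) -> (n_replicates, n_positive_replicates).
LOD_POSITIVITY: dict[float, tuple[int, int]] = {
    1e-4: (2, 2),
    5e-5: (6, 6),
    1e-5: (8, 6),
    5e-6: (12, 2),
    1e-6: (14, 2),
}

#: Replicate-escalation design of the LOD experiment.
LOD_REPLICATE_DESIGN: tuple[int, ...] = (2, 6, 8, 12, 14)
LOD_DILUTION_LABELS: tuple[float, ...] = (1e-4, 5e-5, 1e-5, 5e-6, 1e-6)

#: The protocol's printed template copy numbers for the dilution points
#: (four values for five labels — the mapping was left ambiguous), and a
#: log-scale-consistent per-label assignment anchored at 10 copies for 1e-4.
#: Simulation APIs take explicit copies, so neither labeling is ever guessed.
LOD_COPIES_PRINTED: tuple[float, ...] = (5.0, 2.0, 1.0, 0.5)
LOD_COPIES_BY_LABEL_LOGSCALE: dict[float, float] = {
    1e-4: 10.0,
    5e-5: 5.0,
    1e-5: 1.0,
    5e-6: 0.5,
    1e-6: 0.1,
}

#: Headline statistics reported for the bundled tables.
REFERENCE_VALUES: dict[str, float] = {
    "pearson_r_2dp": 0.87,
    "overall_concordance_pct_1dp": 40.9,
    "overall_concordance_nearest_int": 41,
    "quantifiability_recovery_nearest_int": 46,
    "pnq_quantifiable_pct_1dp": 53.7,
    "neg_confirmed_count": 13,
    "neg_total": 24,
    "mcnemar_p_below": 1e-4,
    "max_sensitivity_dilution": 1e-5,
}


def diagnostic_pairs(policy: str = "per_transcript") -> list[tuple[float, float]]:
    """Paired (Q-RT-PCR, ddPCR) diagnostic values.

    ``per_transcript`` (default): each transcript contributes its own pair,
    so the dual-transcript sample yields two pairs (11 total).
    ``sum_transcripts``: a dual-transcript sample contributes the sum of
    its two transcript ratios (10 pairs).
    """
    if policy == "per_transcript":
        return [(q, d) for _, _, q, d in DIAGNOSTIC_TABLE]
    if policy == "sum_transcripts":
        agg: dict[str, list[float]] = {}
        for sid, _, q, d in DIAGNOSTIC_TABLE:
            agg.setdefault(sid, [0.0, 0.0])
            agg[sid][0] += q
            agg[sid][1] += d
        return [tuple(v) for v in agg.values()]
    raise ValueError(f"unknown pairing policy {policy!r}")


def followup_pairs() -> list[tuple[str, str]]:
    """Expand the follow-up cross-tab into 88 (qrtpcr, ddpcr) class pairs."""
    order = ("POS", "PNQ", "NEG")
    pairs = []
    for i, dd in enumerate(order):
        for j, qrt in enumerate(order):
            pairs.extend([(qrt, dd)] * FOLLOWUP_CROSSTAB[i][j])
    return pairs


def followup_crosstab() -> CrosstabResult:
    return crosstab(followup_pairs())


def lod_positivity_table() -> PositivityTable:
    return PositivityTable.from_counts(
        [(label, n, k) for label, (n, k) in LOD_POSITIVITY.items()]
    )


def write_fixture_files(output_dir: str | Path) -> dict[str, Path]:
    """Write the bundled tables as CSV files; returns name -> path.

    Files round-trip losslessly through the package readers.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = outdir / "diagnostic_comparison.csv"
    pd.DataFrame(
        DIAGNOSTIC_TABLE, columns=["sample_id", "transcript", "qrtpcr", "ddpcr"]
    ).to_csv(p, index=False)
    paths["diagnostic_comparison"] = p

    p = outdir / "followup_class_pairs.csv"
    pd.DataFrame(followup_pairs(), columns=["qrtpcr_class", "ddpcr_class"]).to_csv(
        p, index=False
    )
    paths["followup_class_pairs"] = p

    p = outdir / "lod_positivity.csv"
    pd.DataFrame(
        [
            {
                "dilution_label": label,
                "n_replicates": n,
                "n_positive_replicates": k,
            }
            for label, (n, k) in LOD_POSITIVITY.items()
        ]
    ).to_csv(p, index=False)
    paths["lod_positivity"] = p
    return paths


def read_diagnostic_csv(path: str | Path) -> list[tuple[str, str, float, float]]:
    """Read a diagnostic comparison CSV back into table rows."""
    df = pd.read_csv(path)
    return [
        (str(r.sample_id), str(r.transcript), float(r.qrtpcr), float(r.ddpcr))
        for r in df.itertuples(index=False)
    ]


def read_lod_positivity_csv(path: str | Path) -> PositivityTable:
    df = pd.read_csv(path)
    return PositivityTable.from_counts(
        [
            (float(r.dilution_label), int(r.n_replicates), int(r.n_positive_replicates))
            for r in df.itertuples(index=False)
        ]
    )
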