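"""RIP-qPCR quantification: percent-of-input and fold enrichment.

Recovery of a transcript in an immunoprecipitate is expressed as percent of
input with a correction for the input aliquot fraction:

    percent_input = 100 * 2 ** (Ct_input - log2(100 / input_fraction) - Ct_IP)

With the default 2.5% input aliquot the correction term is log2(40), so
equal Ct values give exactly 2.5%.  Fold enrichment is the percent-input
ratio of a sample over its empty-vector control, aggregated mean-then-ratio
at the percent level across replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError


@dataclass(frozen=True)
class QPCRMeasurement:
    ct_input: float
    ct_ip: float
    input_fraction_percent: float = 2.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_input) and math.isfinite(self.ct_ip)):
            raise ValueError("Ct values must be finite")
        if not 0 < self.input_fraction_percent <= 100:
            raise ValueError("input_fraction_percent must be in (0, 100]")


def percent_input(m: QPCRMeasurement) -> float:
    """100 * 2^(Ct_input - log2(100/input_fraction) - Ct_IP), in percent."""
    exponent = m.ct_input - math.log2(100.0 / m.input_fraction_percent) - m.ct_ip
    return 100.0 * 2.0 ** exponent


def fold_enrichment(percent_sample: float, percent_control: float) -> float:
    """Percent-input ratio of sample over (empty-vector) control."""
    if percent_control <= 0:
        raise InvalidInputError("control percent-input must be positive")
    return percent_sample / percent_control


def percent_input_table(
    table: pd.DataFrame,
    input_fraction_percent: float = 2.5,
    control: str | None = None,
) -> pd.DataFrame:
    """Apply the percent-input formula to a Ct table.

    *table* needs columns ``sample``, ``ct_input``, ``ct_ip``; replicate
    rows sharing a sample name are aggregated as mean percent-input.  When
    *control* names a sample, a ``fold_vs_control`` column reports each
    sample's mean percent relative to the control's mean percent.
    """
    required = {"sample", "ct_input", "ct_ip"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    df = table.copy()
    df["percent_input"] = [
        percent_input(QPCRMeasurement(ci, cp, input_fraction_percent))
        for ci, cp in zip(df["ct_input"].astype(float), df["ct_ip"].astype(float))
    ]
    agg = (
        df.groupby("sample", sort=False)["percent_input"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "percent_input_mean",
                         "std": "percent_input_sd", "count": "n"})
    )
    if control is not None:
        if control not in set(agg["sample"]):
            raise ValueError(f"control sample {control!r} not in table")
        ctrl = float(agg.loc[agg["sample"] == control, "percent_input_mean"].iloc[0])
        agg["fold_vs_control"] = [
            fold_enrichment(v, ctrl) for v in agg["percent_input_mean"]
        ]
    return agg
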