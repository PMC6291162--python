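"""Plate-assay normalization and group comparison.

Two assay layouts are handled, both anchored to a no-template control
(NTC, wells with no expressed protein):

* GTPase luminescence: the signal measures remaining free GTP, so the NTC
  (no enzyme, no hydrolysis) carries the maximal signal. Raw signals are
  rescaled so the NTC mean is 100 (percent remaining GTP) and activity is
  ``100 - scaled signal``; NTC activity is 0 by construction.
* Effector-binding absorbance (G-LISA style): binding is the raw signal
  divided by the NTC mean, so NTC binding is 1 by construction. An
  optional per-construct western-blot intensity factor corrects for
  protein-amount differences.

Group comparisons use Welch's (unequal-variance) two-sided t-test, with
significance tiers rendered as the conventional star strings.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Well",
    "PlateAssay",
    "NormalizationError",
    "normalize_gtpase",
    "normalize_glisa",
    "compare_groups",
    "significance_tier",
    "read_assay_csv",
]

NTC = "NTC"
ASSAY_TYPES = ("gtpase_luminescence", "glisa_absorbance")


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class Well:
    construct: str
    replicate: int
    signal: float
    assay_type: str

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"negative raw signal for {self.construct}")
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"unknown assay type {self.assay_type!r}")


@dataclass
class PlateAssay:
    """Replicate well signals for one assay, plus optional western factors."""

    wells: list[Well]
    western_intensity: dict[str, float] = field(default_factory=dict)

    @property
    def assay_type(self) -> str:
        kinds = {w.assay_type for w in self.wells}
        if len(kinds) != 1:
            raise ValueError(f"mixed assay types in one plate: {sorted(kinds)}")
        return next(iter(kinds))

    def ntc_mean(self) -> float:
        sig = [w.signal for w in self.wells if w.construct == NTC]
        if not sig:
            raise NormalizationError("no NTC wells present")
        return float(np.mean(sig))

    def constructs(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.construct)
        return list(seen)


def normalize_gtpase(assay: PlateAssay) -> list[dict]:
    """Per-well GTPase activity on the NTC-anchored percent scale."""
    if assay.assay_type != "gtpase_luminescence":
        raise NormalizationError(
            f"expected gtpase_luminescence wells, got {assay.assay_type}"
        )
    ntc = assay.ntc_mean()
    if ntc <= 0:
        raise NormalizationError("NTC mean signal is zero; cannot normalize")
    return [
        {
            "construct": w.construct,
            "replicate": w.replicate,
            "raw": w.signal,
            "value": 100.0 - 100.0 * w.signal / ntc,
        }
        for w in assay.wells
    ]


def normalize_glisa(assay: PlateAssay, western_corrected: bool = False) -> list[dict]:
    """Per-well effector binding relative to the NTC mean.

    With ``western_corrected`` each construct's binding is further divided
    by its relative western band intensity, correcting for differing
    amounts of purified protein.
    """
    if assay.assay_type != "glisa_absorbance":
        raise NormalizationError(
            f"expected glisa_absorbance wells, got {assay.assay_type}"
        )
    ntc = assay.ntc_mean()
    if ntc <= 0:
        raise NormalizationError("NTC mean signal is zero; cannot normalize")
    out = []
    for w in assay.wells:
        value = w.signal / ntc
        if western_corrected:
            factor = assay.western_intensity.get(w.construct)
            if factor:
                value /= factor
        out.append(
            {"construct": w.construct, "replicate": w.replicate,
             "raw": w.signal, "value": value}
        )
    return out


def significance_tier(p: float) -> str:
    """Conventional star tiers for a p-value."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    normalized: Sequence[Mapping],
    reference: str,
) -> list[dict]:
    """Welch t-test of each construct against a reference construct.

    Returns one row per non-reference construct with mean, sd, sem,
    two-sided p versus the reference and its star tier. Groups with fewer
    than two replicates are reported with ``skipped`` set and no p-value.
    """
    groups: dict[str, list[float]] = {}
    for row in normalized:
        groups.setdefault(row["construct"], []).append(float(row["value"]))
    if reference not in groups:
        raise KeyError(f"reference construct {reference!r} not in data")
    ref = np.asarray(groups[reference], dtype=float)
    rows = []
    for construct, values in groups.items():
        if construct == reference:
            continue
        arr = np.asarray(values, dtype=float)
        row: dict = {
            "construct": construct,
            "n": len(arr),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
            "sem": float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else float("nan"),
            "reference": reference,
            "skipped": False,
        }
        if len(arr) < 2 or len(ref) < 2:
            row.update(p=None, tier="", skipped=True,
                       warning="fewer than 2 replicates; comparison skipped")
        else:
            if np.allclose(arr, arr[0]) and np.allclose(ref, ref[0]) and math.isclose(arr[0], ref[0]):
                p = 1.0  # identical constant groups: no evidence of difference
            else:
                p = float(stats.ttest_ind(arr, ref, equal_var=False).pvalue)
            row.update(p=p, tier=significance_tier(p))
        rows.append(row)
    return rows


def read_assay_csv(path: str | Path, western_path: str | Path | None = None) -> PlateAssay:
    """Read a long-format CSV (assay, construct, replicate, signal).

    ``western_path`` optionally points to a CSV with columns
    (construct, relative_intensity).
    """
    wells = []
    with Path(path).open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            wells.append(
                Well(
                    construct=row["construct"],
                    replicate=int(row["replicate"]),
                    signal=float(row["signal"]),
                    assay_type=row["assay"],
                )
            )
    western = {}
    if western_path is not None:
        with Path(western_path).open(encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                western[row["construct"]] = float(row["relative_intensity"])
    return PlateAssay(wells=wells, western_intensity=western)
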