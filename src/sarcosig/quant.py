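"""qPCR standard-curve copy-number quantification and FISH summaries.

Standard-curve quantification: each assay gets a least-squares line of Ct
versus log10 template quantity; sample Cts are converted to quantities and
the target/control quantity ratio is normalized to the same ratio in a
non-amplified reference sample (reference = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "CnvResult",
    "FishSummary",
    "fit_standard_curve",
    "quantity_from_ct",
    "relative_copy_number",
    "relative_copy_number_table",
    "summarize_fish",
    "positivity_percent",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit Ct = intercept + slope * log10(quantity) for one assay."""

    assay: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 10**(-1/slope) - 1 (1.0 = 100%)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(
    standards: Sequence[tuple[float, float]] | pd.DataFrame, assay: str = ""
) -> StandardCurve:
    """Least-squares standard curve from (log10_quantity, Ct) pairs.

    Accepts a sequence of pairs or a DataFrame with ``log10_quantity`` and
    ``ct`` columns.  Needs at least 2 distinct quantities; with exactly 2
    points the line passes through both (r² = 1).
    """
    if isinstance(standards, pd.DataFrame):
        logq = standards["log10_quantity"].to_numpy(float)
        ct = standards["ct"].to_numpy(float)
    else:
        arr = np.asarray(standards, dtype=float)
        logq, ct = arr[:, 0], arr[:, 1]
    if not (np.isfinite(logq).all() and np.isfinite(ct).all()):
        raise ValueError("non-finite values in standards")
    if np.unique(logq).size < 2:
        raise ValueError("need at least 2 distinct log10 quantities")
    fit = stats.linregress(logq, ct)
    return StandardCurve(
        assay=assay,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def quantity_from_ct(curve: StandardCurve, ct: float) -> float:
    """Invert the standard curve: quantity = 10**((Ct - intercept) / slope)."""
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


@dataclass(frozen=True)
class CnvResult:
    sample_id: str
    target: str
    control: str
    relative_copy_number: float


def relative_copy_number(
    sample_ct: Mapping[str, float],
    reference_ct: Mapping[str, float],
    curves: Mapping[str, StandardCurve],
    target: str,
    control: str,
    sample_id: str = "",
) -> CnvResult:
    """Relative target copy number of one sample versus a reference sample.

    Cts are converted to quantities through each assay's standard curve;
    the result is the sample's target/control quantity ratio divided by the
    reference sample's target/control ratio (reference = 1).
    """
    for assay in (target, control):
        if assay not in curves:
            raise KeyError(f"no standard curve for assay {assay!r}")
        for name, table in (("sample", sample_ct), ("reference", reference_ct)):
            if assay not in table:
                raise KeyError(f"missing {assay!r} Ct for {name}")
            if not np.isfinite(table[assay]):
                raise ValueError(f"non-finite {assay!r} Ct for {name}")

    def ratio(cts: Mapping[str, float]) -> float:
        qt = quantity_from_ct(curves[target], cts[target])
        qc = quantity_from_ct(curves[control], cts[control])
        if qc == 0:
            raise ValueError("control quantity is zero")
        return qt / qc

    return CnvResult(
        sample_id=sample_id,
        target=target,
        control=control,
        relative_copy_number=ratio(sample_ct) / ratio(reference_ct),
    )


def relative_copy_number_table(
    ct_table: pd.DataFrame,
    curves: Mapping[str, StandardCurve],
    target: str,
    control: str,
    reference: str,
) -> pd.DataFrame:
    """Relative copy number for every sample of a long-format Ct table.

    ``ct_table`` has columns ``sample_id``, ``assay``, ``ct``; technical
    replicates (repeated sample/assay rows) are collapsed by mean Ct before
    the quantity transformation.  ``reference`` names the non-amplified
    reference sample, whose result is 1 by construction.
    """
    mean_ct = (
        ct_table.groupby(["sample_id", "assay"])["ct"].mean().unstack("assay")
    )
    if reference not in mean_ct.index:
        raise ValueError(f"reference sample {reference!r} not in Ct table")
    ref = mean_ct.loc[reference].to_dict()
    rows = [
        relative_copy_number(
            mean_ct.loc[sid].to_dict(), ref, curves, target, control, sample_id=sid
        )
        for sid in mean_ct.index
    ]
    out = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "target": target,
            "control": control,
            "relative_copy_number": [r.relative_copy_number for r in rows],
        }
    )
    return out.set_index("sample_id")


@dataclass(frozen=True)
class FishSummary:
    """Per-specimen FISH metrics over a per-cell signal-count table."""

    n_cells: int
    target_centromere_ratio: float
    percent_gt4: float  # % of cells with target count strictly > 4
    mean_target_per_cell: float


def summarize_fish(
    cells: pd.DataFrame,
    target_col: str = "met_count",
    centromere_col: str = "cen7_count",
    ratio_method: str = "ratio_of_means",
) -> FishSummary:
    """Summarize a per-cell FISH count table.

    Metrics: target/centromere ratio (ratio of means by default,
    ``mean_of_ratios`` selectable and restricted to cells with nonzero
    centromere count), percentage of cells with strictly more than 4 target
    signals, and mean target signals per cell.  A warning is issued when
    fewer than 100 cells were counted.
    """
    if cells.empty:
        raise ValueError("empty FISH cell table")
    t = cells[target_col].to_numpy(float)
    c = cells[centromere_col].to_numpy(float)
    if (t < 0).any() or (c < 0).any():
        raise ValueError("negative signal counts")
    if c.sum() == 0:
        raise ValueError("all centromere counts are zero")
    if ratio_method == "ratio_of_means":
        ratio = t.mean() / c.mean()
    elif ratio_method == "mean_of_ratios":
        ok = c > 0
        ratio = float((t[ok] / c[ok]).mean())
    else:
        raise ValueError(f"unknown ratio_method {ratio_method!r}")
    n = len(cells)
    if n < 100:
        warnings.warn(f"only {n} cells counted (< 100)")
    return FishSummary(
        n_cells=n,
        target_centromere_ratio=float(ratio),
        percent_gt4=float(100.0 * (t > 4).mean()),
        mean_target_per_cell=float(t.mean()),
    )


def positivity_percent(flags: Iterable[bool]) -> int:
    """Percentage of positive entries in a screen, nearest integer percent."""
    flags = [bool(f) for f in flags]
    if not flags:
        raise ValueError("empty screen table")
    return int(round(100.0 * sum(flags) / len(flags)))
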