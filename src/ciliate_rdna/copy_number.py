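"""Copies-per-cell estimation from digital PCR partitions and qPCR curves.

Digital PCR partitions a reaction into thousands of droplets; under Poisson
occupancy the mean copies per partition is lambda = -ln(1 - k/n) for k
positive partitions out of n, and the total template in the reaction is
lambda * n.  Scaling by the dilution factor and the fraction of the
single-cell extract loaded gives absolute copies per cell — the quantity a
chip reader's software reports, reconstructed here explicitly.  A 95%
confidence interval comes from the Wilson score interval on the positive
fraction propagated through the same transform (partition volume cancels for
per-cell reporting, so it is not required).

qPCR absolute quantification inverts a user-supplied standard curve
Cq = intercept + slope * log10(copies).

Cell volumes use the two shape approximations commonly applied to ciliate
cells: elongate bell/cone forms get (1/3) * pi * L * (W/2) * (T/2), roughly
cuboid forms get L * W * T, with thickness T = width / (width:thickness).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

__all__ = [
    "PartitionData",
    "CopyNumberEstimate",
    "StandardCurve",
    "CellGeometry",
    "SaturationError",
    "dpcr_lambda",
    "dpcr_copies_per_cell",
    "qpcr_copies",
    "fold_range",
    "marker_ratio",
    "pearson_r",
    "cell_volume",
    "summarize_copy_numbers",
    "load_reference_survey",
    "marker_comparison",
    "TETRAHYMENA_MTSSU_TEXT_VARIANT",
]

#: The narrative copy-number section quotes Tetrahymena mtSSU as
#: 1.0e4 +/- 9.6e3 while the printed table rounds the mean to 1.1e4; the
#: shipped fixture stores the printed table value and this constant keeps the
#: narrative variant available.
TETRAHYMENA_MTSSU_TEXT_VARIANT = (1.0e4, 9.6e3)


class SaturationError(ValueError):
    """All partitions positive: lambda is unbounded and no estimate exists."""


@dataclass(frozen=True)
class PartitionData:
    """One digital-PCR reaction loaded from a (possibly diluted) single-cell
    extract."""

    n_partitions: int
    n_positive: int
    fraction_loaded: float = 1.0
    dilution_factor: float = 1.0
    cells_in_extract: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_partitions:
            raise ValueError("need 0 <= n_positive <= n_partitions")
        if not 0 < self.fraction_loaded <= 1:
            raise ValueError("fraction_loaded must be in (0, 1]")
        if self.dilution_factor <= 0 or self.cells_in_extract < 1:
            raise ValueError("dilution_factor > 0 and cells_in_extract >= 1 required")


@dataclass(frozen=True)
class CopyNumberEstimate:
    copies_per_cell: float
    ci_low: float
    ci_high: float
    method: Literal["dPCR", "qPCR"]

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.copies_per_cell <= self.ci_high):
            raise ValueError("require 0 <= ci_low <= estimate <= ci_high")


@dataclass(frozen=True)
class StandardCurve:
    """qPCR standard curve Cq = intercept + slope * log10(copies)."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")

    @property
    def efficiency(self) -> float:
        return 10 ** (-1 / self.slope) - 1


@dataclass(frozen=True)
class CellGeometry:
    """Cell dimensions in micrometres; thickness derives from the
    width:thickness ratio measured under the microscope."""

    length: float
    width: float
    width_thickness_ratio: float
    shape: Literal["cuboid", "bell_cone"]

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.width_thickness_ratio) <= 0:
            raise ValueError("all dimensions must be positive")

    @property
    def thickness(self) -> float:
        return self.width / self.width_thickness_ratio


def dpcr_lambda(n_positive: int, n_partitions: int) -> float:
    """Mean copies per partition from the positive-partition count.

    Inverts the Poisson occupancy probability P(positive) = 1 - exp(-lambda).
    """
    if n_positive < 0 or n_partitions <= 0 or n_positive > n_partitions:
        raise ValueError("need 0 <= n_positive <= n_partitions, n_partitions > 0")
    if n_positive == n_partitions:
        raise SaturationError(
            f"all {n_partitions} partitions positive: lambda unbounded"
        )
    return -math.log1p(-n_positive / n_partitions)


def dpcr_copies_per_cell(data: PartitionData) -> CopyNumberEstimate:
    """Absolute copies per cell with a 95% Wilson confidence interval.

    copies = lambda * n_partitions * dilution_factor
             / (fraction_loaded * cells_in_extract)
    """
    lam = dpcr_lambda(data.n_positive, data.n_partitions)
    scale = data.dilution_factor / (data.fraction_loaded * data.cells_in_extract)

    def transform(p: float) -> float:
        return -math.log1p(-min(p, 1 - 1e-300)) * data.n_partitions * scale

    p_low, p_high = proportion_confint(
        data.n_positive, data.n_partitions, alpha=0.05, method="wilson"
    )
    est = CopyNumberEstimate(
        copies_per_cell=lam * data.n_partitions * scale,
        ci_low=transform(max(p_low, 0.0)),
        ci_high=transform(p_high),
        method="dPCR",
    )
    return est


def qpcr_copies(cq: float, curve: StandardCurve) -> float:
    """Absolute copies from a Cq value via the standard curve."""
    return 10 ** ((cq - curve.intercept) / curve.slope)


def fold_range(values: Sequence[float]) -> float:
    """max/min of a set of positive copy numbers (>= 1, = 1 iff all equal)."""
    vals = list(values)
    if not vals:
        raise ValueError("empty value list")
    if min(vals) <= 0:
        raise ValueError("fold range needs strictly positive values")
    return max(vals) / min(vals)


def marker_ratio(nssu: float, mtssu: float) -> float:
    """Copy-number ratio of the nuclear to the mitochondrial marker."""
    if nssu <= 0 or mtssu <= 0:
        raise ValueError("copy numbers must be positive")
    return nssu / mtssu


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Standard product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input vector")
    return float(stats.pearsonr(x, y).statistic)


def cell_volume(geom: CellGeometry) -> float:
    """Cell volume in cubic micrometres under the shape approximation."""
    t = geom.thickness
    if geom.shape == "bell_cone":
        return (1 / 3) * math.pi * geom.length * (geom.width / 2) * (t / 2)
    return geom.length * geom.width * t


def summarize_copy_numbers(
    estimates: pd.DataFrame,
    species_col: str = "species",
    value_col: str = "copies_per_cell",
) -> pd.DataFrame:
    """Per-species mean +/- sd and intraspecific fold range from
    per-individual estimates.

    Singleton species report their mean with blank sd and no fold range.
    """
    rows = []
    for species, grp in estimates.groupby(species_col, sort=False):
        vals = grp[value_col].astype(float)
        rows.append(
            {
                "species": species,
                "n_individuals": len(vals),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if len(vals) > 1 else None,
                "intra_fold_range": fold_range(vals) if len(vals) > 1 else None,
            }
        )
    out = pd.DataFrame.from_records(rows)
    logger.info(
        "summarize_copy_numbers: %d estimates -> %d species", len(estimates), len(out)
    )
    return out


def load_reference_survey() -> pd.DataFrame:
    """The packaged transcription of the published 13-species copy-number
    survey (species, class, per-marker mean and sd across individuals)."""
    with resources.files("ciliate_rdna.data").joinpath("copy_number_survey.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    for col in ("mtssu_mean", "mtssu_sd", "nssu_mean", "nssu_sd"):
        df[col] = df[col].astype(float)
    return df


def marker_comparison(survey: pd.DataFrame) -> dict:
    """Column-wise summaries and per-species marker ratios from a survey table.

    Returns the mtSSU and nSSU column ranges (min, max, fold across species),
    the nSSU:mtSSU ratio per species, and the count of species whose nuclear
    marker is less amplified than the mitochondrial one.
    """
    mt = survey["mtssu_mean"]
    nssu = survey["nssu_mean"]
    ratios = {
        row["species"]: marker_ratio(row["nssu_mean"], row["mtssu_mean"])
        for _, row in survey.iterrows()
    }
    return {
        "mtssu_min": float(mt.min()),
        "mtssu_max": float(mt.max()),
        "mtssu_fold": fold_range(mt),
        "nssu_min": float(nssu.min()),
        "nssu_max": float(nssu.max()),
        "nssu_fold": fold_range(nssu),
        "nssu_min_species": survey.loc[nssu.idxmin(), "species"],
        "nssu_max_species": survey.loc[nssu.idxmax(), "species"],
        "ratios": ratios,
        "n_nssu_below_mtssu": int(sum(r < 1 for r in ratios.values())),
        "mt_vs_nssu_pearson_r": pearson_r(mt, nssu),
    }
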