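"""Mean telomere length (MTL) from total per-cell telomere length.

Total telomere length measured by the probe assay is a per-cell sum over all
chromosome ends. Converting it to a mean per telomere requires the number of
telomeres, which depends on (i) the karyotype — each chromosome contributes
two telomeres — and (ii) the cell-cycle stage: after S phase (G2/M) sister
chromatids double the count. For aneuploid lines with an unstable chromosome
number, low/modal/high scenarios bracket the answer.

Cell-cycle stage is inferred from the DNA content reported by a single-copy
gene (SCG) qPCR assay, calibrated in picograms against the ~6.6 pg diploid
G1 reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "KaryotypeModel",
    "CellCycleCall",
    "MTLResult",
    "ScgCalibration",
    "DIPLOID_G1_PG",
    "load_karyotype",
    "available_karyotypes",
    "telomere_count",
    "fit_scg_curve",
    "dna_content_from_scg",
    "mtl",
]

#: DNA content of a diploid human cell in G1, picograms.
DIPLOID_G1_PG = 6.6

Stage = Literal["G1", "G2M", "ambiguous"]
Scenario = Literal["low", "modal", "high"]


@dataclass(frozen=True)
class KaryotypeModel:
    """Chromosome-count model of a cell line, bracketed low/modal/high."""

    name: str
    chromosomes_low: int
    chromosomes_modal: int
    chromosomes_high: int
    stable: bool = True
    derived_count: bool = False

    def __post_init__(self) -> None:
        c = (self.chromosomes_low, self.chromosomes_modal, self.chromosomes_high)
        if not (0 < c[0] <= c[1] <= c[2]):
            raise ValueError("require 0 < low <= modal <= high chromosome counts")

    def chromosomes(self, scenario: Scenario) -> int:
        return {
            "low": self.chromosomes_low,
            "modal": self.chromosomes_modal,
            "high": self.chromosomes_high,
        }[scenario]


@dataclass(frozen=True)
class CellCycleCall:
    """Stage call from single-copy-gene DNA content."""

    stage: Stage
    dna_pg: float
    ratio_to_diploid: float

    def __post_init__(self) -> None:
        if self.ratio_to_diploid <= 0:
            raise ValueError("ratio to diploid reference must be positive")


@dataclass(frozen=True)
class MTLResult:
    """Three-scenario mean telomere length for one cell."""

    total_tl: float
    telomere_counts: dict
    mtl: dict
    stage: Stage
    karyotype: str
    count_basis: str = "karyotype"  # or "measured_dna_content"


def _preset_path():
    return resources.files("omegaqpcr.data").joinpath("karyotypes.yaml")


def available_karyotypes() -> list[str]:
    with _preset_path().open() as fh:
        return sorted(yaml.safe_load(fh))


def load_karyotype(name: str) -> KaryotypeModel:
    """Load a bundled karyotype preset by cell-line name."""
    with _preset_path().open() as fh:
        presets = yaml.safe_load(fh)
    if name not in presets:
        raise KeyError(
            f"unknown karyotype {name!r}; available: {', '.join(sorted(presets))}"
        )
    entry = presets[name]
    c = entry["chromosomes"]
    return KaryotypeModel(
        name=name,
        chromosomes_low=c["low"],
        chromosomes_modal=c["modal"],
        chromosomes_high=c["high"],
        stable=entry.get("stable", True),
        derived_count=entry.get("derived_count", False),
    )


def telomere_count(
    karyotype: KaryotypeModel, stage: Stage = "G1", scenario: Scenario = "modal"
) -> int:
    """Telomeres per cell: 2 per chromosome, doubled again in G2/M."""
    if stage == "ambiguous":
        raise ValueError("resolve the cell-cycle stage before counting telomeres")
    count = 2 * karyotype.chromosomes(scenario)
    if stage == "G2M":
        count *= 2
    return count


class ScgCalibration:
    """Log-linear pg-DNA-versus-Cq calibration for a single-copy-gene assay."""

    def __init__(self, slope: float, intercept: float, r_squared: float = 1.0):
        if slope >= 0:
            raise ValueError("slope must be negative (more DNA, earlier Cq)")
        self.slope = slope
        self.intercept = intercept
        self.r_squared = r_squared

    def pg(self, cq: float) -> float:
        """DNA content in pg implied by an SCG Cq."""
        return 10.0 ** ((cq - self.intercept) / self.slope)

    def cq(self, pg: float) -> float:
        return self.intercept + self.slope * math.log10(pg)


def fit_scg_curve(points: Sequence[tuple[float, float]]) -> ScgCalibration:
    """Fit Cq on log10(pg DNA) from (pg, Cq) calibration points."""
    pg = np.array([p[0] for p in points], dtype=float)
    cq = np.array([p[1] for p in points], dtype=float)
    if np.any(pg <= 0):
        raise ValueError("DNA amounts must be positive")
    if len(set(pg.tolist())) < 3:
        raise ValueError("need at least 3 distinct DNA levels")
    res = stats.linregress(np.log10(pg), cq)
    return ScgCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(float(res.rvalue**2), 1.0),
    )


def dna_content_from_scg(
    cq: float,
    calibration: ScgCalibration,
    *,
    diploid_pg: float = DIPLOID_G1_PG,
    g2_threshold: float = 1.5,
    dead_zone: tuple[float, float] = (1.4, 1.6),
) -> CellCycleCall:
    """Call the cell-cycle stage from a single-copy-gene Cq.

    The DNA content estimate is referenced to the diploid G1 amount; ratios
    inside ``dead_zone`` are called ambiguous, below it G1, above it G2M.
    The default threshold of 1.5x (with a [1.4, 1.6] dead zone) sits midway
    between unreplicated (1x) and fully replicated (2x) genomes.
    """
    if cq is None or (isinstance(cq, float) and math.isnan(cq)):
        raise ValueError("non-detect SCG Cq cannot report DNA content")
    pg = calibration.pg(cq)
    ratio = pg / diploid_pg
    lo, hi = dead_zone
    if lo <= ratio <= hi:
        stage: Stage = "ambiguous"
    elif ratio < g2_threshold:
        stage = "G1"
    else:
        stage = "G2M"
    return CellCycleCall(stage=stage, dna_pg=pg, ratio_to_diploid=ratio)


def mtl(
    total_tl: float,
    karyotype: KaryotypeModel,
    stage: Stage = "G1",
    *,
    count_basis: str = "karyotype",
) -> MTLResult:
    """Mean telomere length under the three ploidy scenarios.

    For a fixed total, more telomeres means a smaller mean, so
    mtl[low] >= mtl[modal] >= mtl[high].
    """
    if total_tl < 0:
        raise ValueError("total telomere length must be non-negative")
    counts = {s: telomere_count(karyotype, stage, s) for s in ("low", "modal", "high")}
    means = {s: (total_tl / n if total_tl > 0 else 0.0) for s, n in counts.items()}
    return MTLResult(
        total_tl=total_tl,
        telomere_counts=counts,
        mtl=means,
        stage=stage,
        karyotype=karyotype.name,
        count_basis=count_basis,
    )
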