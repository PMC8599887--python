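"""The occlusion-length quantification calculus.

Converts qPCR quantification cycles (Cq) into absolute telomere length in
base pairs. The chain is:

1. Cq -> number of circularized probes, via either a fitted log-linear
   standard curve (Cq = intercept + slope * log10(copies)) or the published
   exponential calibration N = A * exp(-k * Cq).
2. probe count -> telomere length: TL = w * (N - 1) + f with occlusion width
   w = 48 bp and hybridized footprint f = 32 bp, the exact inverse of the
   saturating tiling count in :mod:`omegaqpcr.probe_design`.
3. bookkeeping: plasmid mass -> molecule counts, per-template-copy length,
   replicate aggregation with first-order (delta-method) error propagation,
   and gating of the negative-control Cq band (>= 40 cycles by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .probe_design import ProbeGeometry

__all__ = [
    "StandardCurve",
    "ExpCalibration",
    "QPCRRecord",
    "PlasmidSpec",
    "PSXNEO135",
    "PSXNEO270",
    "fit_standard_curve",
    "copies_from_cq",
    "cq_from_copies",
    "tl_from_count",
    "mass_to_molecules",
    "per_copy_length",
    "background_gate",
    "aggregate_replicates",
]

#: average molar mass of a double-stranded base pair, g/mol
BP_GRAMS_PER_MOLE = 650.0
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear Cq-versus-log10(copies) calibration.

    ``efficiency`` is the per-cycle amplification gain minus one,
    10**(-1/slope) - 1; a slope of -3.3219 corresponds to perfect doubling.
    """

    slope: float
    intercept: float
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def cq(self, copies):
        """Predicted Cq at a template copy number (vectorized)."""
        return self.intercept + self.slope * np.log10(copies)

    def copies(self, cq):
        """Template copies at an observed Cq (vectorized)."""
        return 10.0 ** ((np.asarray(cq, dtype=float) - self.intercept) / self.slope)


@dataclass(frozen=True)
class ExpCalibration:
    """Exponential copies-from-Cq calibration, N = A * exp(-k * Cq).

    Defaults are the published constants A = 4e11 copies, k = 0.691 per cycle.
    """

    amplitude: float = 4e11
    decay: float = 0.691

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.decay <= 0:
            raise ValueError("amplitude and decay must be positive")

    def to_standard_curve(self) -> StandardCurve:
        """The identical calibration in log-linear slope/intercept form."""
        slope = -math.log(10.0) / self.decay
        intercept = math.log(self.amplitude) / self.decay
        return StandardCurve(slope=slope, intercept=intercept, r_squared=1.0)


@dataclass(frozen=True)
class QPCRRecord:
    """One well of a qPCR export: a sample, an assay, a Cq and a replicate id.

    ``cq=None`` is an explicit non-detect; a detected Cq must be positive.
    """

    sample_id: str
    assay: Literal["omega", "scg", "other"]
    cq: float | None
    replicate: int

    def __post_init__(self) -> None:
        if self.cq is not None and not self.cq > 0:
            raise ValueError("detected Cq must be > 0; use cq=None for non-detects")

    @property
    def detected(self) -> bool:
        return self.cq is not None


@dataclass(frozen=True)
class PlasmidSpec:
    """A validation plasmid carrying a synthetic telomere insert."""

    name: str
    insert_length: int  # bp of synthetic telomere
    molecules_per_ug: float

    def __post_init__(self) -> None:
        if self.insert_length <= 0 or self.molecules_per_ug <= 0:
            raise ValueError("insert_length and molecules_per_ug must be positive")

    @classmethod
    def from_total_length(cls, name: str, insert_length: int, total_length_bp: int
                          ) -> "PlasmidSpec":
        """Derive molecules/ug from total plasmid length at 650 g/mol per bp."""
        mpg = AVOGADRO / (total_length_bp * BP_GRAMS_PER_MOLE) * 1e-6
        return cls(name=name, insert_length=insert_length, molecules_per_ug=mpg)


PSXNEO135 = PlasmidSpec("pSXneo135", insert_length=800, molecules_per_ug=2.86e11)
PSXNEO270 = PlasmidSpec("pSXneo270", insert_length=1600, molecules_per_ug=2.29e11)


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Cq on log10(copies).

    ``points`` are (copies, Cq) pairs spanning at least three distinct copy
    levels, all copies positive.
    """
    copies = np.array([p[0] for p in points], dtype=float)
    cqs = np.array([p[1] for p in points], dtype=float)
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    if len(set(copies.tolist())) < 3:
        raise ValueError("need at least 3 distinct copy levels")
    res = stats.linregress(np.log10(copies), cqs)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(float(res.rvalue**2), 1.0),
    )


def copies_from_cq(cq, calibration: ExpCalibration | StandardCurve = ExpCalibration()):
    """Circularized-probe copies implied by a detected Cq (vectorized).

    Strictly decreasing in Cq under either calibration form.
    """
    cq = np.asarray(cq, dtype=float)
    if np.any(np.isnan(cq)):
        raise ValueError("non-detect Cq passed to copies_from_cq; gate first")
    if isinstance(calibration, StandardCurve):
        out = calibration.copies(cq)
    else:
        out = calibration.amplitude * np.exp(-calibration.decay * cq)
    return float(out) if out.ndim == 0 else out


def cq_from_copies(copies, calibration: ExpCalibration | StandardCurve = ExpCalibration()):
    """Inverse of :func:`copies_from_cq` (used by the simulator)."""
    copies = np.asarray(copies, dtype=float)
    if np.any(copies <= 0):
        raise ValueError("copies must be positive to yield a Cq")
    if isinstance(calibration, StandardCurve):
        out = calibration.cq(copies)
    else:
        out = np.log(calibration.amplitude / copies) / calibration.decay
    return float(out) if np.ndim(out) == 0 else out


def tl_from_count(n_cp, geometry: ProbeGeometry = ProbeGeometry()):
    """Total telomere length in bp from a circularized-probe count.

    TL = occlusion * (N - 1) + footprint. ``n_cp`` may be non-integer (a
    population-average count); values in [0, 1) return 0 — less than one
    probe carries no length information.
    """
    n = np.asarray(n_cp, dtype=float)
    if np.any(n < 0):
        raise ValueError("probe count must be non-negative")
    tl = np.where(n >= 1, geometry.occlusion * (n - 1) + geometry.footprint_hyb, 0.0)
    return float(tl) if tl.ndim == 0 else tl


def mass_to_molecules(mass_pg: float, spec: PlasmidSpec) -> float:
    """Molecule count in ``mass_pg`` picograms of a plasmid."""
    if mass_pg <= 0:
        raise ValueError("mass must be positive")
    return mass_pg * 1e-6 * spec.molecules_per_ug


def per_copy_length(total_tl: float, template_copies: float) -> int:
    """Telomere length per template copy, rounded to the nearest bp."""
    if template_copies <= 0:
        raise ValueError("template copies must be positive")
    if total_tl < 0:
        raise ValueError("total length must be non-negative")
    return int(round(total_tl / template_copies))


def background_gate(
    records: Iterable[QPCRRecord], threshold_cq: float = 40.0
) -> tuple[list[QPCRRecord], list[QPCRRecord]]:
    """Partition records into (signal, background).

    Non-detects and wells at or beyond the negative-control threshold
    (default 40 cycles, the bottom of the observed negative-control band)
    are background.
    """
    signal: list[QPCRRecord] = []
    background: list[QPCRRecord] = []
    for rec in records:
        if rec.cq is None or rec.cq >= threshold_cq:
            background.append(rec)
        else:
            signal.append(rec)
    return signal, background


def aggregate_replicates(
    cqs: Sequence[float],
    calibration: ExpCalibration | StandardCurve = ExpCalibration(),
    geometry: ProbeGeometry = ProbeGeometry(),
) -> dict:
    """Replicate summary: mean Cq, per-replicate lengths, delta-method sd.

    The total-length standard deviation propagates the Cq sd to first order:
    with N(Cq) the calibration and TL = w(N-1)+f, sd(TL) ~= w * |dN/dCq| * sd(Cq).
    """
    cqs = np.asarray(cqs, dtype=float)
    if cqs.size == 0:
        raise ValueError("no detected replicates to aggregate")
    mean_cq = float(np.mean(cqs))
    sd_cq = float(np.std(cqs, ddof=1)) if cqs.size > 1 else 0.0
    copies = copies_from_cq(cqs, calibration)
    lengths = tl_from_count(copies, geometry)
    mean_copies = copies_from_cq(mean_cq, calibration)
    if isinstance(calibration, StandardCurve):
        dn_dcq = mean_copies * math.log(10.0) / abs(calibration.slope)
    else:
        dn_dcq = mean_copies * calibration.decay
    sd_tl = geometry.occlusion * dn_dcq * sd_cq
    return {
        "n": int(cqs.size),
        "mean_cq": mean_cq,
        "sd_cq": sd_cq,
        "mean_copies": float(mean_copies),
        "per_replicate_tl": np.atleast_1d(lengths),
        "mean_tl": float(tl_from_count(mean_copies, geometry)),
        "sd_tl": float(sd_tl),
    }
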