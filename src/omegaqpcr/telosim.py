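"""Forward simulator of the circularizable-probe telomere assay.

Simulates the full chain the quantification calculus inverts: probe tiling
on each template tract (deterministic saturating packing, or random
sequential adsorption for the kinetic limit), ligation success at the nick
(near-certain on matched junctions, a small leak on mismatched ones),
Poisson background circularization, and the qPCR readout mapping circle
counts to Cq through an inverted standard curve plus Gaussian Cq noise.

Used for end-to-end parameter-recovery tests: ``simulate_assay`` produces
replicate Cq tables and ``recover`` runs the quantification pipeline on them
and reports bias and spread against the simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .probe_design import (
    OmegaProbe,
    ProbeGeometry,
    check_ligation_junction,
    default_probe,
    revcomp,
    tile_probes,
)
from .quant_core import (
    ExpCalibration,
    StandardCurve,
    copies_from_cq,
    cq_from_copies,
    tl_from_count,
)

__all__ = ["SimConfig", "SimResult", "simulate_assay", "recover"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated assay.

    Templates are either abstract tract lengths (bp per template copy) or
    explicit target sequences; ``template_copies`` identical copies of each
    are present. ``background_circles`` is the expected number of
    template-independent circles; with ``poisson_background`` off the
    expected (possibly fractional) count is used deterministically, which
    models the sub-single-copy effective template of negative controls.
    """

    tract_lengths: tuple = ()
    template_sequences: tuple = ()
    template_copies: int = 1
    tiling_mode: Literal["saturating", "stochastic"] = "saturating"
    p_ligate_match: float = 1.0
    p_ligate_mismatch: float = 0.01
    background_circles: float = 0.0
    poisson_background: bool = True
    calibration: ExpCalibration | StandardCurve = field(default_factory=ExpCalibration)
    cq_noise_sd: float = 0.0
    geometry: ProbeGeometry = field(default_factory=ProbeGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_ligate_match, self.p_ligate_mismatch):
            if not 0.0 <= p <= 1.0:
                raise ValueError("ligation probabilities must lie in [0, 1]")
        if self.p_ligate_mismatch > self.p_ligate_match:
            raise ValueError("mismatch ligation cannot exceed matched ligation")
        if not self.tract_lengths and not self.template_sequences:
            raise ValueError("provide tract_lengths or template_sequences")
        if self.tract_lengths and self.template_sequences:
            raise ValueError("provide either tract_lengths or template_sequences")
        if self.template_copies < 1:
            raise ValueError("template_copies must be >= 1")


@dataclass(frozen=True)
class SimResult:
    """Per-replicate outcome of a simulated assay."""

    true_total_tl: float
    tiled_per_template_set: int
    circularized: np.ndarray  # per replicate
    cq: np.ndarray  # per replicate; NaN marks non-detect
    detected: np.ndarray  # bool per replicate
    config: SimConfig


def _sequence_placements(
    seq: str, probe: OmegaProbe, geometry: ProbeGeometry
) -> list[str]:
    """Junction verdicts of saturating probe placements on one sequence.

    The probe footprint is anchored wherever both arms hybridize (full
    Watson-Crick complementarity outside the two junction-covered bases);
    successive placements are spaced by the occlusion width and each must fit
    within the geometric footprint.
    """
    site = revcomp(probe.arm5) + revcomp(probe.arm3)
    n5 = len(probe.arm5)
    junction_idx = (n5 - 1, n5)
    verdicts: list[str] = []
    pos = 0
    limit = len(seq) - geometry.footprint_hyb
    while pos <= limit:
        window = seq[pos : pos + len(site)]
        if len(window) == len(site) and all(
            window[i] == site[i] for i in range(len(site)) if i not in junction_idx
        ):
            verdicts.append(check_ligation_junction(probe, window))
            pos += geometry.occlusion
        else:
            pos += 1
    return verdicts


def _stochastic_tile_count(length: int, geometry: ProbeGeometry,
                           rng: np.random.Generator) -> int:
    """Random sequential adsorption of probe footprints on [0, length).

    Starts are drawn uniformly among remaining admissible positions; each
    placed probe excludes further starts within the occlusion width either
    side. Jams below the saturating packing density.
    """
    if length < geometry.footprint_hyb:
        return 0
    free = np.ones(length - geometry.footprint_hyb + 1, dtype=bool)
    placed = 0
    w = geometry.occlusion
    while True:
        candidates = np.flatnonzero(free)
        if candidates.size == 0:
            return placed
        x = int(rng.choice(candidates))
        placed += 1
        lo = max(0, x - w + 1)
        free[lo : x + w] = False


def simulate_assay(config: SimConfig, replicates: int = 1) -> SimResult:
    """Run the forward model for ``replicates`` independent wells."""
    rng = np.random.default_rng(config.seed)
    geometry = config.geometry
    probe = default_probe()

    if config.template_sequences:
        verdicts: list[str] = []
        for seq in config.template_sequences:
            verdicts.extend(_sequence_placements(seq, probe, geometry))
        n_match = sum(v == "ligatable" for v in verdicts)
        n_mismatch = len(verdicts) - n_match
        tiled_set = len(verdicts)
        true_total = float(sum(len(s) for s in config.template_sequences)
                           ) * config.template_copies
    else:
        counts = [int(tile_probes(L, geometry)) for L in config.tract_lengths]
        tiled_set = sum(counts)
        n_match, n_mismatch = tiled_set, 0
        true_total = float(sum(config.tract_lengths)) * config.template_copies

    circ = np.zeros(replicates)
    for r in range(replicates):
        if config.tiling_mode == "stochastic" and not config.template_sequences:
            n_sites = config.template_copies * sum(
                _stochastic_tile_count(int(L), geometry, rng)
                for L in config.tract_lengths
            )
            n_mis = 0
        else:
            n_sites = n_match * config.template_copies
            n_mis = n_mismatch * config.template_copies
        n = 0
        if n_sites:
            n += (n_sites if config.p_ligate_match == 1.0
                  else int(rng.binomial(n_sites, config.p_ligate_match)))
        if n_mis and config.p_ligate_mismatch > 0:
            n += int(rng.binomial(n_mis, config.p_ligate_mismatch))
        if config.background_circles > 0:
            if config.poisson_background:
                n += int(rng.poisson(config.background_circles))
            else:
                n += config.background_circles
        circ[r] = n

    cq = np.full(replicates, np.nan)
    detected = circ >= 1.0
    positive = circ > 0
    if np.any(positive):
        cq[positive] = cq_from_copies(circ[positive], config.calibration)
        if config.cq_noise_sd > 0:
            cq[positive] += rng.normal(0.0, config.cq_noise_sd, int(positive.sum()))
    return SimResult(
        true_total_tl=true_total,
        tiled_per_template_set=tiled_set,
        circularized=circ,
        cq=cq,
        detected=detected,
        config=config,
    )


def recover(
    sim: SimResult,
    calibration: ExpCalibration | StandardCurve | None = None,
    geometry: ProbeGeometry | None = None,
) -> dict:
    """Run the quantification pipeline on simulated Cq values.

    Per replicate: Cq -> circle count -> per-template probe count
    (circles / template copies) -> length via the occlusion formula. Reports
    recovered per-template lengths, their mean and sd, and the bias against
    the simulated per-template truth. Flags a calibration mismatch if the
    recovery calibration differs from the one that generated the Cq values.
    """
    cal = calibration if calibration is not None else sim.config.calibration
    geo = geometry if geometry is not None else sim.config.geometry
    mismatch = cal != sim.config.calibration
    cqs = sim.cq[sim.detected]
    if cqs.size == 0:
        return {"n_detected": 0, "calibration_mismatch": mismatch,
                "recovered_per_template": np.array([])}
    circles = np.asarray(copies_from_cq(cqs, cal))
    n_per_template = circles / sim.config.template_copies
    lengths = np.asarray(tl_from_count(n_per_template, geo))
    true_per_template = sim.true_total_tl / sim.config.template_copies
    return {
        "n_detected": int(cqs.size),
        "recovered_per_template": lengths,
        "mean_length": float(np.mean(lengths)),
        "sd_length": float(np.std(lengths, ddof=1)) if cqs.size > 1 else 0.0,
        "true_per_template": float(true_per_template),
        "bias": float(np.mean(lengths) - true_per_template),
        "calibration_mismatch": mismatch,
    }
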