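"""Design and validation of circularizable omega-probes for tandem-repeat targets.

An omega-probe is a linear oligonucleotide whose 5'- and 3'-terminal arms
hybridize to adjacent phases of a tandem repeat (the human telomere G-strand,
(TTAGGG)n, by default) so that its ends abut on the target and can be joined
by a nick ligase. The interior of the probe carries, in order, a reverse-primer
binding region, a forward-primer sequence and a hydrolysis-probe binding
region, so that only the circularized (ligated) form supports exponential qPCR.

The module also houses the probe-packing geometry: each circularized probe
hybridizes ``footprint_hyb`` bases (32 by default) and, through its stem-loops,
occludes ``occlusion`` bases (48) where probes abut. ``tile_probes`` converts a
tract length into the saturating probe count, the inverse of the
length-from-count formula in :mod:`omegaqpcr.quant_core`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "RepeatTarget",
    "OmegaProbe",
    "OmegaORF",
    "ProbeGeometry",
    "DEFAULT_SEGMENTS",
    "HUMAN_TELOMERE_UNIT",
    "build_probe",
    "default_probe",
    "linearize_to_orf",
    "check_ligation_junction",
    "tile_probes",
    "arm_melting_temperature",
]

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

HUMAN_TELOMERE_UNIT = "TTAGGG"

#: Published segment boundaries of the human-telomere omega-probe (5'->3'):
#: 17-nt 5' arm, 19-nt reverse-primer binding region, 21-nt forward primer,
#: 17-nt hydrolysis-probe region, 14-nt 3' arm.  The arms are C-rich
#: (reverse-complementary to phases of the telomere G-strand).
DEFAULT_SEGMENTS = {
    "arm5": "AACCCTAACCCTAACCC",
    "pr_binding": "CGCGCTAGACTAAGCGCTC",
    "pf": "CAGTGACTCAGCAGCTACCCG",
    "hp": "GCAACTAGATGCCGCCC",
    "arm3": "CTAACCCTAACCCT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{name} contains non-DNA characters: {sorted(bad)}")


@dataclass(frozen=True)
class RepeatTarget:
    """A tandem-repeat target tract on the G-rich strand, 5'->3'.

    ``variant_pattern`` describes an adjacent variant repeat (e.g. the
    subtelomeric TTXAGGG) with exactly one wildcard position ``X``; it may be
    one base longer than the canonical unit or the same length.
    """

    unit: str = HUMAN_TELOMERE_UNIT
    n_units: int = 1
    variant_pattern: str | None = None
    strand_convention: Literal["G_strand_5to3"] = "G_strand_5to3"

    def __post_init__(self) -> None:
        _check_dna(self.unit, "repeat unit")
        if self.n_units < 1:
            raise ValueError("n_units must be positive")
        if self.variant_pattern is not None:
            vp = self.variant_pattern
            if vp.count("X") != 1:
                raise ValueError("variant_pattern must contain exactly one wildcard X")
            if len(vp) not in (len(self.unit), len(self.unit) + 1):
                raise ValueError(
                    "variant_pattern must match the unit length or exceed it by one"
                )
            _check_dna(vp.replace("X", "A"), "variant_pattern")

    @property
    def tract(self) -> str:
        """The full canonical tract sequence, ``n_units`` copies of the unit."""
        return self.unit * self.n_units

    @property
    def tract_length(self) -> int:
        return len(self.unit) * self.n_units

    def variant_tract(self, n_units: int, x: str) -> str:
        """A variant tract with the wildcard fixed to base ``x``."""
        if self.variant_pattern is None:
            raise ValueError("target has no variant_pattern")
        _check_dna(x, "wildcard base")
        return self.variant_pattern.replace("X", x) * n_units


@dataclass(frozen=True)
class ProbeGeometry:
    """Packing constants of the occlusion calculus.

    footprint_hyb
        bases hybridized per circularized probe (the two arms), default 32.
    occlusion
        bases of target consumed per probe where probes abut (footprint plus
        stem-loop exclusion), default 48.
    """

    footprint_hyb: int = 32
    occlusion: int = 48

    def __post_init__(self) -> None:
        if not (self.occlusion >= self.footprint_hyb > 0):
            raise ValueError("require occlusion >= footprint_hyb > 0")

    @property
    def min_length(self) -> int:
        """Shortest tract accommodating a single probe."""
        return self.footprint_hyb


@dataclass(frozen=True)
class OmegaProbe:
    """A segmented circularizable probe, stored 5'->3' as synthesized.

    Segments in order of the linear oligo: ``arm5`` (phosphorylated 5'
    terminus), ``pr_binding`` (reverse complement of the reverse primer),
    ``pf`` (forward primer, verbatim), ``hp`` (hydrolysis-probe region),
    ``arm3`` (3' terminus).
    """

    arm5: str
    pr_binding: str
    pf: str
    hp: str
    arm3: str
    phosphorylated: bool = True
    target: RepeatTarget = field(default_factory=RepeatTarget)

    @property
    def full_sequence(self) -> str:
        return self.arm5 + self.pr_binding + self.pf + self.hp + self.arm3

    @property
    def hybridized_footprint(self) -> int:
        """Bases of target covered by the two arms."""
        return len(self.arm5) + len(self.arm3)

    @property
    def junction_target(self) -> str:
        """The two adjacent target bases spanning the ligated 3'/5' nick, 5'->3'.

        The probe anneals antiparallel, so on the target the 3' arm footprint
        lies immediately 3' of the 5' arm footprint; the nick spans the last
        base of the 5'-arm footprint (paired with the probe's 5'-terminal
        base) and the first base of the 3'-arm footprint (paired with the
        probe's 3'-terminal base).
        """
        return revcomp(self.arm5)[-1] + revcomp(self.arm3)[0]

    def arm_phases(self) -> tuple[int, int]:
        """Phases (offsets into the repeat unit) at which each arm anneals.

        Returns ``(phase5, phase3)`` such that the reverse complement of each
        arm is a substring of the infinite repeat starting at that offset.
        Raises ``ValueError`` if an arm is not complementary to any phase.
        """
        unit = self.target.unit
        phases = []
        for name, arm in (("arm5", self.arm5), ("arm3", self.arm3)):
            probe_site = revcomp(arm)
            ref = unit * (len(probe_site) // len(unit) + 2)
            for phase in range(len(unit)):
                if ref[phase : phase + len(probe_site)] == probe_site:
                    phases.append(phase)
                    break
            else:
                raise ValueError(f"{name} is not complementary to any phase of {unit}")
        return tuple(phases)  # type: ignore[return-value]


@dataclass(frozen=True)
class OmegaORF:
    """The linearized rotation of the circular probe, forward primer first."""

    sequence: str


def build_probe(
    arm5: str,
    pr_binding: str,
    pf: str,
    hp: str,
    arm3: str,
    *,
    phosphorylated: bool = True,
    target: RepeatTarget | None = None,
) -> OmegaProbe:
    """Assemble an omega-probe from its five segments (each 5'->3').

    Segments are concatenated arm5 -> pr_binding -> pf -> hp -> arm3.
    Raises ``ValueError`` on empty segments or non-DNA characters.
    """
    for name, seg in (
        ("arm5", arm5),
        ("pr_binding", pr_binding),
        ("pf", pf),
        ("hp", hp),
        ("arm3", arm3),
    ):
        _check_dna(seg, name)
    return OmegaProbe(
        arm5=arm5,
        pr_binding=pr_binding,
        pf=pf,
        hp=hp,
        arm3=arm3,
        phosphorylated=phosphorylated,
        target=target if target is not None else RepeatTarget(),
    )


def default_probe(n_units: int = 1) -> OmegaProbe:
    """The published human-telomere omega-probe with default segmentation."""
    return build_probe(
        **DEFAULT_SEGMENTS,
        target=RepeatTarget(unit=HUMAN_TELOMERE_UNIT, n_units=n_units,
                            variant_pattern="TTXAGGG"),
    )


def linearize_to_orf(probe: OmegaProbe) -> OmegaORF:
    """Rotate the circularized probe so the forward primer sits at the 5' end.

    The result is the open-reading-frame form used to build qPCR standard
    curves: same base content as the probe, with the forward primer and the
    reverse-primer binding region at opposite ends.
    """
    seq = probe.full_sequence
    i = seq.find(probe.pf)
    if i < 0:
        raise ValueError("forward primer not found in probe sequence")
    return OmegaORF(sequence=seq[i:] + seq[:i])


def check_ligation_junction(probe: OmegaProbe, target_window: str) -> str:
    """Decide whether a hybridized probe can be ligated on ``target_window``.

    ``target_window`` is the target segment (G-strand, 5'->3') covered by the
    two arms: first the 5'-arm footprint, then the 3'-arm footprint. Ligation
    requires Watson-Crick pairing of both bases flanking the nick — the target
    base under the probe's phosphorylated 5' terminus and the base under its
    3' terminus. A mismatch at either aborts ligation, which is what
    discriminates the canonical repeat from subtelomeric variants.

    Returns ``"ligatable"`` or ``"mismatch"``.
    """
    _check_dna(target_window, "target_window")
    footprint = probe.hybridized_footprint
    if len(target_window) < footprint:
        raise ValueError(
            f"target window ({len(target_window)} nt) shorter than the "
            f"hybridized footprint ({footprint} nt)"
        )
    n5 = len(probe.arm5)
    # target base paired with the probe 5'-terminal base, then with the
    # 3'-terminal base; the nick lies between them on the target.
    under_5p = target_window[n5 - 1]
    under_3p = target_window[n5]
    ok5 = under_5p == probe.arm5[0].translate(_COMPLEMENT)
    ok3 = under_3p == probe.arm3[-1].translate(_COMPLEMENT)
    return "ligatable" if (ok5 and ok3) else "mismatch"


def tile_probes(tract_length, geometry: ProbeGeometry = ProbeGeometry()):
    """Saturating probe count on a tract of ``tract_length`` bases.

    Deterministic maximal abutting packing: ``floor((L - f)/w) + 1`` probes for
    L >= footprint f with occlusion width w, else 0. Accepts scalars or
    array-likes; the exact inverse of the length-from-count formula on the
    lattice of abuttable lengths.
    """
    length = np.asarray(tract_length)
    if np.any(length < 0):
        raise ValueError("tract length must be non-negative")
    count = np.where(
        length >= geometry.footprint_hyb,
        (length - geometry.footprint_hyb) // geometry.occlusion + 1,
        0,
    )
    if np.isscalar(tract_length) or np.ndim(tract_length) == 0:
        return int(count)
    return count.astype(np.int64)


def arm_melting_temperature(
    arm: str,
    *,
    Na_mM: float = 50.0,
    Mg_mM: float = 0.0,
    dnac1_nM: float = 100.0,
    nn_table=None,
) -> float:
    """Nearest-neighbour melting temperature of a probe arm, in deg C.

    Advisory only: hybridization in the assay is driven by a slow temperature
    ramp, not a sharp Tm, so this serves design of arms for non-default
    repeat units. Salt and strand concentration defaults reflect typical
    ligation buffers.
    """
    if len(arm) < 8:
        raise ValueError("arm too short for a meaningful nearest-neighbour Tm")
    _check_dna(arm, "arm")
    return float(
        _mt.Tm_NN(
            arm,
            Na=Na_mM,
            Mg=Mg_mM,
            dnac1=dnac1_nM,
            dnac2=0,
            nn_table=nn_table if nn_table is not None else _mt.DNA_NN4,
        )
    )
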