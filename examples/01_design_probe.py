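"""Build the human-telomere circularizable probe and inspect its anatomy.

The probe's two C-rich arms anneal to adjacent phases of the (TTAGGG)n
G strand; ligation of the abutting ends requires perfect pairing at the two
junction-covered bases (the TA of GGGTTAGGG), which rejects subtelomeric
variant repeats.
"""

from omegaqpcr import (
    check_ligation_junction,
    default_probe,
    linearize_to_orf,
    revcomp,
    tile_probes,
)

probe = default_probe()
orf = linearize_to_orf(probe)

print(f"probe ({len(probe.full_sequence)} nt): {probe.full_sequence}")
print(f"orf   ({len(orf.sequence)} nt): {orf.sequence}")
print(f"arm phases within TTAGGG: {probe.arm_phases()}")
print(f"junction-covered target bases: {probe.junction_target}")

window = revcomp(probe.arm5) + revcomp(probe.arm3)
print(f"canonical window verdict: {check_ligation_junction(probe, window)}")
variant = window[: len(probe.arm5)] + "C" + window[len(probe.arm5) + 1 :]
print(f"variant-base window verdict: {check_ligation_junction(probe, variant)}")

for L in (32, 800, 1600, 10_000):
    print(f"a {L:>6} bp tract accommodates {tile_probes(L):>4} probes")

# The verdicts show single-base junction discrimination; the tiling counts
# are the saturating packing the length formula inverts (17 probes per
# 800 bp, 33 per 1600 bp).
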