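"""Mean telomere length of single cells under explicit ploidy models.

Total telomere length per cell divides by the telomere count — two per
chromosome, doubled in G2/M — to give a mean per telomere. A single-copy
gene qPCR reports the cell's DNA content, calling the cell-cycle stage
against the 6.6 pg diploid G1 reference. Aneuploid lines are bracketed by
low/modal/high chromosome counts.
"""

from omegaqpcr import (
    dna_content_from_scg,
    fit_scg_curve,
    load_karyotype,
    mtl,
    telomere_count,
)

# Synthetic single-copy-gene calibration: Cq = 41 - 3.4 * log10(pg DNA)
scg = fit_scg_curve([(10.0**e, 41.0 - 3.4 * e) for e in (-1, 0, 1, 2)])
call = dna_content_from_scg(scg.cq(6.6), scg)
print(f"SCG call: {call.dna_pg:.1f} pg, {call.ratio_to_diploid:.2f}x diploid "
      f"-> stage {call.stage}")

total_tl = 470_000.0  # bp per cell, e.g. from the quantification chain
for name in ("CP-A", "HEK-293", "MDA-MB-231", "MCF-7"):
    k = load_karyotype(name)
    res = mtl(total_tl, k, call.stage)
    counts = ", ".join(f"{s}={res.telomere_counts[s]}" for s in ("low", "modal", "high"))
    print(f"{name:<11} telomeres ({counts}) -> MTL "
          + " / ".join(f"{res.mtl[s]:.0f}" for s in ("low", "modal", "high"))
          + " bp (low/modal/high)")

print(f"CP-A in G2/M would have {telomere_count(load_karyotype('CP-A'), 'G2M')} "
      "telomere ends (sister chromatids), halving the mean.")

# For a fixed per-cell total, more chromosomes mean a smaller per-telomere
# mean; the low/modal/high spread shows the ploidy uncertainty band.
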