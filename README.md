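# omegaqpcr

Absolute telomere length in base pairs from qPCR of circularizable
("omega") probes — down to single cells — plus the companion calculations
a practitioner needs around that measurement: probe design against
tandem-repeat targets, ploidy-aware mean telomere length, TRF gel
densitometry for cross-method comparison, and a forward simulator of the
whole assay.

## The method

Telomeres are (TTAGGG)n tracts capping chromosome ends. An omega-probe is a
linear oligo whose 5'- and 3'-terminal C-rich arms hybridize to adjacent
positions on the telomere G strand so its ends abut; a nick ligase then
circularizes it, but only if both bases flanking the junction — positioned
over the TA of GGGTTAGGG — pair perfectly, which rejects subtelomeric
(TTXAGGG)n variants. Only the circular form supports qPCR (the reverse
primer cannot function on the linear probe), so the quantification cycle Cq
counts circularized probes, and with saturating hybridization the count
N<sub>cp</sub> tiles the telomere end to end:

```
TL = 48 (Ncp − 1) + 32        [bp]
```

where 32 bp is the hybridized footprint of one probe and 48 bp the span
each probe occludes where probes abut. Circle counts come from Cq either
through a fitted log-linear standard curve Cq = b + m·log10(N)
(efficiency 10^(−1/m) − 1) or through the published exponential form
N<sub>cp</sub> = 4×10¹¹·exp(−0.691·Cq). Mean telomere length per telomere
divides the per-cell total by the telomere count: two per chromosome, twice
that in G2/M, with the cell-cycle stage called from single-copy-gene DNA
content against the 6.6 pg diploid G1 reference.

## Worked example

`python examples/02_quantify_plasmids.py` runs the plasmid validation
chain — two plasmids carrying synthetic telomere inserts of known length —
and prints:

```
pSXneo135: 0.125 pg = 35750 copies | Cq 19.38 -> 611,182 circles -> 29,336,729 bp total -> 821 bp/plasmid (known 800 bp)
pSXneo270: 0.25 pg = 57250 copies | Cq 17.741 -> 1,896,839 circles -> 91,048,257 bp total -> 1590 bp/plasmid (known 1600 bp)
```

The plasmid mass and molecules-per-microgram give the template copy
number; the Cq gives the circle count; the occlusion formula gives total
length; division gives bp per plasmid, within about 2% of the known
inserts. The other examples cover probe anatomy and junction
discrimination (`01`), single-cell MTL under low/modal/high ploidy
scenarios (`03`), hybridization-corrected TRF lane analysis (`04`), and
simulator-based recovery of known lengths with noise (`05`).

The same workflow is available from the shell:

```
omegaqpcr fixtures --out fx
omegaqpcr quantify fx/plasmid_validation.tsv --out quant.tsv
omegaqpcr mtl quant.tsv --karyotype CP-A
omegaqpcr trf fx/trf_lane.tsv --ladder fx/marker_ladder.tsv
```

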