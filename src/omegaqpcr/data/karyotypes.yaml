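# Built-in karyotype presets for per-cell telomere counting.
# chromosomes: low / modal / high bracket the reported chromosome-number
# range of each line; stable marks lines with a stable modal count.
# derived_count flags presets whose telomere count was never printed in the
# source karyotype literature and is derived here as 2 x modal chromosomes.
CP-A:
  chromosomes: {low: 47, modal: 47, high: 47}
  stable: true
  derived_count: false
HEK-293:
  chromosomes: {low: 64, modal: 64, high: 64}
  stable: true
  derived_count: false
MDA-MB-231:
  chromosomes: {low: 52, modal: 64, high: 68}
  stable: false
  derived_count: false
MCF-7:
  chromosomes: {low: 66, modal: 82, high: 87}
  stable: false
  derived_count: false
K-562:
  chromosomes: {low: 67, modal: 67, high: 67}
  stable: true
  derived_count: true
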