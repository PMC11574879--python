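# Myeloid panel: macrophage polarization by the CD68/CD163 convention.
# M1 + M2 partition the CD68_total population exactly.
name: myeloid
markers: [CD68, CD163, Calprotectin, MARCO]
phenotypes:
  - name: CD68_total
    positive: [CD68]
  - name: CD163_total
    positive: [CD163]
  - name: M1
    positive: [CD68]
    negative: [CD163]
  - name: M2
    positive: [CD68, CD163]
  - name: myeloid_nonmacrophage
    positive: [CD163]
    negative: [CD68]
  - name: Calprotectin_total
    positive: [Calprotectin]
  - name: Calprotectin_single
    positive: [Calprotectin]
    exclusive_single: true
  - name: MARCO_total
    positive: [MARCO]
partitions:
  - parent: CD68_total
    parts: [M1, M2]
  - parent: CD163_total
    parts: [M2, myeloid_nonmacrophage]
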