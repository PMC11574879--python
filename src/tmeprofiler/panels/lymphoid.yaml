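# Lymphoid panel: totals plus the usual memory/Treg subsets.
# "_single" phenotypes require negativity for every other panel marker.
name: lymphoid
markers: [CD8, CD4, CD45R0, CD20, FoxP3]
phenotypes:
  - name: CD8_total
    positive: [CD8]
  - name: CD8_single
    positive: [CD8]
    exclusive_single: true
  - name: CD8_memory
    positive: [CD8, CD45R0]
  - name: CD4_total
    positive: [CD4]
  - name: CD4_single
    positive: [CD4]
    exclusive_single: true
  - name: CD4_memory
    positive: [CD4, CD45R0]
  - name: CD4_Tregs
    positive: [CD4, FoxP3]
  - name: CD45R0_total
    positive: [CD45R0]
  - name: CD20_total
    positive: [CD20]
  - name: FoxP3_total
    positive: [FoxP3]
partitions: []
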