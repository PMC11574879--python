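# Fibroblast panel.  aSMA is tiered (high/low at the mean intensity of the
# positive cells); aSMA_high_single + aSMA_low_single partition aSMA_single.
name: caf
markers: [aSMA, FAP, CD90, NGFR, COL1A1]
tiered_markers: [aSMA]
phenotypes:
  - name: aSMA_total
    positive: [aSMA]
  - name: aSMA_single
    positive: [aSMA]
    exclusive_single: true
  - name: aSMA_high_single
    positive: [aSMA]
    exclusive_single: true
    tiers: {aSMA: high}
  - name: aSMA_low_single
    positive: [aSMA]
    exclusive_single: true
    tiers: {aSMA: low}
  - name: FAP_total
    positive: [FAP]
  - name: FAP_single
    positive: [FAP]
    exclusive_single: true
  - name: CD90_total
    positive: [CD90]
  - name: NGFR_total
    positive: [NGFR]
  - name: COL1A1_total
    positive: [COL1A1]
  - name: COL1A1_single
    positive: [COL1A1]
    exclusive_single: true
  - name: CD90_COL1A1
    positive: [CD90, COL1A1]
  - name: aSMA_COL1A1
    positive: [aSMA, COL1A1]
  - name: aSMA_CD90_COL1A1
    positive: [aSMA, CD90, COL1A1]
  - name: FAP_aSMA
    positive: [FAP, aSMA]
  - name: FAP_CD90
    positive: [FAP, CD90]
  - name: NGFR_COL1A1
    positive: [NGFR, COL1A1]
partitions:
  - parent: aSMA_single
    parts: [aSMA_high_single, aSMA_low_single]
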