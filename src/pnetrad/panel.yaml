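# Declarative registry of the prespecified hybrid signature panel.
# Each signature is a product of factors; a factor pulls a value from the
# harmonized lesion feature table (source: lesion), the delta table
# (source: delta), or the encoded clinical table (source: clinical), with an
# optional transform applied first.  `composite` signatures multiply
# previously computed signatures.  Missing factors propagate to a missing
# signature (never zero).
signatures:
  A1:
    name: "Proliferation x histogram heterogeneity"
    factors:
      - {source: lesion, key: firstorder_Entropy}
      - {source: clinical, key: ki67_fraction}
  A2:
    name: "Morphologic complexity"
    factors:
      - {source: lesion, key: shape_SurfaceVolumeRatio}
      - {source: lesion, key: shape_Sphericity, transform: one_minus}
  A3:
    name: "Functional-morphologic-grade"
    factors:
      - {source: lesion, key: shape_Sphericity, transform: one_minus}
      - {source: clinical, key: functional}
      - {source: clinical, key: grade}
  A4:
    name: "Metastatic burden"
    factors:
      - {source: lesion, key: firstorder_Energy, transform: log1p}
      - {source: clinical, key: grade}
      - {source: clinical, key: n_met_organs, transform: one_plus}
  A5:
    name: "Proliferation x complexity (3-way)"
    composite: [A1, A2]
  A6:
    name: "Spatial heterogeneity x proliferation"
    factors:
      - {source: lesion, key: ngtdm_Busyness}
      - {source: clinical, key: ki67_fraction}
  A7:
    name: "Vascular x differentiation"
    factors:
      - {source: lesion, key: firstorder_Median}
      - {source: clinical, key: grade}
  B1:
    name: "Delta-proliferation"
    factors:
      - {source: delta, key: firstorder_Entropy}
      - {source: clinical, key: ki67_fraction}
  B2:
    name: "Delta-spatial x proliferation"
    factors:
      - {source: delta, key: ngtdm_Busyness}
      - {source: clinical, key: ki67_fraction}
  B3:
    name: "Delta-vascular x differentiation"
    factors:
      - {source: delta, key: firstorder_Median}
      - {source: clinical, key: grade}
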