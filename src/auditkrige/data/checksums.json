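{
  "table1_prevalence.csv": "7001df392df7587b40475070ffb2f8d45a0a089d3fc1ad07dfc7361a08759880",
  "table2_semivariograms.csv": "04d95ba68c72815c937ef706a3aad2d2753ddbf9a5562987ef952724c245aa7b",
  "table3_auc.csv": "e99821b7ebffdfc7703bec538e28eccf28ed94be6e23cb46005411625efff14f"
}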