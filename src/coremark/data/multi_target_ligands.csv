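drug_id,protein_id,score
625439,KIAA0101,145.708
625439,HDAC1,134.097
625439,HDAC4,149.324
645378,CEBPB,158.637
645378,KIAA0101,140.103
668448,BRCA1,192.069
668448,PSMA3,166.516
668577,MYC,125.603
668577,PSMA3,180.11
682094,TERF1,123.287
682094,YWHAZ,182.534
687363,MYC,145.138
687363,YWHAZ,184.649
695175,TRAF2,101.267
695175,PSMA3,148.83
695409,TP53,125.821
695409,PSMA3,164.906
704565,KIAA0101,137.38
704565,HDAC4,153.564
719660,MYC,134.021
719660,YWHAZ,200.903
724305,CEBPB,167.724
724305,HDAC4,141.195
726771,BRCA1,142.956
726771,HDAC4,148.366
742856,MYC,140.093
742856,TP53,100.787
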