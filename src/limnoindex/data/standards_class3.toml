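# Default evaluation standards for the composite water quality index.
#
# Six parameters use Class III limits of China's surface water quality
# standard (GB 3838-2002); turbidity, TOC, Secchi depth (SDD) and
# chlorophyll-a use companion standards for scenic/drinking water and
# key-lake control indicators.  Units match the monitoring CSV columns:
# mg/L for concentrations, NTU for turbidity, m for SDD.

evaluated = ["pH", "DO", "CODMn", "NH3N", "TP", "TN",
             "turbidity", "TOC", "SDD", "ChlA"]

[pH]
family = "pH"
lower = 6.0
upper = 9.0

[DO]
family = "DO"
direction = "benefit"
standard = 5.0

[CODMn]
family = "simple"
direction = "cost"
standard = 6.0

[NH3N]
family = "simple"
direction = "cost"
standard = 1.0

[TP]
family = "simple"
direction = "cost"
standard = 0.05

[TN]
family = "simple"
direction = "cost"
standard = 1.0

[turbidity]
family = "simple"
direction = "cost"
standard = 5.0

[TOC]
family = "simple"
direction = "cost"
standard = 5.0

[SDD]
family = "simple"
direction = "benefit"
standard = 2.5

[ChlA]
family = "simple"
direction = "cost"
standard = 0.04
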