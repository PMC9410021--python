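# Mean centroid-to-centroid distances (mm) between adjacent vertebrae.
# Literature-plausible defaults for an adult spine; editable configuration,
# not anatomical constants.  Integer values keep median-based centroid
# recovery exact on 1 mm grids.
C1-C2: 18
C2-C3: 18
C3-C4: 18
C4-C5: 18
C5-C6: 18
C6-C7: 19
C7-T1: 20
T1-T2: 22
T2-T3: 22
T3-T4: 22
T4-T5: 23
T5-T6: 23
T6-T7: 24
T7-T8: 25
T8-T9: 25
T9-T10: 26
T10-T11: 27
T11-T12: 28
T12-L1: 30
L1-L2: 32
L2-L3: 33
L3-L4: 34
L4-L5: 35
L5-S1: 32
S1-S2: 28
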