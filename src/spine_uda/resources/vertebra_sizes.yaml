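# Average extents (mm) of the dense-label box per vertebra, as
# [sagittal, row, column].  Column extents are odd and smaller than the
# adjacent reference distances so neighbouring boxes never overlap and an
# inter-vertebral gap remains.  Editable configuration.
C1: [25, 25, 13]
C2: [25, 25, 13]
C3: [25, 25, 13]
C4: [25, 25, 13]
C5: [25, 25, 13]
C6: [25, 25, 13]
C7: [25, 25, 13]
T1: [29, 29, 17]
T2: [29, 29, 17]
T3: [29, 29, 17]
T4: [29, 29, 17]
T5: [29, 29, 17]
T6: [29, 29, 17]
T7: [29, 29, 17]
T8: [29, 29, 17]
T9: [29, 29, 17]
T10: [29, 29, 17]
T11: [29, 29, 17]
T12: [29, 29, 17]
L1: [35, 35, 23]
L2: [35, 35, 23]
L3: [35, 35, 23]
L4: [35, 35, 23]
L5: [35, 35, 23]
S1: [31, 31, 19]
S2: [31, 31, 19]
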