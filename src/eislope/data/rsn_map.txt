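# Channel -> resting-state-network assignment for the 55-channel montage.
# Networks: VN visual, SM somatomotor, DA dorsal attention,
# VAL ventral attention + limbic (pooled), FP frontoparietal, DMN default mode.
# Membership is a best-effort scalp projection of the Yeo 7-network
# parcellation (VA and limbic pooled); per-network counts are fixed at
# VN=12, SM=10, DA=9, VAL=12, FP=6, DMN=6.
O1 VN
OZ VN
O2 VN
PO7 VN
PO5 VN
PO3 VN
POZ VN
PO4 VN
PO6 VN
PO8 VN
P7 VN
P8 VN
P5 DA
P3 DA
P1 DA
PZ DA
P2 DA
P4 DA
P6 DA
CP3 DA
CP4 DA
C5 SM
C3 SM
C1 SM
CZ SM
C2 SM
C4 SM
C6 SM
CP1 SM
CPZ SM
CP2 SM
T7 VAL
T8 VAL
FT7 VAL
FT8 VAL
FC5 VAL
FC6 VAL
CP5 VAL
CP6 VAL
F7 VAL
F8 VAL
F5 VAL
F6 VAL
FC3 FP
FC1 FP
FC2 FP
FC4 FP
F3 FP
F4 FP
FP1 DMN
FP2 DMN
AF3 DMN
AF4 DMN
FZ DMN
FCZ DMN
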