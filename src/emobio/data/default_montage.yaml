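# Default 64-channel 10-10 montage (actiCAP-64 label set) and the
# right centro-parietal / parieto-occipital electrode clusters used for
# feature averaging.  Edit cluster memberships here; the code treats this
# file as the single source of truth.
channels:
  - Fp1
  - Fz
  - F3
  - F7
  - FT9
  - FC5
  - FC1
  - C3
  - T7
  - TP9
  - CP5
  - CP1
  - Pz
  - P3
  - P7
  - O1
  - Oz
  - O2
  - P4
  - P8
  - TP10
  - CP6
  - CP2
  - Cz
  - C4
  - T8
  - FT10
  - FC6
  - FC2
  - F4
  - F8
  - Fp2
  - AF7
  - AF3
  - AFz
  - F1
  - F5
  - FT7
  - FC3
  - C1
  - C5
  - TP7
  - CP3
  - P1
  - P5
  - PO7
  - PO3
  - POz
  - PO4
  - PO8
  - P6
  - P2
  - CPz
  - CP4
  - TP8
  - C6
  - C2
  - FC4
  - FT8
  - F6
  - AF8
  - AF4
  - F2
  - Iz
clusters:
  C1: [C2, C4, C6, CP2, CP4, CP6]   # right central-parietal
  C2: [P2, P4, P6, P8]              # right parietal
  C4: [PO4, PO8, TP8]               # right parieto-occipital
  C5: [O2, Iz]                      # right occipital
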