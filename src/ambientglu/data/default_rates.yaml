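name: ubc-ampar-calibrated
units:
  time: ms
  concentration: uM
  conductance: nS
  voltage: mV
T_ref_C: 23.0
Q10: 2.4
g_max_nS: 10.0
open_conductance:
  O1: 1.0
  O2: 1.0
  O3: 1.0
  O4: 1.0
transitions:
- from: C0
  to: C1
  rate: 0.04
  ligand_order: 1
- from: C1
  to: C0
  rate: 0.9999879629359838
  ligand_order: 0
- from: C1
  to: C2
  rate: 0.03
  ligand_order: 1
- from: C2
  to: C1
  rate: 1.9999759258719676
  ligand_order: 0
- from: C2
  to: C3
  rate: 0.02
  ligand_order: 1
- from: C3
  to: C2
  rate: 2.9999638888079514
  ligand_order: 0
- from: C3
  to: C4
  rate: 0.01
  ligand_order: 1
- from: C4
  to: C3
  rate: 3.999951851743935
  ligand_order: 0
- from: C1
  to: O1
  rate: 6.5855298761261665
  ligand_order: 0
- from: O1
  to: C1
  rate: 3.0
  ligand_order: 0
- from: C1
  to: D1
  rate: 0.042881751016842135
  ligand_order: 0
- from: D1
  to: C1
  rate: 0.06
  ligand_order: 0
- from: C2
  to: O2
  rate: 6.5855298761261665
  ligand_order: 0
- from: O2
  to: C2
  rate: 3.0
  ligand_order: 0
- from: C2
  to: D2
  rate: 0.042881751016842135
  ligand_order: 0
- from: D2
  to: C2
  rate: 0.06
  ligand_order: 0
- from: C3
  to: O3
  rate: 4.513093154451065
  ligand_order: 0
- from: O3
  to: C3
  rate: 3.0
  ligand_order: 0
- from: C3
  to: D3
  rate: 0.049257082190418716
  ligand_order: 0
- from: D3
  to: C3
  rate: 0.008
  ligand_order: 0
- from: C4
  to: O4
  rate: 4.513093154451065
  ligand_order: 0
- from: O4
  to: C4
  rate: 3.0
  ligand_order: 0
- from: C4
  to: D4
  rate: 0.049257082190418716
  ligand_order: 0
- from: D4
  to: C4
  rate: 0.008
  ligand_order: 0
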