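parameters:
  compartments:
  - id: C1
    name: Right atrium and intrathoracic great veins
    R_out: 0.0
    C: 0.0095
    V0: 0.367
    valve_out: true
    region: chest
    lung_coupling: 1
    mediastinal_mode: tpf_scaled
  - id: C2
    name: Right ventricle
    R_out: 5.0
    C: 0.016
    V0: 0.15
    valve_out: true
    region: chest
    lung_coupling: 1
    mediastinal_mode: full
  - id: C3
    name: Large pulmonary arteries
    R_out: 10.0
    C: 0.0042
    V0: 0.109
    valve_out: false
    region: chest
    lung_coupling: 1
    mediastinal_mode: tpf_scaled
  - id: C4
    name: Peripheral pulmonary arteries
    R_out: 10.0
    C: 0.00042
    V0: 0.16
    valve_out: false
    region: chest
    lung_coupling: 1
    mediastinal_mode: none
  - id: C5
    name: Peripheral pulmonary veins
    R_out: 5.0
    C: 0.00128
    V0: 0.3
    valve_out: false
    region: chest
    lung_coupling: 1
    mediastinal_mode: none
  - id: C6
    name: Central pulmonary veins and left atrium
    R_out: 0.0
    C: 0.0128
    V0: 0.25
    valve_out: true
    region: chest
    lung_coupling: 1
    mediastinal_mode: tpf_scaled
  - id: C7
    name: Left ventricle
    R_out: 5.0
    C: 0.008
    V0: 0.15
    valve_out: true
    region: chest
    lung_coupling: 1
    mediastinal_mode: full
  - id: C8
    name: Thoracic aorta
    R_out: 10.0
    C: 0.0008
    V0: 0.078
    valve_out: false
    region: chest
    lung_coupling: 1
    mediastinal_mode: tpf_scaled
  - id: C9
    name: Carotid arteries
    R_out: 60.0
    C: 0.0002
    V0: 0.132
    valve_out: false
    region: head
    lung_coupling: 0
    mediastinal_mode: none
  - id: C10
    name: Jugular veins
    R_out: 30.0
    C: 0.012
    V0: 0.216
    valve_out: true
    region: head
    lung_coupling: 0
    mediastinal_mode: none
  - id: C11
    name: Abdominal aorta
    R_out: 25.0
    C: 0.0004
    V0: 0.114
    valve_out: false
    region: abdomen
    lung_coupling: 0
    mediastinal_mode: none
  - id: C12
    name: Femoral arteries
    R_out: 360.0
    C: 0.0002
    V0: 0.133
    valve_out: false
    region: legs
    lung_coupling: 0
    mediastinal_mode: none
  - id: C13
    name: Femoral veins
    R_out: 180.0
    C: 0.0047
    V0: 0.267
    valve_out: true
    region: legs
    lung_coupling: 0
    mediastinal_mode: none
  - id: C14
    name: Inferior vena cava
    R_out: 25.0
    C: 0.0234
    V0: 1.93
    valve_out: false
    region: abdomen
    lung_coupling: 0
    mediastinal_mode: none
  peripherals:
    Rh: 5520.0
    Rht: 10780.0
    Rs: 1800.0
    Rl: 8520.0
    Rpc: 105.0
  tpf: 0.75
  rho: 1060.0
  g: 9.8
  leg_length: 0.79
  epsilon_R: 1.0
  P0: 7.0
tpf: 0.75
compression:
  amplitude: 400.0
  frequency: 100.0
  duty_cycle: 0.5
  k_lung: 0.05751953125
  k_med: 0.05751953125
  force_gate_threshold: 1.0e-09
plr:
  enabled: true
  angle_deg: 90.0
  start_time: 20.0
  leg_length: 0.79
  ramp: 0.0
solver:
  dt: 0.001
  duration: 40.0
  record_every: 1
  method: rk4
windows:
  before:
  - 10.0
  - 20.0
  after:
  - 30.0
  - 40.0
output_dir: .
log_level: INFO
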