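name: desk_small
network:
  N_e: 2000
  N_i: 400
  N_s: 200
  connections:
    RS|RS:
      fan_in: 300
      J_mean: 0.1
      plasticity: 1
      delay_lo: 0.5
      delay_hi: 1.0
    RS|FS:
      fan_in: 200
      J_mean: 0.5
      plasticity: 1
      delay_lo: 0.5
      delay_hi: 1.0
    RS|SOM:
      fan_in: 100
      J_mean: 0.25
      plasticity: 2
      delay_lo: 0.5
      delay_hi: 1.0
    FS|RS:
      fan_in: 800
      J_mean: 0.2
      plasticity: 1
      delay_lo: 0.5
      delay_hi: 1.0
    FS|FS:
      fan_in: 200
      J_mean: 1.0
      plasticity: 1
      delay_lo: 0.5
      delay_hi: 1.0
    FS|SOM:
      fan_in: 50
      J_mean: 0.1
      plasticity: 2
      delay_lo: 0.5
      delay_hi: 1.0
    SOM|RS:
      fan_in: 1000
      J_mean: 0.1
      plasticity: 3
      delay_lo: 0.5
      delay_hi: 1.0
    SOM|FS:
      fan_in: 100
      J_mean: 0.25
      plasticity: 1
      delay_lo: 0.5
      delay_hi: 1.0
  gap_J_mean: 0.05
  gap_delay_lo: 0.1
  gap_delay_hi: 0.5
  r_ext_th: 10.0
  r_ext_bc: 2.0
  bias_mV: 10.0
  I_max: 5.0
readout:
  N_read_RS: 1000
  N_read_FS: 100
  N_read_SOM: 100
  tau_ir: 20.0
  som_boost: 1.2
  delta_T: 10.0
  tau_filter: 15.0
  N_B: 1000
  N_I: 250
  C_ii_R: 200
  J_ei_R: 0.6
  bc_rate_factor: 0.5
sim:
  dt: 0.05
  T_idle: 1200.0
  T_end: 1200.0
  T_w: 600.0
  record_dt: 1.0
  N_trials: 400
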