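# Quiescence-release time course: BJ-like fibroblasts released from G0.
# Restriction-point passage from ~9 h, MCM loading from ~11 h, S entry from
# ~14.5 h. Gates and thresholds are derived from events pooled across
# timepoints (identical regions for every sample).
seed: 1
scenario:
  preset: bj_g0_release
  n_cells: 20000
gating:
  k_mad: 4.0
  w_lo: 0.10
  w_hi: 0.10
  mcm_quantile: 0.99
  pooled: true
n_boot: 200
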