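# Desk-scale study configuration: 96^3 phantom at 2 mm, 64^3 reconstruction
# at 3 mm, 84 angles, 10 Poisson noise realizations.  Run with:
#   cardiacpvc run-study --config configs/desk.yaml --out results/desk
n_angles: 84
radial_mm: 2.0
recon_shape: [64, 64, 64]
recon_voxel_mm: 3.0
scheme: "3i12s,2i6s,2i1s"
gate_mode: DUAL
counts_dual_gate: 3.9e+06
n_realizations: 10
base_seed: 1
threshold_fraction: 0.7
roster:
  - {name: osem3d_rr_post5, kind: osem-rr, post_fwhm_mm: 5.0}
  - {name: map_tv, kind: map-tv, beta: 1.0}
  - {name: map_rd, kind: map-rd, beta: 10.0, gamma: 100.0}
  - {name: bowsher_mr_perf, kind: map-bowsher, beta: 4.0, n_neighbours: 6,
     anatomy: mr}
  - {name: bowsher_hrct, kind: map-bowsher, beta: 4.0, n_neighbours: 6,
     anatomy: hrct}
  - {name: bowsher_mr_aniso, kind: map-bowsher, beta: 4.0, n_neighbours: 6,
     anatomy: mr_aniso}
  - {name: bowsher_mr_shift2, kind: map-bowsher, beta: 4.0, n_neighbours: 6,
     anatomy: mr, anatomy_shift_mm: [1.414, 0.0, 1.414]}
  - {name: bowsher_mr_mism1_ph1, kind: map-bowsher, beta: 4.0, n_neighbours: 6,
     anatomy: mr, heart_scale: 0.9}
  - {name: bowsher_mr_mism2_ph2, kind: map-bowsher, beta: 4.0, n_neighbours: 6,
     anatomy: mr, heart_scale: 1.05, phase_delta: 0.08}
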