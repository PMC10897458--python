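# Versioned clustering-profile registry.  Field names follow the published
# hyperparameter vocabulary (investigate_min_sample, radius_ratio,
# rough_min_points, final_min_points, filter_mode).
version: 1
profiles:
  default:
    dbscan_eps: null   # auto: nearest-neighbour spacing at the observed density
    dbscan_min_samples: 10
    hdbscan_min_cluster_size: 200
    hdbscan_min_samples: null
    cluster_selection_epsilon: 0.03
    investigate_min_sample: 50
    radius_ratio: 1.96
    refine_margin: 0.3
    rough_min_points: 50
    final_min_points: 20
    filter_mode: strict
    density_k: 10
    pdist_max_points: 2000
    failsafe_bins: 128
    failsafe_sigma: 2.0
    failsafe_percentile: 90.0
    seed: 0
  # Simulated-movie treatments: seed-detection requirement lowered to 25
  # because simulated noise is uniform (no docking clumps).
  isotropic:
    cluster_selection_epsilon: 0.05
    investigate_min_sample: 25
  random:
    investigate_min_sample: 25
  fibril:
    dbscan_eps: 0.1
    hdbscan_min_cluster_size: 60
    hdbscan_min_samples: 30
    cluster_selection_epsilon: 0.0
    radius_ratio: 1.0
    investigate_min_sample: 25
    refine_margin: 0.6
    rough_min_points: 60
    final_min_points: 60
  # Sparse nanostructure treatments (3 µm ROI, 4–25 detections/structure):
  # DBSCAN branch engages automatically at these densities; final size
  # filter requires > 5 points except in 4-point mode.
  sparse-25:
    dbscan_eps: 0.07
    dbscan_min_samples: 10
    density_k: 3
    investigate_min_sample: 10
    rough_min_points: 10
    final_min_points: 6
  sparse-15:
    dbscan_eps: 0.07
    dbscan_min_samples: 7
    density_k: 3
    investigate_min_sample: 7
    rough_min_points: 7
    final_min_points: 6
  sparse-8:
    dbscan_eps: 0.07
    dbscan_min_samples: 5
    density_k: 3
    investigate_min_sample: 5
    rough_min_points: 5
    final_min_points: 6
  sparse-4:
    dbscan_eps: 0.07
    dbscan_min_samples: 3
    density_k: 3
    investigate_min_sample: 3
    rough_min_points: 3
    final_min_points: 3
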