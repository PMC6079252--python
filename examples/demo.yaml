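# Example run configuration for a simulated stack acquisition.
# Every simulated run must carry its own seed so it is reproducible.
stack_name: demo
base_dir: ./demo_out
mirror_dir: null
number_of_slices: 5
slice_thickness_nm: 25.0
seed: 7

# Stage calibration: motor axes are rotated and scaled relative to the SEM
# frame.  Obtain these values with `sbemctl calibrate`.
calibration:
  angle_x_deg: 30.0
  angle_y_deg: 28.0
  scale_x: 1.02
  scale_y: 0.98

beam:
  current_pa: 270.0
  dwell_time_us: 0.8
  pixel_size_nm: 10.0
  landing_energy_kev: 1.8

grids:
  - grid_id: 0
    origin_sem_um: [-8.0, -6.0]
    rows: 2
    cols: 2
    frame_size_px: [64, 48]
    pixel_size_nm: 10.0
    overlap_px: 8
    dwell_time_us: 0.8
    active: all          # or a list of [row, col] pairs for adaptive tiling
    acquisition_interval: 1
    interval_offset: 0

overviews:
  - ov_id: 0
    center_sem_um: [0.0, 0.0]
    frame_size_px: [200, 150]
    pixel_size_nm: 150.0
    acquisition_interval: 1
    interval_offset: 0

stub:
  center_sem_um: [0.0, 0.0]
  size_um: [200.0, 150.0]
  # pixel_size_nm defaults to 372

sweep_policy:
  depth_nm: 70.0
  max_sweeps: 3
  continue_after_max: false

debris:
  method: quadrant_meansd
  mean_threshold: 10.0
  sd_threshold: 10.0
  restrict_to_active: false

monitoring:
  mean_threshold: 20.0
  sd_threshold: 15.0
  range_limits: [1.0, 254.0, 0.0, 255.0]

autofocus:
  mode: none
  interval: 25
  offset: 0

stage_move_overhead_s: 2.0
cut_overhead_s: 12.0

simulator:
  base_wd: 7.0
  knife_tilt: [0.02, 0.01]
  noise_scale: 8.0
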