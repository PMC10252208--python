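"""Simulate one lysosome-trafficking movie and run the tracking stage.

Generates a seeded two-corridor movie with a 40% processive fraction, tracks
it (LoG detection -> greedy nearest linking -> per-track parameters), and
compares the recovered motility summary with the generator's ground truth.
"""

import numpy as np

import axoquant as aq

calib = aq.Calibration()  # 229.55 nm/px, 3.3 frames/s per channel
cfg = aq.OrganelleSceneConfig(
    n_organelles=60, moving_fraction=0.4,
    speed_mean_um_s=0.8, speed_sd_um_s=0.2,
    n_frames=100, width=512, height=256, seed=42,
)
stack, truth = aq.generate_organelle_movie(cfg, calib)
linked, params, summary = aq.track_movie(stack.data, calib, marker="lyso")

print(f"tracks (>=2 spots):      {summary['n_tracks']}")
print(f"mean speed (um/s):       {summary['mean_speed']:.3f}   (all tracks, incl. stationary)")
print(f"percent moving:          {summary['percent_moving']:.1f}")
print(f"antero/retro ratio:      {summary['antero_retro_ratio']:.2f}")
print(f"lysosome Feret (um):     {summary['shape']:.2f}")

processive = truth.objects[truth.objects["class"] == "processive"]
moving_speeds = [p.mean_speed for p in params if p.moving]
print(f"\nground truth: {len(processive)}/{len(truth.objects)} processive, "
      f"true mean speed {processive.true_speed_um_s.mean():.3f} um/s")
print(f"recovered moving-track mean speed: {np.mean(moving_speeds):.3f} um/s")
print("(the moving-track estimate recovers the configured processive speed; the")
print(" all-track mean is diluted by stationary and jittering organelles)")

mip = aq.max_intensity_projection(stack.data)
print(f"\nmax-intensity projection: {mip.shape}, processive runs appear as streaks")
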