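"""Decompose a facial thermal video into independent spatial sources.

Simulates one subject (96×96 px, 5 Hz, 2 min) with planted nose, cheek
and respiration sources plus 3 px of head motion, removes the motion by
iterated optical-flow warping, masks the face, and runs spatial ICA.
The printed table shows, for each labelled component, its overlap with
the anatomical templates and the fraction of its spectral power inside
the normal respiratory band (0.16–0.35 Hz): the nose component should
be respiration-free while the respiration component is band-dominated.
"""

import numpy as np

import thermoflow as tf

scene = tf.make_face_scene(seed=0)
video, truth = tf.simulate_thermal_video(
    scene=scene, T=600, seed=0, motion_amplitude=3.0, noise_sigma=0.05
)
print(f"video: {video.n_frames} frames @ {video.rate} Hz, {video.shape[1:]} px")

corrected, report = tf.motion_correct(video, sigma=5.0)
print(f"motion correction: {int(report.converged.sum())}/{video.n_frames} "
      f"frames below the 1 px criterion")

mask = tf.build_face_mask(corrected.frames.mean(axis=0), threshold=28.0)
matrix = tf.vectorize(corrected, mask)
print(f"face mask: {mask.n_pixels} pixels -> source matrix {matrix.data.shape}")

dec = tf.decompose(matrix, n_components=15, seed=1)
templates = scene.template_vectors(mask.mask)
print(f"\n{'comp':>4} {'label':>12} {'resp. band':>10}  best-region overlap")
for ci in range(dec.n_components):
    p = tf.profile_component(
        dec.spatial_maps[ci], dec.timecourses[:, ci], templates, video.rate
    )
    if p.label != "other":
        best = max(p.region_overlap, key=p.region_overlap.get)
        print(f"{ci:>4} {p.label:>12} {p.respiratory_band_fraction:>10.2f}  "
              f"{best}: {p.region_overlap[best]:.2f}")

# recovery against the planted ground truth
idx = np.argwhere(mask.mask)
true_maps = truth.spatial_maps[:, idx[:, 0], idx[:, 1]]
_, r = tf.match_components(true_maps, dec.spatial_maps)
print(f"\nmatched |spatial r| vs planted sources "
      f"(nose, cheek, respiration): {np.round(r, 3)}")
print("values near 1 mean the decomposition recovered the planted anatomy.")
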