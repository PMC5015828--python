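"""Simulate a subject's pre-test and decoder-construction session.

Builds the standard synthetic subject (a 24-voxel target region "CC" that
linearly encodes facial preference, plus two silent regions), rates a
400-face pool on the 1-10 Likert scale, selects the 100 highest / 100
lowest / 40 neutral faces (with 15 induction and 15 baseline faces drawn
from the neutral set), and simulates the 12-run x 20-trial fMRI session.
"""

import pandas as pd

import decnef as dn

gt = dn.make_ground_truth(
    n_other_rois=2, roi_voxels=20, target_voxels=24, noise_sd=1.0, seed=7
)
pool = dn.generate_face_pool(400, gt, seed=1)
pool = dn.select_faces(pool, seed=2)
runs, trial_table = dn.simulate_rating_session(gt, pool, n_runs=12, trials_per_run=20, seed=3)

counts = pd.Series(pool.assigned_set).value_counts()
print("face sets:", counts.to_dict())
print(f"session: {len(runs)} runs x 20 trials, {runs[0].n_volumes} volumes/run at TR {runs[0].tr_s} s")
ratings = trial_table.loc[trial_table.period == "rating", "rating"]
print(f"behavioral ratings: mean {ratings.mean():.2f}, range {ratings.min()}..{ratings.max()}")

# The face-set counts follow the selection quotas (100/100/40 with a 15+15
# split of the neutral set); each 252 s run holds 126 volumes; the mean
# rating is near the scale midpoint because latent preferences are uniform.
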