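"""Generalise valence decoding across subjects via hyperalignment.

Three synthetic subjects share a common valence signal but express it in
individually rotated, scaled and shifted feature spaces. Procrustes
hyperalignment (two-stage group averaging) brings them into a common space;
a nested leave-phrases-out / leave-subject-out cross-validation then measures
classification of a held-out subject on held-out phrases.
"""

import numpy as np

from facevalence import classify as cl
from facevalence import hyperalign as ha
from facevalence import stats as st
from facevalence.synthetic import DatasetSpec, generate_embedded_subjects

spec = DatasetSpec(n_subjects=3, repeats_per_subject=(6, 6, 7),
                   clip_types=("prefix",), n_frames_prefix=12, seed=23)
datasets = generate_embedded_subjects(spec, effect_size=4.0)

res = ha.run_cross_subject_cv(datasets)
t = st.ttest_vs_chance(res.fold_accuracies)
print(f"nested CV: {len(res.fold_accuracies)} folds "
      "(5 outer phrase pairs x 3 subjects x 2 assignments)")
print(f"cross-subject mean accuracy: {res.mean_accuracy:.3f} "
      f"(t({t.df}) = {t.statistic:.2f}, p = {t.p_raw:.2g} vs chance)")

d0 = datasets[0]
man = (d0.index.drop_duplicates("clip_id")
       .merge(d0.index.groupby("clip_id").size().rename("n_frames"),
              on="clip_id"))
within = cl.run_within_subject_cv(d0.samples,
                                  d0.index["clip_id"].to_numpy(), man)
print(f"within-subject mean accuracy (same data): "
      f"{within.mean_accuracy:.3f}")
print("-> the valence code generalises across subjects after alignment, "
      "though below the within-subject ceiling — the shared signal is only "
      "part of each individual's expression code.")
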