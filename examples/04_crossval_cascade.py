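"""Cross-validate the full cascade on balanced phantoms.

Runs 5 repeats of stratified 5-fold cross-validation of the
Wiener -> 2D-DWT -> PPCA -> random-subspace-KNN pipeline on 60
phantoms, refitting PPCA and the ensemble inside each training fold,
and prints the per-repeat and mean accuracy.
"""

from pathobrain import evaluation
from pathobrain.config import PipelineConfig
from pathobrain.pipeline import features_from_images
from pathobrain.synthetic import PhantomSpec, generate_dataset

spec = PhantomSpec(n_images=60, fraction_pathological=0.5, seed=0)
images, labels = generate_dataset(spec)
cfg = PipelineConfig(seed=0)

X = features_from_images(images, cfg)
plan = evaluation.make_cv_plan(labels, cfg.n_folds, cfg.n_repeats, cfg.seed)
result = evaluation.run_cv(X, labels, cfg, plan)

print(result.summary())
print()
print("With the default lesion load the classes are separable, so held-out "
      "accuracy approaches 100%; rerun with lesion_contrast=0.0 in the "
      "PhantomSpec and the same pipeline scores at chance (~50%).")
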