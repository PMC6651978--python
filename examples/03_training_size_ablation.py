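"""Training-size ablation against one fixed test set.

Reduces the per-species training set 20 → 10 → 5 observations with nested
subsampling (every smaller training set is contained in the larger one)
while the test observations never change, so accuracy differences reflect
training-set size only.
"""

import plantfusion as pf

config = pf.SyntheticConfig(seed=5, background_confound=1.0)
manifest, images = pf.generate_image_arrays(config)
loader = pf.array_loader(images)
split = pf.split_by_observation(manifest, n_train=20, n_val=5, n_test=5, seed=5)

table, reports = pf.ablation_curves(
    manifest, split, training_sizes=[20, 10, 5],
    config=pf.TrainConfig(seed=5), image_loader=loader,
)

full = "EP+FF+FL+LT+LB"
print("training observations per species -> fused Top-1 (same test set):")
for size in (20, 10, 5):
    res = reports[size].per_combination[full]
    print(f"  {size:>3}: {res.top1_mean:.2f}  (SE {res.top1_se:.2f})")
print("\nA flat curve would say more training data is unlikely to help; a")
print("steep drop says the classifier is data-limited at the smaller sizes.")
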