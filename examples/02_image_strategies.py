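"""Per-perspective scorers (strategy A) versus one pooled scorer (B).

Renders a synthetic image dataset in which all five images of one
observation share a background tint (a stand-in for habitat background),
then trains both strategies and compares their all-perspective fused
accuracy on the same test observations.
"""

import plantfusion as pf

config = pf.SyntheticConfig(seed=3, background_confound=1.5)
manifest, images = pf.generate_image_arrays(config)
loader = pf.array_loader(images)
split = pf.split_by_observation(manifest, n_train=20, n_val=5, n_test=5, seed=3)
train_config = pf.TrainConfig(seed=3)

scorers = pf.train_strategy_a(manifest, split, train_config, loader)
mats_a = {p: pf.score(scorers[p], manifest, split, p, loader) for p in pf.PERSPECTIVES}
report_a = pf.evaluate_all_combinations(mats_a, manifest, split)

scorer_b = pf.train_strategy_b(manifest, split, train_config, loader)
mats_b = pf.strategy_b_matrices(scorer_b, manifest, split, loader)
report_b = pf.evaluate_all_combinations(mats_b, manifest, split)

full = "EP+FF+FL+LT+LB"
a = report_a.per_combination[full].top1_mean
b = report_b.per_combination[full].top1_mean
print(f"strategy A (five perspective-specific scorers): fused Top-1 = {a:.2f}")
print(f"strategy B (one scorer on all images):          fused Top-1 = {b:.2f}")
print(f"gap A - B = {a - b:+.2f}")
print("\nThe pooled scorer must serve five visually different perspectives at")
print("once and is more easily distracted by the shared background signal, so")
print("perspective-specific training wins on fused accuracy.")
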