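"""The observation data model: manifests, balance, leakage-free splits.

Writes a synthetic dataset to disk, loads its manifest back, verifies
balance, and shows that splitting keeps all five images of one plant in
the same subset.
"""

import tempfile
from pathlib import Path

import plantfusion as pf

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "dataset"
    config = pf.SyntheticConfig(
        n_species=4, n_observations_per_species=6, group_structure=None,
        image_size=24, seed=0,
    )
    pf.generate_image_dataset(config, out)
    manifest = pf.load_manifest(out / "manifest.csv")
    balance = pf.validate_balance(manifest)
    print(f"loaded {len(manifest)} observations = {manifest.n_images} image records")
    print(f"balanced: {balance.balanced}, per-species counts: {balance.counts}")

    split = pf.split_by_observation(manifest, n_train=4, n_val=1, n_test=1, seed=0)
    print(f"\nsplit: {len(split.train_ids)} train / {len(split.validation_ids)} val "
          f"/ {len(split.test_ids)} test observations")
    overlap = split.train_ids & split.test_ids
    print(f"train ∩ test observation ids: {sorted(overlap) or 'none'}")

    reduced = pf.reduce_training(split, manifest, n_reduced=2, seed=0)
    print(f"reduced training to 2/species: nested within parent = "
          f"{reduced.train_ids < split.train_ids}, "
          f"test set unchanged = {reduced.test_ids == split.test_ids}")
print("\nSplitting whole observations (never single images) guarantees a test")
print("plant is never partially seen during training.")
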