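"""Generate a phantom cohort and run the preprocessing pipeline.

Writes 30 synthetic RGB slices with exact tumor masks to ./phantoms_demo,
reloads them through the standard loader, filters out tumor-free slices,
and prints the 70/20/10 split sizes.
"""

from fpnseg import (
    PhantomConfig,
    generate_dataset,
    load_pairs,
    preprocess_records,
    split_dataset,
)

config = PhantomConfig(image_size=(64, 64), tumor_probability=0.5, seed=42)
records, manifest = generate_dataset(30, config, out_dir="phantoms_demo", seed=42)
print(f"generated 30 phantoms, {manifest.n_positive} with tumors")

reloaded = load_pairs("phantoms_demo")
processed = preprocess_records(reloaded)  # normalize, binarize, drop negatives
print(f"after filtering tumor-free slices: {len(processed)} records")

split = split_dataset(processed, (0.7, 0.2, 0.1), seed=42)
print(f"train/validation/test sizes: {split.sizes}")
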