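"""Photometric augmentation counting and the stratified 70:20:10 split.

Run at archive scale on the index alone: 3297 images (1800 benign, 1497
malignant) times five photometric variants gives 16,485, and the split
rounding rule puts 11,540 of them in the training set.
"""

import pandas as pd

from dermopipe.dataset import SplitSpec, augment_index, split

index = pd.DataFrame(
    {
        "path": [f"img_{i}.png" for i in range(3297)],
        "label": ["benign"] * 1800 + ["malignant"] * 1497,
    }
)
augmented = augment_index(index)
print(f"images before augmentation : {len(index)}")
print(f"images after augmentation  : {len(augmented)}")

result = split(augmented, SplitSpec((0.7, 0.2, 0.1), seed=0))
counts = result.groupby(["label", "split"]).size().unstack()
print(counts.to_string())
print(f"training total             : {(result['split'] == 'train').sum()}")
# Each class is allocated independently (train rounded half-up, test rounded
# down, validation takes the remainder), which is what makes the training
# total land exactly on 11,540.
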