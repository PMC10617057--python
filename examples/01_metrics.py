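"""Overlap metrics on a constructed mask pair.

Builds two 20x20 masks with |A| = |B| = 100 and |A ∩ B| = 50, then prints
the Dice coefficient, Jaccard index, pixel accuracy and the smoothed Dice
loss at the default smoothing (xi = 100).
"""

import numpy as np

from fpnseg import confusion_counts, dice_loss, dsc, jaccard, pixel_accuracy

pred = np.zeros((20, 20), np.uint8)
ref = np.zeros((20, 20), np.uint8)
pred.flat[:100] = 1
ref.flat[50:150] = 1

counts = confusion_counts(pred, ref)
print(f"DSC       {dsc(pred, ref):.4f}")          # 0.5: half the pixels overlap
print(f"Jaccard   {jaccard(pred, ref):.4f}")      # 1/3: overlap over union
print(f"accuracy  {pixel_accuracy(counts):.4f}")  # 0.75: 100 of 400 pixels disagree
print(f"Dice loss {dice_loss(pred, ref, xi=100):.4f}")  # 1 - (100+100)/(200+100)
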