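"""Train a small network on synthetic phantoms and segment a held-out slice.

A desk-scale run: 8 two-class phantoms, a 2-block width-8 network, 40 epochs
of the joint Dice + reconstruction objective. Prints the loss trajectory,
the training Dice, and held-out metrics for one unseen phantom.
"""
import numpy as np

from sswan import (
    NetworkConfig,
    PhantomConfig,
    SSWAN,
    TrainConfig,
    classification_metrics,
    confusion,
    dice_coefficient,
    generate_dataset,
    train,
)

phantoms = generate_dataset(8, PhantomConfig(size=(64, 64), noise_sigma=0.05,
                                             seed=0), base_seed=0)
heldout = generate_dataset(1, PhantomConfig(size=(64, 64), noise_sigma=0.05,
                                            seed=0), base_seed=500)[0]

model = SSWAN(NetworkConfig(num_blocks=2, width=8, reduction=4, seed=0))
history = train(model, phantoms, TrainConfig(epochs=40))

for h in history[::10] + [history[-1]]:
    print(f"epoch {h['epoch']:3d}  loss {h['loss']:.4f}  "
          f"train dice {h['mean_foreground_dice']:.4f}")

seg = model.segment(heldout.image)
counts = confusion(seg.label_map, heldout.labels, positive_class=1)
report = classification_metrics(counts)
print(f"\nheld-out dice        : "
      f"{dice_coefficient(seg.label_map, heldout.labels):.4f}")
print(f"held-out accuracy    : {report.accuracy:.4f}")
print(f"held-out sensitivity : {report.sensitivity:.4f}")
print(f"held-out specificity : {report.specificity:.4f}")
# Dice near 1 on training phantoms shows the attention trunk plus 1x1 head
# can fit the nested-ellipse geometry; the held-out numbers show the fit
# transfers to unseen geometry drawn from the same phantom distribution.
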