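"""Train the compact DenseBlock-Unet on synthetic images (pure numpy).

Ten 128x128 synthetic fundus images train a depth-2 network on 32x32
patches; an eleventh image held out from training measures generalization.
Takes a couple of minutes on one CPU core.
"""

from fvs3d.channels import ChannelProportion, fuse_channels
from fvs3d.segmentation import (
    SegmenterConfig,
    build_denseblock_unet,
    evaluate_segmentation,
    predict_prob_map,
    train_segmenter,
)
from fvs3d.synthetic import generate_vessel_tree, render_fundus

pairs = []
for i in range(11):
    tree = generate_vessel_tree(image_size=(128, 128), root_radius=5.0,
                                seed=40 + i)
    b = render_fundus(tree, seed=40 + i)
    pairs.append((fuse_channels(b.image, ChannelProportion(1.0, 0.0)), b.mask))

cfg = SegmenterConfig(depth=2, base_channels=8, epochs=25, batch_size=8,
                      patch_size=32, patches_per_epoch=64,
                      learning_rate=3e-3, seed=0)
model = build_denseblock_unet(cfg)
print(f"model: depth {cfg.depth}, base {cfg.base_channels} channels, "
      f"{model.parameter_count()} parameters")

model, losses = train_segmenter(model, pairs[:10], cfg)
print(f"training loss: {losses[0]:.4f} -> {losses[-1]:.4f} "
      f"over {cfg.epochs} epochs")

prob = predict_prob_map(model, pairs[10][0])
m = evaluate_segmentation(prob, pairs[10][1])
print(f"held-out image: AUC {m.auc:.4f}  ACC {m.acc:.4f}  "
      f"SE {m.se:.3f}  SP {m.sp:.3f}")
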