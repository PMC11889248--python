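"""Desk-scale end-to-end run: synthesize, split, train, evaluate.

Trains the dual-attention variant (SE in the inverted-residual blocks, NAM
in the transformer blocks) for 5 epochs on 200 easy-mode synthetic images
at 64x64 and evaluates on a held-out 60-image split.  Takes a few minutes
on one CPU; balanced accuracy on the held-out split typically lands in the
0.90-0.97 range.
"""

import warnings
from dataclasses import replace
from pathlib import Path

from mnvit.model_zoo import PRESETS, build_model, count_parameters
from mnvit.pipeline import split_dataset
from mnvit.synthetic import easy_spec, generate_dataset
from mnvit.train_eval import TrainConfig, evaluate, train

warnings.filterwarnings("ignore", message="degenerate predictions")

out = Path("scratch/example_run")
_, manifest = generate_dataset(260, 0.5, easy_spec(64), seed=1, out_dir=out / "images")
manifest = split_dataset(manifest, ratios=(200 / 260, 0.0001, 59.99 / 260), seed=1)

cfg = replace(PRESETS["MV2_SE_Mb_NAM"], num_classes=2, input_size=64)
model = build_model(cfg, seed=1)
print(f"model MV2_SE_Mb_NAM, {count_parameters(model):,} trainable parameters")

history = train(model, manifest,
                TrainConfig(batch_size=8, epochs=5, input_side=64, seed=1),
                out_dir=out / "run", eval_val=False)
for row in history.epochs:
    print(f"epoch {row['epoch']}  lr {row['lr']:.5f}  train loss {row['train_loss']:.4f}")

report = evaluate(model, manifest, "test", input_side=64)
print(f"\nheld-out test: Avg_Acc {report.avg_acc:.3f}  "
      f"F1 {report.f1:.3f}  ROC {report.roc_auc:.3f}")
print(f"confusion table [[TN, FP], [FN, TP]]: {report.confusion}")
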