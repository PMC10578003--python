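"""Train the convolution-attention accessibility classifier on the study
genome and evaluate it on the held-out 3L arm.

Saves the model checkpoint, training history, per-tissue decision
thresholds, and test metrics (including the GC baseline) under results/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from chromaccess import pipeline

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    study = pipeline.run_study(seed=SEED, verbose=True)
    study.model.save(OUT / "model.npz")
    study.history.to_csv(OUT / "training_history.csv", index=False)

    report = {"thresholds": study.thresholds, "tissues": list(study.tissues)}
    for t in study.tissues:
        r, g = study.test_metrics[t], study.gc_metrics[t]
        report[t] = {"auroc": r.auroc, "aupr": r.aupr,
                     "gc_auroc": g.auroc, "gc_aupr": g.aupr,
                     "n_pos": r.n_pos, "n_neg": r.n_neg}
        print(f"{t}: AUROC {r.auroc:.3f}  AUPR {r.aupr:.3f}  "
              f"(GC baseline AUROC {g.auroc:.3f})  "
              f"threshold {study.thresholds[t]:.4f}")
    (OUT / "model_metrics.json").write_text(json.dumps(report, indent=1))
    print(f"saved model + metrics to {OUT}")


if __name__ == "__main__":
    main()
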