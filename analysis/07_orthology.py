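"""Multi-context peak orthology on a three-species scenario.

Builds three sister genomes with a known conserved fraction, runs the
merge → reciprocal-filter → classify pipeline on their fragmented liftover
maps, and scores the calls against the planted truth.
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
    summary, stats, calls = pipeline.orthology_analysis(
        conserve_fraction=0.75, seed=SEED)
    print(summary.to_string(index=False))
    print(f"pooled conserved fraction: {stats['conserved_fraction']:.3f} "
          f"(target 0.75)")
    print(f"species-specific calls: precision {stats['specific_precision']:.3f}, "
          f"recall {stats['specific_recall']:.3f}")
    summary.to_csv(OUT / "orthology_summary.tsv", sep="\t", index=False)
    (OUT / "orthology_stats.json").write_text(json.dumps(stats, indent=1))


if __name__ == "__main__":
    main()
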