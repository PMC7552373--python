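"""Generate the two synthetic training cohorts with planted ground truth.

Emulates the study design of the real training data: one study of 17 IPF
patients and 6 healthy controls, a second of 46 NSCLC patients and 45
healthy controls, on a shared 1000-gene universe with per-study batch
distortion, 100 differential genes per disease (40 shared), and two
planted mutually exclusive alteration pairs.

Writes expression TSVs, the sample sheet and ground-truth JSON under
results/data/.
"""

import sys
from pathlib import Path

from lungsig import SimulationConfig, simulate_cohorts
from lungsig.simulate import write_cohorts

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    config = SimulationConfig(seed=SEED)
    studies, sheet, truth = simulate_cohorts(config)
    write_cohorts(studies, sheet, truth, OUT)
    for sid, m in studies.items():
        counts = m.samples["phenotype"].value_counts().to_dict()
        print(f"{sid}: {m.n_genes} genes x {m.n_samples} samples {counts}")
    print(f"planted: {len(truth.common_de_genes)} common DE genes, "
          f"{sum(len(v) for v in truth.mutex_pairs.values())} mutex pair "
          f"realizations")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
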