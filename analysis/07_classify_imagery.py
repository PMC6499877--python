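#!/usr/bin/env python
"""Classify imagined letters with the pretrained-encoder softmax head.

Leave-one-run-out over the four imagery runs (train 96 / test 32 per
fold) per subject, with a scrambled-label permutation null; accuracy is
declared significant if it exceeds the null's 95th percentile.
"""

import numpy as np
import pandas as pd
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from studyconfig import CONFIG, RESULTS_DIR, subject_inputs

import prfdecode as pfd


def main() -> None:
    outdir = Path(RESULTS_DIR)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in range(CONFIG.n_subjects):
        inputs = subject_inputs(s)
        pset = pfd.extract_session_patterns(inputs["session"])
        avg = pfd.average_letter_patterns(pset, "perception")
        ae = pfd.train_autoencoder(
            np.vstack([avg[L].values for L in pfd.LETTERS]),
            pfd.autoencoder_config(seed=inputs["seeds"][4]),
        )
        loro = pfd.loro_cross_validate(pset, ae)
        perm = pfd.permutation_test(
            pset, ae, n_permutations=CONFIG.n_permutations,
            seed=inputs["seeds"][5], observed=loro,
        )
        rows.append(dict(
            subject=s, mean_accuracy=loro.mean_accuracy,
            chance=0.25, null_mean=perm.null_mean,
            null_p95=perm.threshold, significant=perm.significant,
            train_size=loro.train_sizes[0], test_size=loro.test_sizes[0],
        ))
        print(f"subject {s}: LORO accuracy {loro.mean_accuracy:.3f} "
              f"(folds {np.round(loro.fold_accuracies, 3)}), null 95th pct "
              f"{perm.threshold:.3f} -> "
              f"{'significant' if perm.significant else 'not significant'}")
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "classification_accuracy.csv", index=False)
    print(f"\n{int(table.significant.sum())}/{len(table)} subjects decode "
          "imagined letters above the permutation threshold "
          f"(theoretical chance {0.25:.2f})")


if __name__ == "__main__":
    main()
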