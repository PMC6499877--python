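#!/usr/bin/env python
"""Extract z-normalized single-trial and average voxel patterns.

High-pass filters and z-normalizes each run, averages the volumes at
onset+2..onset+3, and stores the pattern sets with a tidy manifest.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from studyconfig import CONFIG, RESULTS_DIR, subject_inputs

import prfdecode as pfd
from prfdecode.io import save_patterns_h5


def main() -> None:
    outdir = Path(RESULTS_DIR)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in range(CONFIG.n_subjects):
        session = subject_inputs(s)["session"]
        pset = pfd.extract_session_patterns(session)
        save_patterns_h5(outdir / f"patterns_s{s:02d}.h5", pset)
        pset.manifest.to_csv(outdir / f"patterns_manifest_s{s:02d}.csv",
                             index=False)
        counts = pset.counts()
        print(f"subject {s}: {len(pset.manifest)} single-trial patterns "
              f"({counts[('imagery', 'H')]} imagery / "
              f"{counts[('perception', 'H')]} perception per letter), "
              f"{pset.n_voxels} voxels each")
    print(f"patterns written to {outdir}/patterns_s*.h5")


if __name__ == "__main__":
    main()
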