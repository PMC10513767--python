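#!/usr/bin/env python
"""Generate the synthetic study cohort.

Thirty dermoscopy-like lesions sweeping all 27 (A, B, C) grade cells, with
a ~5% off-canvas (border NA) fraction, rendered to PNG triples plus a JSON
manifest under results/study/cohort/.  Every later stage reads the config
this stage writes, so the whole analysis is reproducible from one seed.
"""

from dermxai.config import RunConfig
from dermxai.pipeline import run_synth

CONFIG = RunConfig(
    seed=0,
    n_lesions=30,
    outdir="results/study",
    lime_segments=24,
    lime_samples=150,
)

if __name__ == "__main__":
    manifest = run_synth(CONFIG)
    print(f"cohort manifest: {manifest}")
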