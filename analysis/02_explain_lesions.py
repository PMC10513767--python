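#!/usr/bin/env python
"""Compute the five saliency maps for every cohort lesion.

The classifier is the seeded fixture CNN at cohort resolution; every
(lesion, technique) pair yields one 16-bit PNG map plus a JSON sidecar
under results/study/maps/.  Grad-CAM, Grad-CAM++, Eigen-CAM and Score-CAM
read the last convolutional layer; LIME perturbs SLIC superpixels and fits
its ridge surrogate with the config's sample budget.
"""

from dermxai.config import RunConfig
from dermxai.pipeline import run_explain

if __name__ == "__main__":
    config = RunConfig.from_yaml("results/study/config.yaml")
    map_dir = run_explain(config)
    print(f"saliency maps: {map_dir}")
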