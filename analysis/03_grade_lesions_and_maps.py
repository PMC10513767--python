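#!/usr/bin/env python
"""Grade the cohort clinically, then grade every saliency map.

Clinical mode applies the algorithmic ABC rubric to each lesion image and
stores the derived color-abnormality maps; map mode grades each technique's
map against the same rubric (border NA propagating from the clinical
grades).  Both modes write one CSV under results/study/.
"""

from dermxai.config import RunConfig
from dermxai.pipeline import run_grade

if __name__ == "__main__":
    config = RunConfig.from_yaml("results/study/config.yaml")
    clinical_csv = run_grade(config, mode="clinical")
    map_csv = run_grade(config, mode="map")
    print(f"clinical grades: {clinical_csv}")
    print(f"map grades:      {map_csv}")
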