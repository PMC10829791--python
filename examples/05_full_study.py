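"""End-to-end synthetic study run.

Generates a calibrated two-group cohort, fits kinetic subjects, segments a
phantom, runs the group comparisons and prints the headline contrasts.
"""

import json

from batkinetics import run_study
from batkinetics.pipeline import StudyConfig
from batkinetics.synthetic import CohortConfig

cfg = StudyConfig(seed=1, cohort=CohortConfig(seed=1, calibrate=True))
bundle = run_study(cfg)

print(json.dumps(bundle["headline"], indent=2))
print("\nphantom segmentation exact:", bundle["petseg"]["mask_matches_truth"])
print("kinetic fits converged:", all(k["converged"] for k in bundle["kinetics"]))
# The headline block reports the fold-difference of group median BAT
# volume/activity, the percent-lower HBAT VLDL-TG, and the age gap.
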