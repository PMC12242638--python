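"""Curate a bioactivity table into active/inactive screening sets.

Builds a small synthetic Ki/Kd/IC50 table with a known composition,
classifies it with the standard kinase thresholds (active <= 100 nM,
inactive >= 5000 nM, Ki/Kd only), applies the structural filters and
picks one diverse representative per Tanimoto cluster.
"""

import tempfile
from pathlib import Path

from phorescreen.curation import (
    apply_structural_filters,
    classify_activity,
    diversity_select,
    parse_activity_table,
)
from phorescreen.synthetic import make_activity_table

with tempfile.TemporaryDirectory() as td:
    make_activity_table(
        n_active=12, n_inactive=25, n_intermediate=6, n_ic50=4,
        seed=11, out_dir=td,
    )
    records, rejects = parse_activity_table(Path(td) / "activities.csv")

labeled = classify_activity(records)
kept, removed = apply_structural_filters(labeled.actives)
reps, clusters = diversity_select(kept, distance_threshold=0.5)

print(f"parsed {len(records)} records, {len(rejects)} rejected rows")
print(f"actives: {len(labeled.actives)}  inactives: {len(labeled.inactives)}  "
      f"excluded: {len(labeled.excluded)}")
print(f"actives surviving salt/stereo/MW filters: {len(kept)}")
print(f"diversity representatives at Tanimoto distance 0.5: {len(reps)}")
# The excluded bucket holds the intermediate-potency band (100-5000 nM)
# and IC50 rows, which are never pooled with binding constants.
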