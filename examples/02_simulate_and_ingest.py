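"""Generate a small synthetic cohort, write it as TSVs, read it back, and
standardize it (stage harmonization, log2, probe collapse)."""

import tempfile
from pathlib import Path

from chemoatlas import (
    collapse_probes,
    default_cohort_spec,
    generate_cohort,
    read_dataset,
    to_log2,
    write_cohort,
)

spec = default_cohort_spec(seed=0, n_per_arm=5)
datasets = generate_cohort(spec)
print(f"generated {len(datasets)} datasets; first: {datasets[0].dataset_id} "
      f"with {datasets[0].matrix.shape[0]} probes x {datasets[0].matrix.shape[1]} samples")

with tempfile.TemporaryDirectory() as tmp:
    write_cohort(datasets, tmp)
    ds = read_dataset(Path(tmp) / "ibd_1")
    # raw labels are heterogeneous ("UC", "CD", "normal colonic mucosa", ...)
    # but every sample harmonizes onto one of the five stages:
    labels = {(s.raw_label, s.stage) for s in ds.samples}
    for raw, stage in sorted(labels):
        print(f"  {raw!r:26} -> {stage}")
    table = collapse_probes(to_log2(ds))
    print(f"collapsed to {len(table.genes)} genes "
          f"(duplicate probes resolved to the strongest mean signal)")
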