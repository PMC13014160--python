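"""Simulate the two tracer-like domains and quantify their label shift.

Generates small FDG-like (source) and PSMA-like (target) cohorts with the
built-in simulator and prints the lesion count and size statistics that make
cross-tracer adaptation a label-shift problem, not just an appearance
problem.
"""

import numpy as np

from tracershift import (
    AdaptationConfig,
    box_volume_cc,
    default_domain_specs,
    generate_dataset,
    size_histogram,
)

fdg, psma = default_domain_specs()
cohorts = {
    spec.name: generate_dataset(spec, 30, shape=(48, 48, 48), seed=seed)
    for spec, seed in ((fdg, 0), (psma, 1))
}

binning = AdaptationConfig().binning
hists = {}
for name, data in cohorts.items():
    counts = [len(s.boxes) for s in data]
    vols = [box_volume_cc(b, s.spacing) for s in data for b in s.boxes]
    hists[name] = size_histogram(
        [b for s in data for b in s.boxes], data[0].spacing, binning
    )
    print(
        f"{name}: {np.mean(counts):.2f} lesions/subject, "
        f"median lesion volume {np.median(vols):.2f} cc, "
        f"largest {np.max(vols):.1f} cc"
    )

l1 = np.abs(hists["fdg"] - hists["psma"]).sum()
print(f"\nL1 distance between the size-bin histograms: {l1:.3f}")
print(
    "The target domain has roughly twice the lesions per subject and a much\n"
    "smaller typical lesion; an L1 distance near 1 means the two size\n"
    "compositions barely overlap, so a source-tuned detector and a fixed\n"
    "selection rule both inherit the wrong size profile."
)
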