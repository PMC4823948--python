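#!/usr/bin/env python
"""Generate one example dataset per modality and record its ground truth.

Writes a view field per biosensor assay (multi-page TIFF + truth sidecar),
a cytometry event table, and an HE tissue image under results/simulated/,
then prints what was planted in each — the latent labels that the later
analyses must recover.
"""

from pathlib import Path

import icd_profiler as icd
from icd_profiler.io import write_events_csv, write_field_tiff, write_tissue_image

OUT = Path("results/simulated")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 11

for assay in icd.ASSAYS:
    spec = icd.FieldSpec(assay=assay, responder_fraction=0.4, seed=SEED)
    img, truth = icd.generate_field(spec)
    write_field_tiff(img, OUT / f"field_{assay.lower()}.tiff", truth)
    print(
        f"{assay:10s}: {len(truth.cells)} cells, "
        f"{truth.cells.responder.sum()} responders, "
        f"{truth.cells.dead.sum()} dead"
    )

espec = icd.EventSpec(seed=SEED)
events, etruth = icd.generate_events(espec)
write_events_csv(events, OUT / "events.csv")
etruth.to_csv(OUT / "events_truth.csv", index=False)
print(
    f"events    : {len(events)} events, live fraction "
    f"{etruth.live.mean():.3f}, positive among live "
    f"{etruth[etruth.live].marker_positive.mean():.3f}"
)

tspec = icd.TissueSpec(seed=SEED)
rgb, ttruth = icd.generate_he_tissue(tspec)
write_tissue_image(rgb, OUT / "tissue.png")
print(
    f"tissue    : necrotic fraction {ttruth.necrotic_area_fraction:.3f}, "
    f"{ttruth.leukocyte_count} leukocytes planted"
)
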