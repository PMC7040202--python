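"""Negative control: score the EGFR-like null cohort.

The signature trained on the texture-driven cohort is applied unchanged
(training normalization and cutoff) to a cohort whose hazards are
texture-independent; stratification should NOT be significant.
"""

import pandas as pd

from common import demo_config
from ctradiomics.io_formats import read_clinical, read_image, read_json, read_mask
from ctradiomics.features import extract_features
from ctradiomics.survival import SignatureModel, grho_logrank, stratify
from pathlib import Path

cfg = demo_config()
out = Path(cfg.output_dir)
sel = read_json(out / "selection.json")
model = SignatureModel.from_dict(read_json(out / "signature.json")["model"])

null_dir = out / "cohort_null"
clinical = read_clinical(null_dir / "clinical.csv")
rows = []
for pid in clinical["patient_id"]:
    img = read_image(null_dir / f"{pid}_image.nrrd")
    mask = read_mask(null_dir / f"{pid}_mask.nrrd", img)
    rows.append(extract_features(img, mask, cfg.extraction(), patient_id=pid))
feats = pd.DataFrame(rows)

mean = pd.Series(sel["normalization"]["mean"])
sd = pd.Series(sel["normalization"]["sd"])
scores = model.score((feats[mean.index] - mean) / sd)
groups = stratify(model, scores)
chi, p = grho_logrank(
    clinical["pfs_days"].to_numpy(), clinical["event"].to_numpy(), groups, rho=cfg.rho
)
print(f"null cohort n={len(clinical)}: G-rho log-rank chi2={chi:.3f}, p={p:.3f}")
print("no significant stratification expected (p should usually exceed 0.05)")
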