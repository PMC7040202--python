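"""Evaluate the signature on both cohort halves.

Kaplan-Meier stratification with the G-rho (rho = 1) weighted log-rank
test, Harrell C-index with bootstrap CI, time-dependent AUC at 183 days,
baseline chi-square comparisons, per-factor hazard ratios, and the
clinical/combined model comparison.
"""

from common import demo_config, publish
from ctradiomics.io_formats import read_json
from ctradiomics.pipeline import stage_evaluate

cfg = demo_config()
path = stage_evaluate(cfg)
rep = read_json(path)
for name in ("train", "validation"):
    r = rep[name]
    lo, hi = r["cindex_ci"]
    print(
        f"{name}: n={r['n']} events={r['n_events']} "
        f"C-index={r['cindex']:.3f} (95% CI {lo:.3f}-{hi:.3f}) "
        f"AUC(183d)={r['auc'] if r['auc'] is None else round(r['auc'], 3)} "
        f"log-rank p={r['logrank_p']:.4f} "
        f"median PFS high/low={r['median_pfs'].get('high')}/{r['median_pfs'].get('low')}"
    )
m = rep["models"]
print(f"clinical covariates passing the screen: {m['clinical_covariates']}")
print(f"signature validation C-index: {m['signature_cindex_validation']:.3f}")
if m["clinical_model"]:
    print(f"clinical model validation C-index: {m['clinical_model']['cindex_validation']:.3f}")
print(f"combined model validation C-index: {m['combined_model']['cindex_validation']:.3f}")
publish('report.json', 'forest_table.csv', 'km_train_high.csv', 'km_train_low.csv', 'km_validation_high.csv', 'km_validation_low.csv')
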