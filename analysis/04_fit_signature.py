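"""Fit the radiomic signature.

Unpenalized multivariate Cox regression on the selected features; the
signature score is the linear predictor and the training-median score is
the high/low risk cutoff.
"""

from common import demo_config, publish
from ctradiomics.io_formats import read_json
from ctradiomics.pipeline import stage_fit

cfg = demo_config()
path = stage_fit(cfg)
model = read_json(path)["model"]
print("radiomic signature:")
for name, coef in zip(model["feature_names"], model["coefs"]):
    print(f"  {coef:+.4f} x {name}")
print(f"training-median cutoff: {model['cutoff']:.4f}")
publish('signature.json')
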