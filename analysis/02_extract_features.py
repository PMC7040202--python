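"""Extract the 481-feature radiomic vector for every patient.

13 shape features plus 9 intensity channels (original + 8 undecimated
coif1 wavelet sub-bands) x 52 features (16 first-order, 24 GLCM, 12 GLRLM)
on the 1 mm isotropic grid, 32 gray levels, 13 directions at distance 1.
"""

from common import demo_config
from ctradiomics.io_formats import read_feature_table
from ctradiomics.pipeline import stage_extract

cfg = demo_config()
path = stage_extract(cfg)
table = read_feature_table(path)
print(f"feature table: {table.shape[0]} patients x {table.shape[1]} features -> {path}")
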