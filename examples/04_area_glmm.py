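"""Fit the gamma GLMM to habitat-change area records.

Simulates tidy per-species area records from the model itself (known
coefficients, including a negative mitigation effect), then fits the gamma
random-intercept GLMM with log(current area) offset and prints the Wald
table, mirroring the final statistical stage of the pipeline.
"""

import numpy as np
import pandas as pd

from habishift import fit_area_glmm

rng = np.random.default_rng(1)
TRUE = {"intercept": -1.7, "mitigation": -0.10, "h2": 0.35,
        "mitigation_x_h2": -0.12, "rep1": 0.06}
SHAPE, SIGMA = 1.75, 0.6

rows = []
for i in range(400):
    sp = f"sp{i:04d}"
    taxon = ["vascular_plant", "bird", "mammal"][i % 3]
    b = rng.normal(0, SIGMA)
    cur = 10 ** rng.uniform(3, 5)
    for arm in ("baseline", "mitigation"):
        for hz in ("h1", "h2"):
            for rep in ("rep0", "rep1"):
                eta = TRUE["intercept"] + b + np.log(cur)
                eta += TRUE["mitigation"] * (arm == "mitigation")
                eta += TRUE["h2"] * (hz == "h2")
                eta += TRUE["mitigation_x_h2"] * (arm == "mitigation" and hz == "h2")
                eta += TRUE["rep1"] * (rep == "rep1")
                rows.append(dict(species_id=sp, arm=arm, horizon=hz,
                                 ssp="SSP2", replicate=rep, taxon_group=taxon,
                                 lost_total=rng.gamma(SHAPE, np.exp(eta) / SHAPE),
                                 gained_total=0.0, current_area=cur))
records = pd.DataFrame(rows)

fit = fit_area_glmm(records, response="lost")
print(fit.summary().round(3).to_string())
print(f"\ngamma shape: {fit.shape:.3f} (true {SHAPE})")
print(f"random-intercept SD: {fit.re_sd:.3f} (true {SIGMA})")
# The mitigation main effect and the mitigation x later-horizon interaction
# should come out negative with tight CIs: mitigation reduces habitat loss,
# and the reduction grows at the later horizon.
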