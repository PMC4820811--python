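"""8-plex reporter-ion protein quantification on simulated PSM tables.

Simulates two labelling platforms over the same 400 proteins (15 planted
effects), runs filter -> median aggregation -> quantile normalization ->
t-test -> 3-sigma detection on each, and reconciles them by
direction-consistent concordance.
"""

import numpy as np

from omicscreen.proteome import cross_platform_concordance, run_proteome_pipeline
from omicscreen.simulate import SimConfig, simulate_psm_table

rng = np.random.default_rng(1)
idx = rng.choice(400, 15, replace=False)
effects = tuple((f"prot_{i:05d}", float(rng.choice([-1.5, 1.5]))) for i in idx)
cfg = SimConfig(seed=1, effect_table=effects)

outputs = {}
for platform in ("itraq", "tmt"):
    psms, _ = simulate_psm_table(cfg, platform, n_proteins=400)
    out = run_proteome_pipeline(psms)
    outputs[platform] = out
    rep = out["filter_report"]
    print(f"{platform}: kept {rep['n_surviving']}/{rep['n_input']} PSMs; "
          f"sigma={out['sigma'].sigma:.4f} (3-sigma = {out['sigma'].fold(3):.2f}-fold); "
          f"{len(out['hits'])} differential proteins")

concordant, discordant = cross_platform_concordance(
    outputs["itraq"]["hits"], outputs["tmt"]["hits"]
)
planted = {f for f, _ in effects}
print(f"concordant on both platforms: {len(concordant)} "
      f"({len(set(concordant) & planted)}/15 planted); discordant: {len(discordant)}")
# concordant proteins changed in the same direction under two independent
# labelling chemistries — the strongest single-omics evidence this screen gives
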