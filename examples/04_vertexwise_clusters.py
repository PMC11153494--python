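"""Vertex-wise thickness GLM with Freedman-Lane cluster FWE correction.

Smooths each specimen's thickness field along the skeleton mesh (heat
equation, T=4, missing-data aware), regresses thickness on the tau rating
with age and sex as nuisance covariates at every vertex, and assigns each
suprathreshold cluster a permutation-corrected p-value.
"""

import numpy as np

import taumap as tm
import taumap.io as tio
from taumap.vertexstats import DesignMatrix

template = tm.make_template((48, 36, 28), (0.4, 0.4, 0.4), seed=0,
                            skeleton_shape=(24, 14))
cohort = tm.simulate_cohort(template, 30, seed=7, realize_volumes=False)
fields = [sp.field for sp in cohort.specimens]
spec_df = tio.specimen_table(cohort.records)

config = tm.default_config()
config.n_permutations = 500

for variable in ("rating_tau", "rating_asyn"):
    design = DesignMatrix.from_table(spec_df, variable, ("age", "sex"),
                                     sidedness="negative")
    table, statmap, clusters = tm.vertex_model_run(
        fields, design, template, config, seed=1
    )
    sig = [c for c in clusters if c.corrected_p <= 0.05]
    print(f"\n{variable} (age, sex): {len(clusters)} candidate clusters "
          f"(uncorrected p < {config.cluster_p})")
    for c in clusters[:3]:
        print(f"  extent {c.extent:4d} vertices, corrected p = "
              f"{c.corrected_p:.3f}{'  *' if c.corrected_p <= 0.05 else ''}")
    print(f"  -> {len(sig)} significant after family-wise correction")

print("\nOnly tau drives thinning in the generator, so the tau model finds "
      "a large significant cluster while alpha-synuclein finds none.")
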