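"""Project core vs redundant samples into 2-D to inspect what pruning removed.

Runs core extraction on one center, maps raw pixel vectors to the first two
principal components, and summarizes where the core and redundant sets sit.
If pruning only removes over-represented content, the two sets should
occupy the same region of feature space rather than separate clusters.
"""

import numpy as np

from fedcmc import (
    GeneratorConfig,
    PruneConfig,
    extract_core,
    generate_federation,
    pca_projection,
)

ds = generate_federation(GeneratorConfig(seed=0))[0]
part = extract_core(ds, PruneConfig(seed=1))

ids = sorted(part.S)
X, _, _ = ds.arrays(ids)
Z = pca_projection(X.reshape(len(X), -1), out_dim=2)
pos = {s: i for i, s in enumerate(ids)}
core_Z = Z[[pos[s] for s in sorted(part.core)]]
red_Z = Z[[pos[s] for s in sorted(part.redundant)]]

for name, z in (("core", core_Z), ("redundant", red_Z)):
    print(f"{name:>9}: n={len(z):3d}  centroid=({z[:,0].mean():+.2f}, {z[:,1].mean():+.2f})  "
          f"spread=({z[:,0].std():.2f}, {z[:,1].std():.2f})")
dist = np.linalg.norm(core_Z.mean(0) - red_Z.mean(0))
pooled = np.linalg.norm(Z.std(0))
print(f"centroid separation / pooled spread: {dist / pooled:.2f}")

# Interpretation: a ratio well below 1 means the redundant set overlays the
# core set's support instead of forming its own cluster -- pruning thinned
# over-represented regions rather than carving out a distinct subpopulation.
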