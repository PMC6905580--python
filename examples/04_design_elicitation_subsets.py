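"""Choose which sites experts should view: Gower clustering and per-expert
image-subset sampling.

Sites are grouped on mixed-type habitat features (ordinal vegetation height
and density, distance to water, FPC, presence/absence) so each expert's ten
images span the range of habitat present rather than ten similar scenes.
"""

import numpy as np
import pandas as pd

import sdmfusion as sf

rng = np.random.default_rng(1)
cov = sf.generate_landscape(82, seed=1)
features = pd.DataFrame(
    {
        "veg_height": rng.integers(1, 6, 82),
        "veg_density": rng.integers(1, 5, 82),
        "dist_water": cov.dist_water,
        "fpc": cov.fpc,
        "presence": rng.integers(0, 2, 82),
    }
)

dist = sf.gower_distance(features)
labels = sf.cluster_sites(dist, n_clusters=10)  # complete linkage by default
sizes = pd.Series(labels).value_counts().sort_index()
print("Cluster sizes:", sizes.to_list())

for expert in range(1, 4):
    picks = sf.sample_image_subset(labels, seed=expert)
    print(f"Expert {expert} views sites: {sorted(cov.site_id.iloc[picks])}")
print("\nEach subset has one site per cluster, so all ten habitat types are "
      "represented in every interview.")
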