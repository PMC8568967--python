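"""Gower dissimilarity, functional dispersion and Rao Q of a community.

Builds a small mixed-type trait matrix, computes the Gower matrix and the
abundance-weighted diversity metrics of two contrasting communities.
"""

import pandas as pd

from nectarweb import TraitMatrix, fdis, gower_dissimilarity, rao_q, species_richness

traits = TraitMatrix(
    pd.DataFrame(
        {
            "corolla_height": [0.5, 0.6, 3.0, 2.5, 1.5],
            "flower_start": [110, 115, 160, 150, 130],
            "nectar_type": ["floral", "floral", "floral", "extrafloral", "none"],
            "color": ["white", "white", "purple", "yellow", "yellow"],
        },
        index=["daisy_a", "daisy_b", "tube_a", "vetch", "grass"],
    ),
    {
        "corolla_height": "quantitative",
        "flower_start": "quantitative",
        "nectar_type": "categorical",
        "color": "categorical",
    },
)
d = gower_dissimilarity(traits)
print("Gower dissimilarity (0 = identical traits, 1 = maximally different):")
print(d.round(2))

clustered = {"daisy_a": 40.0, "daisy_b": 40.0, "grass": 5.0}        # similar dominants
dispersed = {"daisy_a": 25.0, "tube_a": 25.0, "vetch": 25.0}        # spread in trait space
for name, ab in [("clustered", clustered), ("dispersed", dispersed)]:
    print(
        f"{name}: richness={species_richness(ab)} "
        f"FDis={fdis(ab, d):.3f} RaoQ={rao_q(ab, d):.3f}"
    )
# FDis is the abundance-weighted mean distance to the community centroid in
# trait space; the dispersed community scores higher on both metrics.
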