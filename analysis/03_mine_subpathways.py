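"""Mine distance-k=4 subpathways from every pathway graph and summarize
their sizes (local pathway regions where all gene pairs lie within
shortest-path distance 4)."""

import numpy as np
import pandas as pd

from mirsubnet import io as iof
from common import get_bundle, outdir


def main():
    bundle = get_bundle()
    out = outdir()
    iof.write_subpathways(bundle.subpathways, out / "subpathways.tsv")
    sizes = np.array([len(sp.genes) for sp in bundle.subpathways])
    per_pathway = pd.Series(
        [sp.pathway_id for sp in bundle.subpathways]
    ).value_counts()
    print(
        f"{len(bundle.subpathways)} subpathways from {len(bundle.pathways)} "
        f"pathways at k=4; sizes {sizes.min()}-{sizes.max()} genes "
        f"(median {int(np.median(sizes))}); "
        f"{per_pathway.min()}-{per_pathway.max()} subpathways per pathway"
    )


if __name__ == "__main__":
    main()
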