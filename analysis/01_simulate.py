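"""Generate the study-scale synthetic inputs and write every input dialect.

Emulates the study's raw material: pathway gene graphs, predicted-target
tables with predictor support, a tumor/normal expression matrix, miRNA
direction labels, and an 89-patient two-miRNA survival cohort, with two
planted 5-miRNA co-regulation groups recorded as truth.
"""

import pandas as pd

from mirsubnet import io as iof
from common import get_bundle, outdir


def main():
    bundle = get_bundle()
    out = outdir("data")
    iof.write_pathways(bundle.pathways, out / "pathways.tsv")
    iof.write_subpathways(bundle.subpathways, out / "subpathways.tsv")
    iof.write_targets(bundle.targets, out / "targets.tsv")
    iof.write_expression(bundle.expression, out / "expression.tsv")
    iof.write_directions(bundle.directions, out / "directions.tsv")
    iof.write_patients(bundle.patients, out / "patients.tsv")
    rows = [
        (m, ",".join(g["shared_subpathways"]), g["sharing"])
        for g in bundle.truth["planted_groups"]
        for m in g["members"]
    ]
    pd.DataFrame(rows, columns=["mirna", "shared_subpathways", "sharing"]).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )
    print(
        f"{len(bundle.pathways)} pathways, {len(bundle.subpathways)} mined "
        f"subpathways, {len(bundle.targets)} target predictions for "
        f"{bundle.config.n_mirnas} miRNAs "
        f"({bundle.config.n_up} up / {bundle.config.n_down} down), "
        f"{len(bundle.patients)} patients -> {out}"
    )


if __name__ == "__main__":
    main()
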