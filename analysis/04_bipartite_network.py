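"""Build the significant (P<0.05) miRNA-subpathway bipartite network and its
up/down splits; report node and edge counts and the top hub miRNAs."""

from mirsubnet import io as iof
from mirsubnet.bipartite import bipartite_degrees
from common import get_bundle, get_result, outdir


def main():
    bundle = get_bundle()
    result = get_result(bundle)
    out = outdir()
    iof.write_bipartite(result.bipartite.edges, out / "bipartite.tsv")
    iof.write_bipartite(result.bipartite_up.edges, out / "bipartite_up.tsv")
    iof.write_bipartite(result.bipartite_down.edges, out / "bipartite_down.tsv")

    degrees = bipartite_degrees(result.bipartite)
    hubs = (
        degrees[degrees["side"] == "mirna"]
        .sort_values("degree", ascending=False)
        .head(3)
    )
    hub_text = ", ".join(f"{r.node} ({r.degree})" for r in hubs.itertuples())
    for name, net in [
        ("total", result.bipartite),
        ("up", result.bipartite_up),
        ("down", result.bipartite_down),
    ]:
        print(
            f"{name:>5}: {len(net.mirnas)} miRNAs x {len(net.subpathways)} "
            f"subpathways, {len(net.edges)} significant pairs"
        )
    print(f"hub miRNAs by subpathway degree: {hub_text}")


if __name__ == "__main__":
    main()
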