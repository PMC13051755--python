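"""Co-occurrence networks per cultivar class: topology, modules, keystones.

Builds the merged bacteria+fungi Spearman network (|rho| > 0.6,
p < 0.01) within each cultivar class, detects modules, assigns Zi-Pi
topological roles and summarises keystone counts and the keystone-score
regressions against degree and betweenness.
"""

from common import pipeline_results, save


def main() -> None:
    res = pipeline_results()
    print("Co-occurrence networks (per cultivar class):")
    payload = {}
    for cls, summary in res["network"].items():
        net = res["_objects"]["networks"][cls]
        roles = net.nodes["role"].value_counts().to_dict()
        regs = net.nodes.attrs.get("keystone_regressions", {})
        print(
            f"  {cls:12s} {summary['n_nodes']} nodes, {summary['n_edges']} edges, "
            f"avg degree {summary['avg_degree']:.1f}, "
            f"keystones {summary['n_keystones']} ({roles})"
        )
        payload[cls] = {**summary, "roles": roles, "keystone_regressions": regs}
        truth = res["_objects"]["bundle"].truth
        deg = net.nodes["degree"]
        in_net = [h for h in truth.hub_ids if h in deg.index]
        if in_net:
            top = float(deg.quantile(0.9))
            share = float((deg.reindex(in_net) >= top).mean())
            print(f"    planted hubs in top degree decile: {100 * share:.0f}%")
            payload[cls]["planted_hub_top_decile_share"] = share
    save("06_network.json", payload)


if __name__ == "__main__":
    main()
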