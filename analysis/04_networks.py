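"""CC network, DMCC co-methylation network, and module mining.

CC: two circRNAs connect iff they share a differentially expressed miRNA.
DMCC: CC edges between differentially methylated host genes whose
methylation correlates with r > 0.6 and beats a 1000-permutation null.
Modules: MCODE-style dense subgraphs; members become candidate circRNAs.
"""

import pandas as pd
from _common import RESULTS, SEED, load_inputs

from methsponge import io as msio, networks


def _passed(name):
    t = pd.read_csv(RESULTS / f"screen_{name}.tsv", sep="\t")
    return set(t.loc[t["passed"], "feature"])


def main() -> None:
    inputs = load_inputs()
    hosts = msio.read_matrix(RESULTS / "methylation_hosts.tsv", "methylation",
                             inputs["groups"], resolution="gene")
    de_mirnas = _passed("de_mirna")
    dm_hosts = _passed("dm_host")

    cc = networks.build_cc_network(inputs["interactions"], de_mirnas)
    summary = networks.degree_summary(cc)
    networks.write_network(cc, RESULTS / "cc_network.tsv")
    print(f"CC network: {cc.number_of_nodes()} circRNAs, "
          f"{cc.number_of_edges()} edges, max degree {summary['max_degree']}, "
          f"degree-survival tail slope {summary['tail_slope']:.2f}")

    dmcc = networks.build_dmcc_network(
        cc, hosts, dm_hosts, inputs["circ_annotation"].host_of(),
        r_min=0.6, n_perm=1000, alpha=0.05, rng_seed=SEED)
    networks.write_network(dmcc, RESULTS / "dmcc_network.tsv")
    print(f"DMCC network: {dmcc.number_of_nodes()} circRNAs, "
          f"{dmcc.number_of_edges()} co-methylation edges")

    modules = networks.mine_modules(dmcc)
    networks.write_modules(modules, RESULTS / "modules.tsv")
    for i, m in enumerate(modules, 1):
        print(f"module {i}: {len(m.members)} members, score {m.score:.2f}, "
              f"seed {m.seed}")
    print(f"candidate circRNAs: {len(networks.candidate_circrnas(modules))}")


if __name__ == "__main__":
    main()
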