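"""Driver-gene selection and the circRNA-miRNA-driver (CMD) network.

Drivers = differentially expressed genes intersected with the curated
driver list; candidate pairs = (module circRNA, driver) connected through
at least one differentially expressed miRNA.
"""

import pandas as pd
from _common import RESULTS, load_inputs

from methsponge import cmd_network


def main() -> None:
    inputs = load_inputs()
    de_gene = pd.read_csv(RESULTS / "screen_de_gene.tsv", sep="\t")
    de_genes = set(de_gene.loc[de_gene["passed"], "feature"])
    de_mirna = pd.read_csv(RESULTS / "screen_de_mirna.tsv", sep="\t")
    de_mirnas = set(de_mirna.loc[de_mirna["passed"], "feature"])
    modules = pd.read_csv(RESULTS / "modules.tsv", sep="\t")
    candidates = set(modules["member"])

    drivers = cmd_network.select_driver_genes(de_genes, inputs["driver_list"])
    print(f"drivers: {len(de_genes)} DE genes ∩ {len(inputs['driver_list'])} "
          f"curated -> {len(drivers)}")
    pairs, edges = cmd_network.build_cmd_network(
        candidates, drivers, inputs["interactions"], de_mirnas)
    cmd_network.write_candidate_pairs(pairs, RESULTS / "candidate_pairs.tsv")
    edges.to_csv(RESULTS / "cmd_network.tsv", sep="\t", index=False)
    universe = cmd_network.cmd_mirna_universe(pairs, edges)
    print(f"CMD network: {len(candidates)} candidate circRNAs, "
          f"{len(drivers)} drivers, {len(universe)} miRNAs")
    print(f"candidate circRNA-driver pairs: {len(pairs)}")


if __name__ == "__main__":
    main()
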