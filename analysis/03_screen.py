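"""Differential screening between tumor and normal samples.

SAM-style moderated t with permutation q-values.  Expression gates:
fold change > 2 or < 0.5 with q <= 0.01; methylation gates: fold change
> 1.5 or < 2/3 with q <= 0.05.
"""

from _common import RESULTS, SEED, load_inputs

from methsponge import differential, io as msio


def main() -> None:
    inputs = load_inputs()
    hosts = msio.read_matrix(RESULTS / "methylation_hosts.tsv", "methylation",
                             inputs["groups"], resolution="gene")
    runs = [
        ("de_mirna", inputs["mirna_expr"], differential.EXPRESSION_GATES),
        ("de_gene", inputs["gene_expr"], differential.EXPRESSION_GATES),
        ("dm_host", hosts, differential.METHYLATION_GATES),
    ]
    for i, (name, mat, gates) in enumerate(runs):
        res = differential.differential_screen(
            mat, n_perm=200, rng_seed=SEED + i, **gates)
        res.table.to_csv(RESULTS / f"screen_{name}.tsv", sep="\t",
                         index_label="feature")
        print(f"{name}: {len(res.passed_ids)}/{len(res.table)} features passed")


if __name__ == "__main__":
    main()
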