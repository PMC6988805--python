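"""Filter 450K-style probes and aggregate methylation.

Drops probes with missing values, multi-gene annotation, sex-chromosome
location or SNP overlap; averages surviving probes per circRNA host gene
and over each driver gene's promoter window (TSS-1500 .. TSS+500,
strand-aware).
"""

from _common import RESULTS, load_inputs

from methsponge import io as msio, preprocess


def main() -> None:
    inputs = load_inputs()
    probes = inputs["meth_probes"]
    ann = inputs["probe_annotation"]
    clean = preprocess.filter_probes(probes, ann)
    print(f"probe filter: {len(probes.values)} -> {len(clean.values)} probes")
    hosts = preprocess.aggregate_gene_methylation(
        clean, ann, inputs["circ_annotation"])
    promoters = preprocess.promoter_methylation(
        clean, ann, inputs["gene_annotation"])
    msio.write_matrix(hosts, RESULTS / "methylation_hosts.tsv")
    msio.write_matrix(promoters, RESULTS / "methylation_promoters.tsv")
    print(f"host-gene methylation: {hosts.values.shape[0]} genes")
    print(f"promoter methylation: {promoters.values.shape[0]} driver genes")


if __name__ == "__main__":
    main()
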