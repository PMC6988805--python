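"""Shared paths and loaders for the numbered analysis scripts.

Each script reads only files written by earlier scripts (or the simulated
inputs from 01) out of ``results/analysis/`` and writes its own tables
back there, so the sequence can be re-run stage by stage.
"""

from pathlib import Path

from methsponge import io as msio

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"
DATA = RESULTS / "data"

SEED = 20240901  # one global seed for the whole analysis


def load_inputs():
    groups = msio.read_groups(DATA / "groups.tsv")
    return {
        "groups": groups,
        "mirna_expr": msio.read_matrix(DATA / "mirna_expression.tsv",
                                       "expression", groups),
        "gene_expr": msio.read_matrix(DATA / "gene_expression.tsv",
                                      "expression", groups),
        "meth_probes": msio.read_matrix(DATA / "methylation_probes.tsv",
                                        "methylation", groups, "probe"),
        "probe_annotation": msio.read_probe_annotation(DATA / "probe_annotation.tsv"),
        "circ_annotation": msio.read_bed_like(DATA / "circ_annotation.bed"),
        "gene_annotation": msio.read_gene_annotation(DATA / "gene_annotation.tsv"),
        "interactions": msio.read_interactions(DATA / "circ_mirna.tsv",
                                               DATA / "mirna_gene.tsv"),
        "driver_list": msio.read_driver_list(DATA / "driver_genes.txt"),
        "clinical": msio.read_clinical(DATA / "clinical.tsv"),
    }
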