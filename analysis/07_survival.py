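"""Prognostic-index survival stratification of the tumor cohort.

Joint Cox fit on the predicted sponge circRNAs' host-gene methylation;
PI = sum beta_i x_i per patient; median split into high/low risk and a
log-rank comparison with Kaplan-Meier curves.
"""

import pandas as pd
from _common import RESULTS, load_inputs

from methsponge import io as msio, survival as surv
from methsponge.types import MethylationProfile


def main() -> None:
    inputs = load_inputs()
    clinical = inputs["clinical"]
    hosts = msio.read_matrix(RESULTS / "methylation_hosts.tsv", "methylation",
                             inputs["groups"], resolution="gene")
    predicted = pd.read_csv(RESULTS / "predicted_pairs.tsv", sep="\t")
    host_of = inputs["circ_annotation"].host_of()
    covariates = sorted({host_of[c] for c in predicted["circ_id"].unique()})
    print(f"covariates (sponge circRNA host genes): {covariates}")

    tumor_cols = [c for c in hosts.values.columns if c in clinical.table.index]
    cov_meth = MethylationProfile(
        hosts.values.loc[covariates, tumor_cols], "gene").validate()
    model = surv.fit_cox(cov_meth, clinical, covariates)
    print("Cox coefficients:")
    for g, b in model.beta.items():
        print(f"  {g}: {b:+.3f}")

    assign = surv.prognostic_index(model, cov_meth)
    surv.write_risk_table(assign, RESULTS / "risk_groups.tsv")
    result = surv.stratify_and_test(assign, clinical)
    km = pd.concat([result["km"][g].assign(group=g) for g in ("high", "low")])
    km.to_csv(RESULTS / "km_curves.tsv", sep="\t", index=False)
    print(f"median-PI split: {result['n_high']} high risk, "
          f"{result['n_low']} low risk")
    print(f"log-rank statistic {result['statistic']:.2f}, "
          f"p = {result['p_value']:.4g}")


if __name__ == "__main__":
    main()
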