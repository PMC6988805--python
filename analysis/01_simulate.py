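"""Generate the synthetic tumor/normal multi-omics study.

60 tumor / 30 normal samples; 5 planted sponge circRNA-driver pairs inside
2 co-methylated host-gene modules, 64 decoy pairs capped at 3 shared target
sites, and survival times driven by the sponge hosts' methylation.
"""

from _common import DATA, SEED

from methsponge.synthetic_data import SimulationConfig, simulate_all, write_dataset


def main() -> None:
    cfg = SimulationConfig(rng_seed=SEED)
    data = simulate_all(cfg)
    paths = write_dataset(data, DATA)
    truth = data.truth
    print(f"wrote {len(paths)} input files to {DATA}")
    print(f"planted DE miRNAs: {len(truth.true_de_mirnas)}")
    print(f"planted modules: {[sorted(m)[:3] for m in truth.true_modules]} ...")
    print(f"planted sponge pairs: {truth.true_sponge_pairs}")
    print(f"decoy pairs: {len(truth.true_decoy_pairs)}")


if __name__ == "__main__":
    main()
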