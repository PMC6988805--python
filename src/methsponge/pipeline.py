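"""End-to-end pipeline: simulate -> preprocess -> screen -> networks ->
CMD -> sponge prediction -> survival, driven by one YAML config.

Every stage reads files written by earlier stages (no hidden state) and
appends a manifest record with parameter values and SHA-256 hashes of its
inputs and outputs, so identical config + seed reproduces identical
hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cmd_network, differential, io as msio, networks, preprocess
from . import sponge_predict, survival as surv
from . import synthetic_data
from .types import MethylationProfile, SimulationConfig, ValidationError

log = logging.getLogger(__name__)

STAGES = (
    "simulate", "preprocess", "screen", "cc-net", "dmcc-net",
    "modules", "cmd-net", "predict", "survival",
)


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and the cause."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence((seed, STAGES.index(stage)))
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise ValidationError("config must set a global 'seed'")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValidationError("config needs a 'simulate' block or an 'inputs' map")
    return cfg


def default_config(seed: int = 0, **simulate_overrides) -> dict:
    """The default synthetic-study config (all stage parameters explicit)."""
    return {
        "seed": seed,
        "simulate": dict(simulate_overrides),
        "screen": {
            "expression": dict(differential.EXPRESSION_GATES, n_perm=200),
            "methylation": dict(differential.METHYLATION_GATES, n_perm=200),
        },
        "dmcc": {"r_min": 0.6, "n_perm": 1000, "alpha": 0.05},
        "mcode": {"degree_cutoff": 2, "node_score_cutoff": 0.2,
                  "k_core": 2, "haircut": True},
        "cmd": {"de_mirnas_only": True},
        "predict": {"p1_max": 0.05, "p2_max": 0.05, "perm_alpha": 0.05,
                    "min_sites": 8, "meth_expr_alpha": 0.05,
                    "n_perm": 1000, "min_shared_samples": 10},
    }


def run_all(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute every stage; returns the manifest (also written as JSON).

    ``config`` is a dict or a YAML path.  Partial outputs are retained on
    failure; the raised :class:`PipelineError` names the failing stage.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: list[dict] = []
    t_start = time.time()

    def record(stage, params, inputs, outputs):
        manifest.append({
            "stage": stage,
            "params": params,
            "inputs": {k: _sha256(Path(v)) for k, v in inputs.items()},
            "outputs": {k: _sha256(Path(v)) for k, v in outputs.items()},
        })
        log.info("stage %s done (%.1fs elapsed)", stage, time.time() - t_start)

    def fail(stage, exc):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: simulate / pre-flight ----------------------------------
    if "simulate" in config:
        try:
            sim_kwargs = dict(config.get("simulate") or {})
            if "survival_beta" in sim_kwargs:
                sim_kwargs["survival_beta"] = tuple(sim_kwargs["survival_beta"])
            sim_cfg = SimulationConfig(rng_seed=seed, **sim_kwargs)
            data = synthetic_data.simulate_all(sim_cfg)
            files = synthetic_data.write_dataset(data, out / "data")
        except Exception as exc:
            fail("simulate", exc)
        record("simulate", {"rng_seed": seed, **sim_kwargs}, {}, files)
    else:
        files = {k: Path(v) for k, v in config["inputs"].items()}
        missing = [k for k, v in files.items() if not Path(v).exists()]
        if missing:
            raise PipelineError(
                f"stage 'pre-flight' failed: missing input files: {missing}"
            )

    # ---- load -----------------------------------------------------------
    groups = msio.read_groups(files["groups"])
    mirna_expr = msio.read_matrix(files["mirna_expr"], "expression", groups)
    gene_expr = msio.read_matrix(files["gene_expr"], "expression", groups)
    probes = msio.read_matrix(files["meth_probes"], "methylation", groups, "probe")
    probe_ann = msio.read_probe_annotation(files["probe_annotation"])
    circ_ann = msio.read_bed_like(files["circ_annotation"])
    gene_ann = msio.read_gene_annotation(files["gene_annotation"])
    interactions = msio.read_interactions(files["circ_mirna"], files["mirna_gene"])
    driver_list = msio.read_driver_list(files["driver_list"])
    clinical = msio.read_clinical(files["clinical"])
    host_of = circ_ann.host_of()

    # ---- stage: preprocess ----------------------------------------------
    try:
        clean = preprocess.filter_probes(probes, probe_ann)
        host_meth = preprocess.aggregate_gene_methylation(clean, probe_ann, circ_ann)
        promoter_meth = preprocess.promoter_methylation(clean, probe_ann, gene_ann)
        host_path = out / "methylation_hosts.tsv"
        prom_path = out / "methylation_promoters.tsv"
        msio.write_matrix(host_meth, host_path)
        msio.write_matrix(promoter_meth, prom_path)
    except Exception as exc:
        fail("preprocess", exc)
    record(
        "preprocess", {},
        {"meth_probes": files["meth_probes"],
         "probe_annotation": files["probe_annotation"]},
        {"hosts": host_path, "promoters": prom_path},
    )

    # ---- stage: screen ---------------------------------------------------
    scr_cfg = config.get("screen", {})
    expr_gates = dict(differential.EXPRESSION_GATES, n_perm=200)
    expr_gates.update(scr_cfg.get("expression", {}))
    meth_gates = dict(differential.METHYLATION_GATES, n_perm=200)
    meth_gates.update(scr_cfg.get("methylation", {}))
    s_seed = _stage_seed(seed, "screen")
    try:
        de_mirna = differential.differential_screen(
            mirna_expr, rng_seed=s_seed, **expr_gates)
        de_gene = differential.differential_screen(
            gene_expr, rng_seed=s_seed + 1, **expr_gates)
        dm_host = differential.differential_screen(
            host_meth, rng_seed=s_seed + 2, **meth_gates)
        screen_paths = {}
        for name, res in [("de_mirna", de_mirna), ("de_gene", de_gene),
                          ("dm_host", dm_host)]:
            p = out / f"screen_{name}.tsv"
            res.table.to_csv(p, sep="\t", index_label="feature",
                             float_format="%.17g")
            screen_paths[name] = p
    except Exception as exc:
        fail("screen", exc)
    record("screen", {"expression": expr_gates, "methylation": meth_gates,
                      "seed": s_seed},
           {"mirna_expr": files["mirna_expr"], "gene_expr": files["gene_expr"],
            "hosts": host_path},
           screen_paths)

    # ---- stage: cc-net ---------------------------------------------------
    try:
        cc = networks.build_cc_network(interactions, de_mirna.passed_ids)
        cc_path = out / "cc_network.tsv"
        networks.write_network(cc, cc_path)
    except Exception as exc:
        fail("cc-net", exc)
    record("cc-net", {"n_de_mirnas": len(de_mirna.passed_ids)},
           {"circ_mirna": files["circ_mirna"], "de_mirna": screen_paths["de_mirna"]},
           {"cc": cc_path})

    # ---- stage: dmcc-net -------------------------------------------------
    dmcc_cfg = dict({"r_min": 0.6, "n_perm": 1000, "alpha": 0.05},
                    **config.get("dmcc", {}))
    d_seed = _stage_seed(seed, "dmcc-net")
    try:
        dmcc = networks.build_dmcc_network(
            cc, host_meth, dm_host.passed_ids, host_of,
            rng_seed=d_seed, **dmcc_cfg)
        dmcc_path = out / "dmcc_network.tsv"
        networks.write_network(dmcc, dmcc_path)
    except Exception as exc:
        fail("dmcc-net", exc)
    record("dmcc-net", {**dmcc_cfg, "seed": d_seed},
           {"cc": cc_path, "hosts": host_path, "dm_host": screen_paths["dm_host"]},
           {"dmcc": dmcc_path})

    # ---- stage: modules --------------------------------------------------
    mcode_cfg = dict({"degree_cutoff": 2, "node_score_cutoff": 0.2,
                      "k_core": 2, "haircut": True},
                     **config.get("mcode", {}))
    try:
        modules = networks.mine_modules(dmcc, **mcode_cfg)
        mod_path = out / "modules.tsv"
        networks.write_modules(modules, mod_path)
    except Exception as exc:
        fail("modules", exc)
    record("modules", mcode_cfg, {"dmcc": dmcc_path}, {"modules": mod_path})
    candidates_set = networks.candidate_circrnas(modules)

    # ---- stage: cmd-net --------------------------------------------------
    de_only = config.get("cmd", {}).get("de_mirnas_only", True)
    try:
        drivers = cmd_network.select_driver_genes(de_gene.passed_ids, driver_list)
        pairs, tri_edges = cmd_network.build_cmd_network(
            candidates_set, drivers, interactions,
            de_mirna.passed_ids if de_only else None)
        pairs_path = out / "candidate_pairs.tsv"
        tri_path = out / "cmd_network.tsv"
        cmd_network.write_candidate_pairs(pairs, pairs_path)
        tri_edges.to_csv(tri_path, sep="\t", index=False)
    except Exception as exc:
        fail("cmd-net", exc)
    record("cmd-net", {"de_mirnas_only": de_only, "n_drivers": len(drivers)},
           {"modules": mod_path, "de_gene": screen_paths["de_gene"]},
           {"pairs": pairs_path, "cmd": tri_path})

    # ---- stage: predict --------------------------------------------------
    pred_kwargs = dict(config.get("predict", {}))
    p_seed = _stage_seed(seed, "predict")
    try:
        pred_cfg = sponge_predict.PredictionConfig(rng_seed=p_seed, **pred_kwargs)
        universe = cmd_network.cmd_mirna_universe(pairs, tri_edges)
        predicted, scores = sponge_predict.predict_sponge_pairs(
            pairs, host_meth, promoter_meth, gene_expr, interactions,
            host_of, universe, candidates_set, drivers, pred_cfg)
        pred_path = out / "predicted_pairs.tsv"
        score_path = out / "pair_scores.tsv"
        predicted.to_csv(pred_path, sep="\t", index=False, float_format="%.17g")
        scores.to_csv(score_path, sep="\t", index=False, float_format="%.17g")
    except Exception as exc:
        fail("predict", exc)
    record("predict", {**pred_kwargs, "seed": p_seed},
           {"pairs": pairs_path, "hosts": host_path, "promoters": prom_path,
            "gene_expr": files["gene_expr"]},
           {"predicted": pred_path, "scores": score_path})

    # ---- stage: survival -------------------------------------------------
    try:
        sponge_hosts = sorted(
            {host_of[c] for c in predicted["circ_id"].unique()
             if host_of.get(c) in host_meth.values.index}
        )
        surv_out = {}
        surv_params = {"covariates": sponge_hosts}
        if sponge_hosts:
            tumor_cols = [c for c in host_meth.values.columns
                          if c in clinical.table.index]
            cov_meth = MethylationProfile(
                host_meth.values.loc[sponge_hosts, tumor_cols], "gene"
            ).validate()
            model = surv.fit_cox(cov_meth, clinical, sponge_hosts)
            assign = surv.prognostic_index(model, cov_meth)
            result = surv.stratify_and_test(assign, clinical)
            risk_path = out / "risk_groups.tsv"
            surv.write_risk_table(assign, risk_path)
            km_path = out / "km_curves.tsv"
            km = pd.concat(
                [result["km"][g].assign(group=g) for g in ("high", "low")]
            )
            km.to_csv(km_path, sep="\t", index=False, float_format="%.17g")
            summary_path = out / "survival_summary.json"
            with open(summary_path, "w", encoding="utf-8") as fh:
                json.dump({
                    "logrank_statistic": result["statistic"],
                    "logrank_p": result["p_value"],
                    "n_high": result["n_high"], "n_low": result["n_low"],
                    "beta": {k: float(v) for k, v in model.beta.items()},
                }, fh, indent=2, sort_keys=True)
            surv_out = {"risk": risk_path, "km": km_path, "summary": summary_path}
        else:
            log.warning("survival stage skipped: no predicted sponge pairs")
    except Exception as exc:
        fail("survival", exc)
    record("survival", surv_params,
           {"predicted": pred_path, "hosts": host_path,
            "clinical": files["clinical"]},
           surv_out)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return {"manifest": manifest, "manifest_path": manifest_path, "out_dir": out}
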