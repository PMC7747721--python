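"""End-to-end pipeline: simulate -> harmonize -> DMP -> DMR -> replicate
-> SNP QC -> blocks -> mQTL, with every intermediate table written out.

The configuration is a plain nested dict (loadable from YAML); every
output table starts with a ``# config_hash=...`` comment so a result
file can always be traced to the exact configuration that produced it.
Two runs with the same configuration (the seed lives inside it) produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os

import pandas as pd
import yaml

from ewaskit import dmp, dmr, genetics, harmonization, mqtl, replication, synthetic


def default_config(seed: int = 0, outdir: str = "ewaskit_run") -> dict:
    """A complete synthetic-study configuration with planted signal."""
    return {
        "seed": seed,
        "outdir": outdir,
        "simulate": {
            "n_probes": 2000,
            "discovery": {"n_case": 23, "n_control": 16},
            "validation": {"n_case": 12, "n_control": 12},
            "noise_sd": 0.55,
            "batch_shift": 0.4,
            "planted_dmrs": [
                {
                    "gene": "HTR2A",
                    "chrom": "13",
                    "start_pos": 47_472_138,
                    "n_cpgs": 5,
                    "spacing_bp": 55,
                    "delta": -0.15,
                    "feature": "TSS1500",
                },
                {
                    "gene": "MDGA1",
                    "chrom": "6",
                    "start_pos": 37_616_410,
                    "n_cpgs": 4,
                    "spacing_bp": 500,
                    "delta": 0.15,
                    "feature": "Body",
                },
            ],
            "mqtl": {
                "snp_id": "rs_focal",
                "risk_allele": "C",
                "other_allele": "T",
                "maf_case": 0.40,
                "maf_control": 0.13,
                "carrier_methylation_shift": -0.10,
            },
        },
        "dmp": {"p_max": 0.05, "delta_min": 0.10},
        "dmr": {"max_gap": 1500, "min_cpgs": 2, "mode": "gene"},
        "region_scan": {"delta_min": 0.05, "p_max": 0.005, "direction": "hypo"},
        "snp_qc": {
            "sample_callrate_min": 0.95,
            "callrate_min": 0.98,
            "maf_min": 0.05,
            "hwe_p_min": 1e-5,
        },
    }


def validate_config(config: dict) -> None:
    d = config.get("dmp", {})
    if not 0 < d.get("p_max", 0.05) <= 1:
        raise ValueError(f"dmp.p_max must be in (0, 1], got {d.get('p_max')}")
    if not 0 <= d.get("delta_min", 0.1) <= 0.5:
        raise ValueError("dmp.delta_min must be in [0, 0.5]")
    r = config.get("dmr", {})
    if r.get("min_cpgs", 2) < 2:
        raise ValueError("dmr.min_cpgs must be >= 2")
    if r.get("max_gap", 1500) < 2:
        raise ValueError("dmr.max_gap must be >= 2 bp")
    if r.get("mode", "gene") not in ("gene", "strict-distance"):
        raise ValueError("dmr.mode must be 'gene' or 'strict-distance'")
    q = config.get("snp_qc", {})
    for key in ("sample_callrate_min", "callrate_min", "maf_min"):
        v = q.get(key, 0.5)
        if not 0 <= v <= 1:
            raise ValueError(f"snp_qc.{key} must be in [0, 1]")
    if "seed" not in config:
        raise ValueError("config requires an explicit seed")


def config_hash(config: dict) -> str:
    # the output location is not a parameter: two runs of the same analysis
    # into different directories must hash (and compare) identically
    params = {k: v for k, v in config.items() if k != "outdir"}
    canon = yaml.safe_dump(params, sort_keys=True)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str, chash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _planted_designs(config: dict):
    sim = config["simulate"]
    seed = config["seed"]
    dmrs = tuple(
        synthetic.PlantedDMR(
            gene=d["gene"],
            chrom=str(d["chrom"]),
            start_pos=d["start_pos"],
            n_cpgs=d["n_cpgs"],
            spacing_bp=d["spacing_bp"],
            delta=d["delta"],
            feature=d.get("feature", "TSS1500"),
        )
        for d in sim["planted_dmrs"]
    )
    disc = synthetic.CohortDesign(
        n_case=sim["discovery"]["n_case"],
        n_control=sim["discovery"]["n_control"],
        n_probes=sim["n_probes"],
        cohort="discovery",
        planted_dmrs=dmrs,
        batch_shift=sim.get("batch_shift", 0.0),
        noise_sd=sim.get("noise_sd", 0.55),
        seed=seed,
    )
    valid = synthetic.CohortDesign(
        n_case=sim["validation"]["n_case"],
        n_control=sim["validation"]["n_control"],
        n_probes=sim["n_probes"],
        cohort="validation",
        planted_dmrs=dmrs,
        batch_shift=sim.get("batch_shift", 0.0),
        noise_sd=sim.get("noise_sd", 0.55),
        seed=seed + 1000,
    )
    return disc, valid


def run_pipeline(config: dict) -> dict:
    """Execute every stage on a simulated study; returns the run report."""
    validate_config(config)
    chash = config_hash(config)
    outdir = config["outdir"]
    os.makedirs(outdir, exist_ok=True)
    log: list[dict] = []

    def stage(name: str, **counts) -> None:
        log.append({"stage": name, **counts})

    # --- simulate ---------------------------------------------------------
    disc_design, valid_design = _planted_designs(config)
    manifest = synthetic.generate_manifest(valid_design)
    manifest.loc[manifest["planted"], "on_450k"] = True
    manifest_450k = manifest[manifest["on_450k"]]

    beta_d, sheet_d = synthetic.generate_cohort(manifest_450k, disc_design)
    beta_v, sheet_v = synthetic.generate_cohort(manifest, valid_design)
    stage("simulate", discovery_probes=len(beta_d), validation_probes=len(beta_v),
          discovery_samples=beta_d.shape[1], validation_samples=beta_v.shape[1])

    # --- harmonize --------------------------------------------------------
    beta_d, report_d = harmonization.filter_probes(
        beta_d, manifest=manifest_450k.drop(columns=["planted"])
    )
    beta_v, report_v = harmonization.filter_probes(
        beta_v, manifest=manifest.drop(columns=["planted"])
    )
    beta_d, beta_v = harmonization.intersect_cohorts(beta_d, beta_v)
    sheet = pd.concat([sheet_d, sheet_v])
    combined = pd.concat([beta_d, beta_v], axis=1)
    screen_before = harmonization.svd_batch_screen(combined, sheet)
    adjusted = harmonization.combat_adjust(combined, sheet, batch_key="batch")
    screen_after = harmonization.svd_batch_screen(adjusted, sheet)
    stage(
        "harmonize",
        common_probes=len(combined),
        batch_p_before=screen_before.min_p("batch"),
        batch_p_after=screen_after.min_p("batch"),
    )

    # --- per-cohort DMP/DMR ----------------------------------------------
    p_max = config["dmp"]["p_max"]
    delta_min = config["dmp"]["delta_min"]
    dmr_cfg = config["dmr"]
    results = {}
    for name, cohort_sheet in (("discovery", sheet_d), ("validation", sheet_v)):
        cohort_beta = adjusted[cohort_sheet.index]
        records = dmp.dmp_table(cohort_beta, cohort_sheet, manifest)
        selected = dmp.select_dmps(records, p_max=p_max, delta_min=delta_min)
        regions = dmr.call_dmrs(
            selected,
            max_gap=dmr_cfg["max_gap"],
            min_cpgs=dmr_cfg["min_cpgs"],
            mode=dmr_cfg["mode"],
        )
        results[name] = {"records": records, "selected": selected, "dmrs": regions}
        write_table(
            dmp.records_to_frame(selected), os.path.join(outdir, f"dmps_{name}.tsv"), chash
        )
        write_table(
            dmr.dmr_frame(regions), os.path.join(outdir, f"dmrs_{name}.tsv"), chash,
            index=False,
        )
        stage(f"dmp_{name}", n_tested=len(records), n_selected=len(selected),
              n_dmrs=len(regions))

    # --- replication ------------------------------------------------------
    dmp_rep = replication.intersect_dmps(
        results["discovery"]["selected"], results["validation"]["selected"]
    )
    dmr_rep = replication.intersect_dmrs(
        results["discovery"]["dmrs"], results["validation"]["dmrs"]
    )
    replicated_genes = [a.region_key for a, _ in dmr_rep]
    stage("replicate", n_common_dmps=dmp_rep["n_common"],
          n_consistent=dmp_rep["n_consistent"], replicated_dmrs=replicated_genes)

    scan_cfg = config["region_scan"]
    scan_gene = config["simulate"]["planted_dmrs"][0]["gene"]
    scan = replication.combined_region_scan(
        adjusted, sheet, manifest, scan_gene,
        delta_min=scan_cfg["delta_min"], p_max=scan_cfg["p_max"],
        direction=scan_cfg["direction"],
    )
    stage("region_scan", gene=scan_gene, n_kept=scan["n_kept"], span_bp=scan["span_bp"])

    # --- genetics + mQTL --------------------------------------------------
    mq = config["simulate"]["mqtl"]
    planted0 = config["simulate"]["planted_dmrs"][0]
    tagged = manifest.index[
        (manifest["chrom"] == str(planted0["chrom"]))
        & (manifest["pos"] == planted0["start_pos"])
    ][0]
    design = synthetic.MQTLDesign(
        snp_id=mq["snp_id"],
        risk_allele=mq["risk_allele"],
        other_allele=mq["other_allele"],
        maf_case=mq["maf_case"],
        maf_control=mq["maf_control"],
        carrier_methylation_shift=mq["carrier_methylation_shift"],
        tagged_cpg=tagged,
        seed=config["seed"],
    )
    geno, beta_mqtl = synthetic.generate_genotypes(design, sheet, adjusted)
    qc_cfg = config["snp_qc"]
    geno, sample_report = genetics.snp_sample_qc(
        geno, sample_callrate_min=qc_cfg["sample_callrate_min"]
    )
    geno, snp_report = genetics.snp_variant_qc(
        geno, sheet, callrate_min=qc_cfg["callrate_min"],
        maf_min=qc_cfg["maf_min"], hwe_p_min=qc_cfg["hwe_p_min"],
    )
    write_table(snp_report, os.path.join(outdir, "snp_qc.tsv"), chash)
    blocks = genetics.gabriel_blocks(geno)
    assoc = genetics.allele_assoc(geno, sheet, design.snp_id)
    stage("snp_qc", n_snps_kept=int(snp_report["kept"].sum()),
          n_blocks=len(blocks), allele_or=assoc.odds_ratio,
          carrier_or=assoc.carrier_odds_ratio, fisher_p=assoc.fisher_p)

    carriers = mqtl.carrier_coding(geno, design.snp_id, design.risk_allele)
    by_carrier = mqtl.methylation_by_genotype(beta_mqtl, tagged, carriers)
    fit = mqtl.joint_logistic(
        sheet.loc[geno.sample_ids], carriers, beta_mqtl.loc[tagged, geno.sample_ids]
    )
    stage("mqtl", tagged_cpg=tagged, carrier_anova_p=by_carrier.anova_p,
          cpg_wald_p=float(fit.wald_p["cpg"]), snp_wald_p=float(fit.wald_p["snp"]),
          separation=fit.separation)

    report = {
        "config_hash": chash,
        "stages": log,
        "replicated_dmrs": replicated_genes,
        "mqtl_significant": by_carrier.anova_p < 0.05,
    }
    with open(os.path.join(outdir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
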