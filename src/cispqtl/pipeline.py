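"""End-to-end orchestration of the synthetic cis-pQTL study.

``run_pipeline`` executes simulate → preprocess → fine-map → replicate →
colocalize → annotate on a synthetic cohort, writing plain-text outputs
and a provenance manifest to the output directory. All randomness
descends from the single root seed, so identical configurations produce
byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from cispqtl import io
from cispqtl.annotate import (
    catalog_overlap,
    exwas_convergence,
    feature_enrichment,
    filter_catalog,
)
from cispqtl.assoc import marginal_scan, replicate_leads
from cispqtl.coloc import coloc_screen
from cispqtl.containers import RunManifest
from cispqtl.finemap import (
    joint_lead_test,
    select_L_grid,
    sex_interaction_test,
    variance_explained,
)
from cispqtl.preprocess import genotype_pcs, prepare_trait
from cispqtl.simulate import (
    SimTruth,
    simulate_catalog_and_burden,
    simulate_covariates,
    simulate_genotypes,
    simulate_protein_trait,
    simulate_trait_pair,
)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "pipeline_out",
    "genotypes": {"n": 600, "m": 200, "maf_range": [0.05, 0.5], "rho": 0.8, "block_size": 20},
    "proteins": [
        {"name": "PROT1", "n_causal": 1, "h2": 0.25},
        {"name": "PROT2", "n_causal": 2, "h2": 0.20},
        {"name": "PROT3", "n_causal": 0, "h2": 0.0},
    ],
    "preprocess": {"pcs_k": 4, "rint_offset": 0.5},
    "finemap": {"grid": [2, 10], "cs_ld_threshold": 0.1, "coverage": 0.95, "min_purity": 0.5},
    "replication": {"n": 600, "alpha": 0.05},
    "coloc": {
        "n": 1500, "m": 600, "mode": "shared", "h2_a": 0.05, "h2_b": 0.05,
        "p12": 1e-6, "min_overlap": 500, "pp_threshold": 0.8,
    },
    "write_ld": False,
    "include_timestamps": True,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _spaced_causals(rng: np.random.Generator, m: int, k: int, min_gap: int = 40) -> list[int]:
    """Pick k causal columns at least ``min_gap`` apart (distinct LD blocks)."""
    for _ in range(200):
        cand = sorted(rng.choice(m, size=k, replace=False))
        if all(b - a >= min_gap for a, b in zip(cand, cand[1:])):
            return [int(j) for j in cand]
    raise ValueError(f"cannot place {k} causals {min_gap} apart among {m} variants")


def _simulate_cohort(cfg, seeds, manifest, label, variants=None):
    g = cfg["genotypes"]
    G = simulate_genotypes(
        n=g["n"], m=g["m"], maf_range=tuple(g["maf_range"]), rho=g["rho"],
        block_size=g["block_size"], seed=int(seeds[f"genotypes_{label}"]),
        variants=variants,
    )
    cov = simulate_covariates(G.n, sex=G.sex, seed=int(seeds[f"covariates_{label}"]))
    manifest.add_count(f"simulate_{label}", "samples", G.n)
    manifest.add_count(f"simulate_{label}", "variants", G.m)
    return G, cov


def run_pipeline(config: dict | str | Path | None = None) -> Path:
    """Run the full synthetic study; returns the output directory."""
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)
    t0 = time.time()

    root = np.random.SeedSequence(int(cfg["seed"]))
    stream = root.generate_state(32) % (2**31)
    seed_names = [
        "genotypes_disc", "covariates_disc", "genotypes_rep", "covariates_rep",
        "truth", "traits_disc", "traits_rep", "coloc_geno", "coloc_pair",
        "catalog", "features",
    ]
    seeds = {name: int(stream[i]) for i, name in enumerate(seed_names)}
    manifest.seeds = {"root": int(cfg["seed"]), **seeds}

    # --- simulate discovery and replication cohorts ------------------------
    G, cov = _simulate_cohort(cfg, seeds, manifest, "disc")
    G_rep, cov_rep = _simulate_cohort(cfg, seeds, manifest, "rep", variants=G.variants)
    truth_rng = np.random.default_rng(seeds["truth"])

    proteins = cfg["proteins"]
    truths: dict[str, SimTruth] = {}
    raw_traits, raw_traits_rep = {}, {}
    trait_rng = np.random.default_rng(seeds["traits_disc"])
    trait_rng_rep = np.random.default_rng(seeds["traits_rep"])
    for prot in proteins:
        name, k, h2 = prot["name"], prot["n_causal"], prot["h2"]
        idx = _spaced_causals(truth_rng, G.m, k) if k else []
        truths[name] = SimTruth(
            causal_indices={name: idx},
            effect_sizes={name: [1.0] * k},
            h2={name: h2},
            covariate_effects={name: {"age": 0.01, "sex": 0.2, "plate": 0.3}},
            seed=seeds["truth"],
        )
        y, _ = simulate_protein_trait(
            G, truths[name], covariates=cov, seed=int(trait_rng.integers(2**31)),
            trait=name,
        )
        y_rep, _ = simulate_protein_trait(
            G_rep, truths[name], covariates=cov_rep,
            seed=int(trait_rng_rep.integers(2**31)), trait=name,
        )
        raw_traits[name], raw_traits_rep[name] = y, y_rep

    io.write_genotypes_tsv(G, out / "genotypes.tsv", out / "variants.tsv")
    cov.to_csv(out / "covariates.tsv", sep="\t", index=False)
    pd.DataFrame(raw_traits, index=G.samples).to_csv(
        out / "traits_raw.tsv", sep="\t", index_label="sample_id"
    )
    truth_json = {
        name: {
            "causal_indices": t.causal_indices[name],
            "causal_ids": [G.variant_ids[j] for j in t.causal_indices[name]],
            "h2": t.h2[name],
        }
        for name, t in truths.items()
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=2, sort_keys=True) + "\n")

    # --- preprocess --------------------------------------------------------
    pcs_k = cfg["preprocess"]["pcs_k"]
    pcs = genotype_pcs(G, pcs_k)
    pcs_rep = genotype_pcs(G_rep, pcs_k)
    cov_full = pd.concat(
        [cov, pd.DataFrame(pcs, columns=[f"pc{i+1}" for i in range(pcs_k)])], axis=1
    )
    cov_full_rep = pd.concat(
        [cov_rep, pd.DataFrame(pcs_rep, columns=[f"pc{i+1}" for i in range(pcs_k)])],
        axis=1,
    )
    resid = {
        name: prepare_trait(y, cov_full, rint_offset=cfg["preprocess"]["rint_offset"]).values
        for name, y in raw_traits.items()
    }
    resid_rep = {
        name: prepare_trait(y, cov_full_rep, rint_offset=cfg["preprocess"]["rint_offset"]).values
        for name, y in raw_traits_rep.items()
    }
    pd.DataFrame(resid, index=G.samples).to_csv(
        out / "traits_residual.tsv", sep="\t", index_label="sample_id"
    )

    # --- fine-mapping + joint filter + sex interaction ---------------------
    fm_cfg = cfg["finemap"]
    grid = range(fm_cfg["grid"][0], fm_cfg["grid"][1] + 1)
    set_rows, finemap_out = [], {}
    for name in resid:
        y = resid[name]
        scan = marginal_scan(G, y, trait_id=name)
        fit, sets = select_L_grid(
            G.dosages, y, grid=grid,
            cs_ld_threshold=fm_cfg["cs_ld_threshold"],
            coverage=fm_cfg["coverage"], min_purity=fm_cfg["min_purity"],
            marginal_p=scan.table["pval"].to_numpy(),
        )
        prot_info = {"L": fit.L, "converged": bool(fit.converged), "sets": []}
        if sets:
            leads = [cs.lead for cs in sets]
            joint = joint_lead_test(G.dosages[:, leads], y, lead_indices=leads)
            r2 = variance_explained(G.dosages[:, leads], y)
            jt = joint.table.set_index("lead_index")
            sex_res = sex_interaction_test(G.dosages[:, leads[0]], y, G.sex)
            for s_i, cs in enumerate(sets):
                lead_id = G.variant_ids[cs.lead]
                row = {
                    "protein": name,
                    "set_id": f"{name}_cs{s_i}",
                    "lead_index": cs.lead,
                    "lead_id": lead_id,
                    "chrom": G.variants.loc[cs.lead, "chrom"],
                    "pos": int(G.variants.loc[cs.lead, "pos"]),
                    "n_members": len(cs.variant_indices),
                    "member_ids": ",".join(G.variant_ids[j] for j in cs.variant_indices),
                    "attained_coverage": cs.attained_coverage,
                    "purity": cs.purity,
                    "joint_beta": float(jt.loc[cs.lead, "beta"]) if cs.lead in jt.index else np.nan,
                    "joint_se": float(jt.loc[cs.lead, "se"]) if cs.lead in jt.index else np.nan,
                    "joint_p": float(jt.loc[cs.lead, "p"]) if cs.lead in jt.index else np.nan,
                    "retained": bool(jt.loc[cs.lead, "retained"]) if cs.lead in jt.index else False,
                    "variance_explained": r2,
                    "sex_interaction_p": sex_res["p_interaction"],
                }
                set_rows.append(row)
            prot_info["variance_explained"] = r2
        finemap_out[name] = prot_info
        manifest.add_count("finemap", f"{name}_sets", len(sets))
    sets_df = pd.DataFrame(
        set_rows,
        columns=[
            "protein", "set_id", "lead_index", "lead_id", "chrom", "pos",
            "n_members", "member_ids", "attained_coverage", "purity",
            "joint_beta", "joint_se", "joint_p", "retained",
            "variance_explained", "sex_interaction_p",
        ],
    )
    sets_df.to_csv(out / "credible_sets.tsv", sep="\t", index=False)
    (out / "finemap.json").write_text(json.dumps(finemap_out, indent=2, sort_keys=True) + "\n")

    # --- replication of retained leads -------------------------------------
    retained = sets_df[sets_df["retained"]]
    n_tests = max(len(retained), 1)
    rep_rows = []
    for name, sub in retained.groupby("protein", sort=False):
        leads = list(sub["lead_index"])
        joint = joint_lead_test(G.dosages[:, leads], resid[name], lead_indices=leads)
        rep = replicate_leads(
            joint, G_rep.dosages[:, leads], resid_rep[name],
            rep_lead_columns={li: j for j, li in enumerate(leads)},
            alpha=cfg["replication"]["alpha"], n_tests=n_tests,
        )
        t = rep.table.copy()
        t.insert(0, "protein", name)
        rep_rows.append(t)
    rep_df = (
        pd.concat(rep_rows, ignore_index=True)
        if rep_rows
        else pd.DataFrame(columns=["protein", "lead_index", "beta_disc", "beta_rep",
                                   "p_rep", "concordant", "replicated"])
    )
    rep_df.to_csv(out / "replication.tsv", sep="\t", index=False)
    manifest.add_count("replication", "n_tests", n_tests)
    manifest.add_count("replication", "replicated", int(rep_df["replicated"].sum()) if len(rep_df) else 0)

    # --- phenome colocalization on a dedicated region ----------------------
    cc = cfg["coloc"]
    G_coloc = simulate_genotypes(
        n=cc["n"], m=cc["m"], rho=cfg["genotypes"]["rho"],
        block_size=cfg["genotypes"]["block_size"], seed=seeds["coloc_geno"],
    )
    stats_a, stats_b, ld, pair_truth = simulate_trait_pair(
        G_coloc, mode=cc["mode"], h2_a=cc["h2_a"], h2_b=cc["h2_b"],
        seed=seeds["coloc_pair"],
    )
    record = coloc_screen(
        stats_a, stats_b, ld, p12=cc["p12"],
        pp_threshold=cc["pp_threshold"], min_overlap=cc["min_overlap"],
    )
    io.write_summary_stats(stats_a, out / "coloc_pqtl_stats.tsv")
    io.write_summary_stats(stats_b, out / "coloc_trait_stats.tsv")
    if cfg["write_ld"]:
        io.write_ld(ld, out / "coloc_ld.tsv")
    coloc_json = {
        "protein": record.protein_id,
        "trait": record.trait_id,
        "mode_simulated": pair_truth.sharing_mode,
        "posterior": None if record.posterior is None else {
            f"pp{i}": float(p) for i, p in enumerate(record.posterior.as_array())
        },
        "n_overlap": None if record.posterior is None else record.posterior.n_overlap,
        "sentinel_pqtl": record.sentinel_pqtl,
        "sentinel_trait": record.sentinel_trait,
        "sentinel_r2": record.sentinel_r2,
        "passed_filters": record.passed_filters,
        "effect_direction": record.effect_direction,
        "colocalized": record.colocalized,
    }
    (out / "coloc_record.json").write_text(json.dumps(coloc_json, indent=2, sort_keys=True) + "\n")
    manifest.add_count("coloc", "colocalized", int(record.colocalized))

    # --- catalog annotation and burden convergence -------------------------
    truth_leads = sets_df[["set_id", "lead_id", "chrom", "pos"]].copy()
    truth_leads["protein_gene"] = sets_df["protein"]
    genes = pd.DataFrame(
        {
            "protein_gene": [p["name"] for p in proteins],
            "nearest_gene": [f"{p['name']}_NB" for p in proteins],
            "decoy_gene": [f"{p['name']}_DECOY" for p in proteins],
        }
    )
    ld_disc = pd.DataFrame(G.corr(), index=G.variant_ids, columns=G.variant_ids)
    catalog, burden, labels = simulate_catalog_and_burden(
        truth_leads, genes, ld=ld_disc, seed=seeds["catalog"]
    )
    catalog.to_csv(out / "catalog.tsv", sep="\t", index=False)
    burden.to_csv(out / "burden.tsv", sep="\t", index=False)
    filtered, cat_counts = filter_catalog(catalog)
    manifest.add_count("annotate", "catalog_rows_in", cat_counts["rows_in"])
    manifest.add_count("annotate", "catalog_rows_dropped", cat_counts["rows_dropped"])
    matches = catalog_overlap(truth_leads, filtered, R=ld_disc)
    matches_df = pd.DataFrame(
        [
            {
                "set_id": m.set_id, "protein_gene": m.protein_gene,
                "trait": m.trait, "match_type": m.match_type,
                "proxy_r2": m.proxy_r2, "classification": m.classification,
                "nearest_gene_differs": m.nearest_gene_differs,
            }
            for m in matches
        ]
    )
    matches_df.to_csv(out / "catalog_matches.tsv", sep="\t", index=False)

    coloc_gene_records = pd.DataFrame(
        {
            "gene": [proteins[0]["name"]],
            "trait": ["lipids"],
            "pp": [0.0 if record.posterior is None else record.posterior.pp4],
        }
    )
    conv = exwas_convergence(
        coloc_gene_records, burden, covered_genes=[p["name"] for p in proteins]
    )
    (out / "convergence.json").write_text(
        json.dumps({"counts": conv.counts,
                    "pairs": conv.overlapping_pairs.to_dict(orient="records")},
                   indent=2, sort_keys=True, default=float) + "\n"
    )

    feat_rng = np.random.default_rng(seeds["features"])
    universe = len(proteins) * 50
    has_pqtl = feat_rng.random(universe) < 0.3
    feature = np.where(has_pqtl, feat_rng.random(universe) < 0.6,
                       feat_rng.random(universe) < 0.3)
    odds, ci, p_enrich = feature_enrichment(has_pqtl, feature)
    (out / "enrichment.json").write_text(
        json.dumps({"odds_ratio": odds, "ci95": list(ci), "p": p_enrich},
                   indent=2, sort_keys=True) + "\n"
    )

    # --- report ------------------------------------------------------------
    report = pd.DataFrame(
        {
            "protein": [p["name"] for p in proteins],
            "n_sets": [int((sets_df["protein"] == p["name"]).sum()) for p in proteins],
            "n_retained": [
                int(((sets_df["protein"] == p["name"]) & sets_df["retained"]).sum())
                for p in proteins
            ],
            "n_replicated": [
                int(((rep_df["protein"] == p["name"]) & rep_df["replicated"]).sum())
                if len(rep_df) else 0
                for p in proteins
            ],
        }
    )
    report.to_csv(out / "report.tsv", sep="\t", index=False)
    md = ["# Synthetic cis-pQTL study report", "",
          "| protein | credible sets | retained (p<5e-8) | replicated |",
          "|---|---|---|---|"]
    for r in report.itertuples(index=False):
        md.append(f"| {r.protein} | {r.n_sets} | {r.n_retained} | {r.n_replicated} |")
    md += ["", f"Colocalization declared: {record.colocalized} "
           f"(simulated mode: {pair_truth.sharing_mode})",
           f"Convergence counts: {conv.counts}"]
    (out / "report.md").write_text("\n".join(md) + "\n")

    if cfg["include_timestamps"]:
        manifest.timestamps = {"started": t0, "finished": time.time()}
    for f in sorted(out.glob("*.tsv")):
        manifest.input_digests[f.name] = io.file_digest(f)
    io.write_manifest(manifest, out / "manifest.json")
    return out
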