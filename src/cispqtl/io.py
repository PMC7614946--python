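"""Readers and writers for the pipeline's plain-text formats.

Genotypes travel as samples-by-variants TSV (header = variant ids) with
a side-car variant table, or as a minimal VCF with GT genotypes;
summary statistics, LD matrices, covariates and traits as TSV; ground
truth and manifests as JSON. Every reader counts the rows it keeps and
drops so no row is lost silently.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from cispqtl.containers import (
    AMBIGUOUS_PAIRS,
    SUMMARY_COLUMNS,
    GenotypeMatrix,
    RegionalSummaryStats,
    RunManifest,
)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Summary statistics


def write_summary_stats(stats: RegionalSummaryStats, path: str | Path) -> None:
    t = stats.table.copy()
    t["trait_id"] = stats.trait_id
    t["trait_type"] = stats.trait_type
    t["case_fraction"] = "" if stats.case_fraction is None else stats.case_fraction
    t.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> tuple[RegionalSummaryStats, dict]:
    """Read, type, and validate a summary-statistics TSV.

    Allele columns are upper-cased (with a warning on strand-ambiguous
    pairs), rows with non-numeric or non-positive standard errors are
    dropped and counted, and z-vs-p consistency warnings are collected.
    Returns the stats plus a counts dict for the manifest.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file missing columns: {missing}")
    counts = {"rows_in": len(df)}

    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    ambiguous = [
        vid
        for vid, ea, oa in zip(df["variant_id"], df["effect_allele"], df["other_allele"])
        if (ea, oa) in AMBIGUOUS_PAIRS
    ]
    for vid in ambiguous:
        warnings.warn(f"strand-ambiguous alleles at {vid}", stacklevel=2)

    df["se"] = pd.to_numeric(df["se"], errors="coerce")
    ok = df["se"].notna() & (df["se"] > 0)
    counts["rows_dropped"] = int((~ok).sum())
    df = df[ok].reset_index(drop=True)
    counts["rows_used"] = len(df)

    trait_id = str(df["trait_id"].iloc[0]) if "trait_id" in df and len(df) else "trait"
    trait_type = str(df["trait_type"].iloc[0]) if "trait_type" in df and len(df) else "quant"
    cf = None
    if trait_type == "binary" and "case_fraction" in df:
        cf = float(df["case_fraction"].iloc[0])
    stats = RegionalSummaryStats(
        trait_id=trait_id,
        table=df[SUMMARY_COLUMNS].copy(),
        trait_type=trait_type,
        case_fraction=cf,
    )
    counts["z_p_warnings"] = len(stats.validate())
    return stats, counts


# ---------------------------------------------------------------------------
# Genotypes


def write_genotypes_tsv(G: GenotypeMatrix, dosage_path: str | Path,
                        variant_path: str | Path | None = None) -> None:
    pd.DataFrame(G.dosages, index=G.samples, columns=G.variant_ids).to_csv(
        dosage_path, sep="\t", index_label="sample_id"
    )
    if variant_path is not None:
        G.variants.to_csv(variant_path, sep="\t", index=False)


def read_genotypes_tsv(
    dosage_path: str | Path, variant_path: str | Path | None = None
) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col="sample_id")
    if variant_path is not None:
        variants = pd.read_csv(variant_path, sep="\t", dtype={"chrom": str})
    else:
        variants = pd.DataFrame(
            {
                "id": df.columns,
                "chrom": "1",
                "pos": np.arange(1, df.shape[1] + 1),
                "effect_allele": "A",
                "other_allele": "G",
                "maf": np.minimum(df.mean(axis=0) / 2, 1 - df.mean(axis=0) / 2).to_numpy(),
            }
        )
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        variants=variants,
        samples=list(df.index.astype(str)),
    )


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call genotypes as a minimal GT-only VCF (GRCh37 contigs).

    Dosages are rounded to the nearest integer genotype; the effect
    allele is written as ALT so that the ALT dosage matches the matrix.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in dict.fromkeys(G.variants["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.samples))
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j, v in enumerate(G.variants.itertuples(index=False)):
        hard = np.rint(G.dosages[:, j]).astype(int)
        gts = "\t".join(gt_codes[int(g)] for g in hard)
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.other_allele}\t{v.effect_allele}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, multiallelic: str = "skip") -> tuple[GenotypeMatrix, dict]:
    """Read a GT-only VCF into a dosage matrix.

    ALT-allele dosage is the genotype count; missing genotypes (./.) are
    mean-imputed per variant with a manifest count. Multiallelic records
    are skipped (the default) or rejected per ``multiallelic``.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, meta = [], []
    counts = {"variants_in": 0, "multiallelic_skipped": 0, "missing_imputed": 0}
    for rec in vf:
        counts["variants_in"] += 1
        if rec.alts is None or len(rec.alts) != 1:
            if multiallelic == "skip":
                counts["multiallelic_skipped"] += 1
                continue
            raise ValueError(f"multiallelic record at {rec.chrom}:{rec.pos}")
        dos = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            dos[i] = float(sum(gt))
        n_missing = int(np.isnan(dos).sum())
        if n_missing:
            counts["missing_imputed"] += n_missing
            dos[np.isnan(dos)] = np.nanmean(dos)
        rows.append(dos)
        eaf = float(np.mean(dos) / 2)
        meta.append(
            {
                "id": rec.id or f"{rec.chrom}:{rec.pos}",
                "chrom": str(rec.chrom),
                "pos": int(rec.pos),
                "effect_allele": str(rec.alts[0]),
                "other_allele": str(rec.ref),
                "maf": min(eaf, 1 - eaf),
            }
        )
    counts["variants_used"] = len(rows)
    G = GenotypeMatrix(
        dosages=np.array(rows).T if rows else np.empty((len(samples), 0)),
        variants=pd.DataFrame(meta),
        samples=samples,
    )
    return G, counts


def read_genotypes(path: str | Path, fmt: str = "tsv", **kwargs) -> GenotypeMatrix:
    if fmt == "tsv":
        return read_genotypes_tsv(path, **kwargs)
    if fmt == "vcf":
        return read_vcf(path, **kwargs)[0]
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# LD, truth, manifest


def write_ld(ld: pd.DataFrame, path: str | Path) -> None:
    ld.to_csv(path, sep="\t", index_label="variant_id")


def read_ld(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="variant_id")


def write_truth(truth, path: str | Path) -> None:
    d = {
        "causal_indices": truth.causal_indices,
        "effect_sizes": truth.effect_sizes,
        "h2": truth.h2,
        "covariate_effects": truth.covariate_effects,
        "sharing_mode": truth.sharing_mode,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True, default=str) + "\n"
    )


def read_manifest(path: str | Path) -> RunManifest:
    return RunManifest.from_dict(json.loads(Path(path).read_text()))
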