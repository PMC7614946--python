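"""GWAS-catalog locus annotation, rare-burden convergence, and protein
feature enrichment.

Credible-set leads (or LD proxies at r² ≥ 0.8) are matched against
reported genome-wide-significant catalog associations and the catalog's
gene assignment is classified as confirmed, refined, or a novel
reassignment relative to the protein-coding gene. Colocalization results
are cross-referenced with exome-wide gene-burden hits to tally the
convergence of common regulatory and rare coding evidence. Protein
feature enrichment uses Fisher's exact test against the full assayed
protein background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def ld_proxies(
    variant_idx: int, R: np.ndarray | pd.DataFrame, r2_min: float = 0.8
) -> np.ndarray:
    """Indices of all variants with r² ≥ ``r2_min`` to the index variant.

    The comparison is inclusive; the variant is always its own proxy.
    ``R`` must be a square symmetric correlation matrix with unit
    diagonal.
    """
    Rm = R.to_numpy() if isinstance(R, pd.DataFrame) else np.asarray(R, dtype=float)
    if Rm.shape[0] != Rm.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(Rm, Rm.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    return np.flatnonzero(Rm[variant_idx] ** 2 >= r2_min)


def filter_catalog(
    catalog: pd.DataFrame,
    p_max: float = 5e-8,
    trait_denylist: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the catalog row invariants: drop rows missing an effect
    estimate or risk allele, rows above genome-wide significance, and
    (optionally) multiplex-proteomic-assay traits."""
    counts = {"rows_in": len(catalog)}
    c = catalog.copy()
    c = c[c["OR/BETA"].notna()]
    c = c[c["RISK_ALLELE"].astype(str).str.len() > 0]
    c = c[c["RISK_ALLELE"].astype(str) != "nan"]
    c = c[pd.to_numeric(c["P-VALUE"], errors="coerce") <= p_max]
    if trait_denylist:
        deny = {t.lower() for t in trait_denylist}
        c = c[~c["DISEASE/TRAIT"].str.lower().isin(deny)]
    counts["rows_kept"] = len(c)
    counts["rows_dropped"] = counts["rows_in"] - counts["rows_kept"]
    return c.reset_index(drop=True), counts


def _split_reported(reported) -> list[str]:
    if reported is None or (isinstance(reported, float) and np.isnan(reported)):
        return []
    return [g.strip() for g in str(reported).replace(";", ",").split(",") if g.strip()]


def classify_assignment(
    protein_gene: str, reported_genes: list[str], mapped_gene: str
) -> str:
    """Causal-gene classification for one credible-set/catalog match.

    - ``confirmed``: the protein-coding gene is the unique reported gene;
    - ``refined``: the protein gene is one of several reported genes (or
      is only supported by the catalog's nearest-gene mapping);
    - ``novel_reassignment``: the protein gene appears in neither the
      reported genes nor the mapped gene.
    """
    if protein_gene in reported_genes:
        return "confirmed" if len(reported_genes) == 1 else "refined"
    if protein_gene == mapped_gene:
        return "refined"
    return "novel_reassignment"


@dataclass
class CatalogMatch:
    set_id: str
    protein_gene: str
    catalog_row: int
    trait: str
    match_type: str  # direct | proxy
    proxy_r2: float
    classification: str
    nearest_gene_differs: bool
    ld_flagged: bool = False


def catalog_overlap(
    credible_sets: pd.DataFrame,
    catalog: pd.DataFrame,
    R: pd.DataFrame | None = None,
    proxy_r2: float = 0.8,
) -> list[CatalogMatch]:
    """Match credible-set leads against filtered catalog associations.

    ``credible_sets`` needs columns ``set_id, lead_id, protein_gene``.
    Catalog variants are matched directly by id, or through any variant
    with r² ≥ ``proxy_r2`` to the lead in the supplied LD matrix
    (variant-id labelled). Catalog variants absent from the LD matrix
    can only match directly and the match is flagged.
    """
    matches: list[CatalogMatch] = []
    for cs in credible_sets.itertuples(index=False):
        proxies: dict[str, float] = {cs.lead_id: 1.0}
        if R is not None and cs.lead_id in R.index:
            r = R.loc[cs.lead_id]
            for vid, rv in r.items():
                if rv**2 >= proxy_r2:
                    proxies[str(vid)] = float(rv**2)
        for row_idx, row in catalog.iterrows():
            snp = str(row["SNPS"])
            ld_flagged = False
            if snp == cs.lead_id:
                mtype, r2 = "direct", 1.0
                # direct-match-only when the catalog variant is absent from R
                ld_flagged = R is not None and snp not in R.index
            elif snp in proxies:
                mtype, r2 = "proxy", proxies[snp]
            else:
                continue
            reported = _split_reported(row["REPORTED GENE(S)"])
            mapped = str(row["MAPPED_GENE"])
            cls = classify_assignment(cs.protein_gene, reported, mapped)
            matches.append(
                CatalogMatch(
                    set_id=str(cs.set_id),
                    protein_gene=cs.protein_gene,
                    catalog_row=int(row_idx),
                    trait=str(row["DISEASE/TRAIT"]),
                    match_type=mtype,
                    proxy_r2=r2,
                    classification=cls,
                    nearest_gene_differs=cs.protein_gene != mapped,
                    ld_flagged=ld_flagged,
                )
            )
    return matches


@dataclass
class ConvergenceSummary:
    """Tally of genes implicated by rare burden, common pQTL coloc, or both."""

    counts: dict  # exwas_only, pqtl_only, both
    overlapping_pairs: pd.DataFrame  # gene, trait, mask, burden_beta, burden_p, pp
    excluded_genes: dict = field(default_factory=dict)


def exwas_convergence(
    coloc_records: pd.DataFrame,
    burden_table: pd.DataFrame,
    covered_genes: list[str],
    burden_p: float = 1e-6,
    pp: float = 0.8,
    trait_map: dict[str, str] | None = None,
) -> ConvergenceSummary:
    """Cross-reference colocalized pQTL genes with exome-wide burden hits.

    ``coloc_records`` needs columns ``gene, trait, pp``; ``burden_table``
    needs ``gene, trait, mask, beta, p``. A gene is an ExWAS hit when any
    burden row passes exome-wide significance and a pQTL hit when any
    colocalization posterior reaches the threshold; the three counts
    partition the union of implicated genes restricted to
    ``covered_genes``. For a gene–trait pair significant under several
    variant masks only the most significant row is carried forward.
    ``trait_map`` optionally translates colocalization trait names to
    burden trait names (the externalized manual harmonization).
    """
    covered = set(covered_genes)
    excluded = {
        "coloc": sorted(set(coloc_records["gene"]) - covered),
        "burden": sorted(set(burden_table["gene"]) - covered),
    }
    cr = coloc_records[coloc_records["gene"].isin(covered)].copy()
    bt = burden_table[burden_table["gene"].isin(covered)].copy()
    bt = bt.drop_duplicates()
    if trait_map:
        cr["trait"] = cr["trait"].map(lambda t: trait_map.get(t, t))

    exwas_genes = set(bt.loc[bt["p"] < burden_p, "gene"])
    pqtl_genes = set(cr.loc[cr["pp"] >= pp, "gene"])
    counts = {
        "exwas_only": len(exwas_genes - pqtl_genes),
        "pqtl_only": len(pqtl_genes - exwas_genes),
        "both": len(exwas_genes & pqtl_genes),
    }

    both = exwas_genes & pqtl_genes
    sig_burden = bt[(bt["gene"].isin(both)) & (bt["p"] < burden_p)]
    # keep the single most significant mask per gene-trait pair
    sig_burden = sig_burden.sort_values("p", kind="stable").groupby(
        ["gene", "trait"], as_index=False
    ).first()
    sig_coloc = cr[(cr["gene"].isin(both)) & (cr["pp"] >= pp)]
    pairs = sig_burden.merge(
        sig_coloc[["gene", "trait", "pp"]], on=["gene", "trait"], how="inner"
    )
    pairs = pairs.rename(columns={"beta": "burden_beta", "p": "burden_p"})
    return ConvergenceSummary(
        counts=counts, overlapping_pairs=pairs, excluded_genes=excluded
    )


def feature_enrichment(
    has_pqtl: np.ndarray, feature: np.ndarray
) -> tuple[float, tuple[float, float], float]:
    """Fisher's exact test of a protein feature among pQTL-bearing proteins.

    Both flags must be defined on the same protein universe (the full
    assayed panel as background). Returns (odds ratio, 95% CI, two-sided
    exact p). The p-value sums hypergeometric probabilities of tables at
    most as probable as the observed one; the CI is the Woolf log-OR
    interval. A zero margin makes the OR undefined: 0.5 is added to all
    cells for the OR and CI only (the exact p is unchanged).
    """
    has_pqtl = np.asarray(has_pqtl, dtype=bool)
    feature = np.asarray(feature, dtype=bool)
    if has_pqtl.shape != feature.shape:
        raise ValueError("flags must share the same protein universe")
    a = int(np.sum(has_pqtl & feature))
    b = int(np.sum(has_pqtl & ~feature))
    c = int(np.sum(~has_pqtl & feature))
    d = int(np.sum(~has_pqtl & ~feature))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")

    if min(a + b, c + d, a + c, b + d) == 0 or 0 in (a, b, c, d):
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    odds = (aa * dd) / (bb * cc)
    se_log = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = float(np.exp(np.log(odds) - 1.96 * se_log))
    hi = float(np.exp(np.log(odds) + 1.96 * se_log))
    return float(odds), (lo, hi), float(p)
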