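"""Marginal association scans, fixed-effects meta-analysis, and replication.

The scan is plain per-variant OLS of the residualized trait on dosage
(the study design excludes relatives, so a mixed model adds nothing to
first order). Per-cohort scans are combined by inverse-variance-weighted
fixed-effects meta-analysis after allele harmonization; credible-set
leads are replicated by refitting the exact joint model in an
independent sample with a direction-concordance plus Bonferroni rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cispqtl.containers import AMBIGUOUS_PAIRS, RegionalSummaryStats
from cispqtl.finemap import JointModelResult, joint_lead_test


def _two_sided_p(z: np.ndarray, n: int, exact_t_below: int = 100) -> np.ndarray:
    """Two-sided p from the normal for n > 100, exact t below that."""
    z = np.abs(z)
    if n > exact_t_below:
        return 2 * stats.norm.sf(z)
    return 2 * stats.t.sf(z, df=max(n - 2, 1))


def marginal_scan(
    G,
    y: np.ndarray,
    trait_id: str = "trait",
    trait_type: str = "quant",
    case_fraction: float | None = None,
) -> RegionalSummaryStats:
    """Per-variant simple linear regression of a trait on dosage.

    Returns per-allele beta, its standard error, and a two-sided p-value
    for every variant. Constant-dosage columns are emitted with missing
    statistics and a warning rather than silently dropped.
    """
    X = G.dosages if hasattr(G, "dosages") else np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if y.size != n:
        raise ValueError("trait length does not match genotype rows")

    xm = X.mean(axis=0)
    xc = X - xm
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    constant = sxx == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant dosage columns: stats set to NaN",
            stacklevel=2,
        )
    sxy = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = yc @ yc - beta * sxy
        dof = max(n - 2, 1)
        se = np.sqrt(np.maximum(rss, 0) / dof / sxx)
        z = beta / se
    pval = _two_sided_p(z, n)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    beta[constant] = np.nan
    se[constant] = np.nan
    pval[constant] = np.nan

    if hasattr(G, "variants"):
        v = G.variants
        table = pd.DataFrame(
            {
                "variant_id": v["id"].to_numpy(),
                "chrom": v["chrom"].to_numpy(),
                "pos": v["pos"].to_numpy(),
                "effect_allele": v["effect_allele"].to_numpy(),
                "other_allele": v["other_allele"].to_numpy(),
                "eaf": xm / 2.0,
                "beta": beta,
                "se": se,
                "pval": pval,
                "n": n,
            }
        )
    else:
        table = pd.DataFrame(
            {
                "variant_id": [f"v{j}" for j in range(m)],
                "chrom": "1",
                "pos": np.arange(1, m + 1),
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": xm / 2.0,
                "beta": beta,
                "se": se,
                "pval": pval,
                "n": n,
            }
        )
    return RegionalSummaryStats(
        trait_id=trait_id,
        table=table,
        trait_type=trait_type,
        case_fraction=case_fraction,
    )


def harmonize_alleles(
    ref: pd.DataFrame, other: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Align ``other`` rows to ``ref`` effect/other alleles by id.

    Rows whose alleles are swapped relative to the reference have beta
    negated and eaf reflected; rows with irreconcilable alleles are
    dropped. Strand-ambiguous pairs (A/T, C/G) trigger a warning and are
    kept as-is. Returns the aligned frame (indexed like ``ref``) and a
    counts dict (matched / flipped / dropped / ambiguous).
    """
    counts = {"matched": 0, "flipped": 0, "dropped": 0, "ambiguous": 0}
    o = other.set_index("variant_id")
    rows = []
    for row in ref.itertuples(index=False):
        if row.variant_id not in o.index:
            continue
        cand = o.loc[row.variant_id]
        if isinstance(cand, pd.DataFrame):
            cand = cand.iloc[0]
        ea, oa = str(cand["effect_allele"]).upper(), str(cand["other_allele"]).upper()
        if (ea, oa) in AMBIGUOUS_PAIRS:
            counts["ambiguous"] += 1
            warnings.warn(
                f"strand-ambiguous alleles at {row.variant_id}", stacklevel=2
            )
        rec = cand.copy()
        if ea == row.effect_allele and oa == row.other_allele:
            counts["matched"] += 1
        elif ea == row.other_allele and oa == row.effect_allele:
            rec["beta"] = -float(cand["beta"])
            rec["eaf"] = 1.0 - float(cand["eaf"])
            rec["effect_allele"], rec["other_allele"] = row.effect_allele, row.other_allele
            counts["flipped"] += 1
        else:
            counts["dropped"] += 1
            continue
        rec["variant_id"] = row.variant_id
        rows.append(rec)
    aligned = pd.DataFrame(rows).reset_index(drop=True)
    return aligned, counts


def ivw_meta(*stats_list: RegionalSummaryStats, trait_id: str | None = None) -> RegionalSummaryStats:
    """Inverse-variance-weighted fixed-effects meta-analysis of ≥2 cohorts.

    Variants are matched on id and harmonized alleles; β_meta =
    Σ wᵢβᵢ / Σ wᵢ with wᵢ = seᵢ⁻², se_meta = (Σ wᵢ)^(-1/2), p from the
    normal z. Symmetric and associative across cohorts.
    """
    if len(stats_list) < 2:
        raise ValueError("need at least two cohorts to meta-analyse")
    ref = stats_list[0].table
    aligned = [ref]
    for s in stats_list[1:]:
        a, _ = harmonize_alleles(ref, s.table)
        aligned.append(a)
    common = set(aligned[0]["variant_id"])
    for a in aligned[1:]:
        common &= set(a["variant_id"])
    common_ids = [v for v in ref["variant_id"] if v in common]

    frames = [a.set_index("variant_id").loc[common_ids] for a in aligned]
    betas = np.column_stack([f["beta"].to_numpy(dtype=float) for f in frames])
    ses = np.column_stack([f["se"].to_numpy(dtype=float) for f in frames])
    ns = np.column_stack([f["n"].to_numpy(dtype=float) for f in frames])
    eafs = np.column_stack([f["eaf"].to_numpy(dtype=float) for f in frames])

    w = 1.0 / ses**2
    beta_meta = (w * betas).sum(axis=1) / w.sum(axis=1)
    se_meta = 1.0 / np.sqrt(w.sum(axis=1))
    z = beta_meta / se_meta
    p_meta = np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    base = frames[0]
    table = pd.DataFrame(
        {
            "variant_id": common_ids,
            "chrom": base["chrom"].to_numpy(),
            "pos": base["pos"].to_numpy(),
            "effect_allele": base["effect_allele"].to_numpy(),
            "other_allele": base["other_allele"].to_numpy(),
            "eaf": (eafs * ns).sum(axis=1) / ns.sum(axis=1),
            "beta": beta_meta,
            "se": se_meta,
            "pval": p_meta,
            "n": ns.sum(axis=1).astype(int),
        }
    )
    return RegionalSummaryStats(
        trait_id=trait_id or stats_list[0].trait_id,
        table=table,
        trait_type=stats_list[0].trait_type,
        case_fraction=stats_list[0].case_fraction,
    )


@dataclass
class ReplicationResult:
    """Discovery-vs-replication comparison of credible-set leads."""

    table: pd.DataFrame  # lead_index, beta_disc, beta_rep, p_rep, concordant, replicated
    threshold: float
    effect_correlation: float
    non_evaluable: list[int] = field(default_factory=list)


def replicate_leads(
    discovery: JointModelResult,
    G_rep: np.ndarray,
    y_rep: np.ndarray,
    rep_lead_columns: dict[int, int] | None = None,
    alpha: float = 0.05,
    n_tests: int = 1,
) -> ReplicationResult:
    """Refit the joint lead model in an independent replication sample.

    A lead replicates when its replication effect is directionally
    concordant with discovery AND its replication p-value passes the
    Bonferroni threshold alpha / n_tests. Leads absent from the
    replication genotypes are marked non-evaluable and excluded from the
    reported discovery–replication effect correlation.
    """
    G_rep = np.atleast_2d(np.asarray(G_rep, dtype=float))
    if G_rep.shape[0] == 1 and G_rep.shape[1] == np.asarray(y_rep).size:
        G_rep = G_rep.T
    disc = discovery.table
    lead_idx = list(disc["lead_index"])
    if rep_lead_columns is None:
        rep_lead_columns = {li: j for j, li in enumerate(lead_idx)}

    evaluable = [li for li in lead_idx if li in rep_lead_columns]
    non_evaluable = [li for li in lead_idx if li not in rep_lead_columns]
    if not evaluable:
        raise ValueError("no discovery lead present in the replication genotypes")

    cols = [rep_lead_columns[li] for li in evaluable]
    rep_fit = joint_lead_test(G_rep[:, cols], y_rep, lead_indices=evaluable,
                              threshold=alpha / n_tests)
    rep = rep_fit.table.set_index("lead_index")
    threshold = alpha / n_tests

    rows = []
    for li in evaluable:
        b_d = float(disc.loc[disc["lead_index"] == li, "beta"].iloc[0])
        b_r = float(rep.loc[li, "beta"])
        p_r = float(rep.loc[li, "p"])
        concordant = bool(np.sign(b_r) == np.sign(b_d)) and b_d != 0
        rows.append(
            {
                "lead_index": li,
                "beta_disc": b_d,
                "beta_rep": b_r,
                "p_rep": p_r,
                "concordant": concordant,
                "replicated": concordant and p_r < threshold,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) > 1:
        r = float(np.corrcoef(table["beta_disc"], table["beta_rep"])[0, 1])
    else:
        r = float("nan")
    return ReplicationResult(
        table=table, threshold=threshold, effect_correlation=r,
        non_evaluable=non_evaluable,
    )
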