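"""Bayesian colocalization of cis-pQTLs with phenome-wide trait signals.

Per-variant approximate Bayes factors (Wakefield's asymptotic form) feed
the standard five-hypothesis enumeration: no signal (H0), a signal for
one trait only (H1/H2), two distinct causal variants (H3), or one shared
causal variant (H4). The phenome-wide screen wraps the posterior in the
gating rules used for discovery: suggestive trait association at the
lead cis-pQTL or a strong proxy, a minimum SNP overlap of 500, presence
of the strongest cis-pQTL (or proxy) in the overlap, sentinel–sentinel
LD r² ≥ 0.8, and PP4 ≥ 80%, under a conservative shared-causal prior
p12 = 1e-6 (relaxed to 1e-5 for eQTL colocalization). A simplified
multi-trait extension ("hyprcoloc-lite") scores all-share-one-signal
against all-independent and divisively peels traits until the shared
posterior clears the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from cispqtl.containers import RegionalSummaryStats
from cispqtl.assoc import harmonize_alleles

#: Wakefield prior standard deviations by trait type (binary on log-odds scale)
PRIOR_SD = {"quant": 0.15, "binary": 0.2}


@dataclass
class ColocPosterior:
    """Five-hypothesis colocalization posterior for one trait pair."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    priors: tuple[float, float, float]  # (p1, p2, p12)
    n_overlap: int

    def __post_init__(self) -> None:
        self.pp0, self.pp1, self.pp2, self.pp3, self.pp4 = (
            float(self.pp0), float(self.pp1), float(self.pp2),
            float(self.pp3), float(self.pp4),
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    def validate(self, tol: float = 1e-10) -> None:
        pp = self.as_array()
        if not np.isclose(pp.sum(), 1.0, atol=tol):
            raise ValueError("posterior probabilities do not sum to 1")
        if (pp < -tol).any() or (pp > 1 + tol).any():
            raise ValueError("posterior probabilities outside [0, 1]")


@dataclass
class ColocRecord:
    """Outcome of the screened colocalization of one protein–trait pair."""

    protein_id: str
    trait_id: str
    posterior: ColocPosterior | None
    sentinel_pqtl: str | None = None
    sentinel_trait: str | None = None
    sentinel_r2: float | None = None
    passed_filters: dict = field(default_factory=dict)
    effect_direction: int | None = None  # trait effect per protein-increasing allele
    colocalized: bool = False
    evaluable: bool = True
    reason: str | None = None


def wakefield_labf(
    stats: RegionalSummaryStats | pd.DataFrame | None = None,
    prior_sd: float | None = None,
    beta: np.ndarray | None = None,
    se: np.ndarray | None = None,
) -> np.ndarray:
    """Per-variant log approximate Bayes factor for association.

    With sampling variance V = se², z = beta/se and prior effect
    variance W = prior_sd²:

        labf = ½ [ log(V / (V + W)) + z²·W/(V + W) ]

    Binary-trait rows fitted by linear regression should be converted to
    the log-odds scale first (see ``labf_for_stats``).
    """
    if stats is not None:
        t = stats.table if isinstance(stats, RegionalSummaryStats) else stats
        beta = t["beta"].to_numpy(dtype=float)
        se = t["se"].to_numpy(dtype=float)
        if prior_sd is None and isinstance(stats, RegionalSummaryStats):
            prior_sd = PRIOR_SD[stats.trait_type]
    if prior_sd is None:
        prior_sd = PRIOR_SD["quant"]
    if prior_sd < 0:
        raise ValueError("prior_sd must be non-negative")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    V = se**2
    W = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * (np.log(V / (V + W)) + z2 * W / (V + W))


def linear_to_logodds(beta: float | np.ndarray, mu: float) -> float | np.ndarray:
    """Convert a linear-regression coefficient on a 0/1 outcome to a log OR.

    log(odds ratio) = β / (μ·(1 − μ)) where μ is the case fraction.
    """
    if not 0 < mu < 1:
        raise ValueError(f"case fraction must be in (0, 1), got {mu}")
    return np.asarray(beta, dtype=float) / (mu * (1.0 - mu)) if np.ndim(beta) else beta / (mu * (1.0 - mu))


def labf_for_stats(
    stats: RegionalSummaryStats, table: pd.DataFrame | None = None,
    prior_sd: float | None = None,
) -> np.ndarray:
    """Bayes factors with the trait-type prior, converting binary-trait
    linear-scale rows to log odds ratios via the stored case fraction."""
    t = stats.table if table is None else table
    beta = t["beta"].to_numpy(dtype=float)
    se = t["se"].to_numpy(dtype=float)
    if stats.trait_type == "binary":
        mu = stats.case_fraction
        beta = beta / (mu * (1.0 - mu))
        se = se / (mu * (1.0 - mu))
        sd = PRIOR_SD["binary"] if prior_sd is None else prior_sd
    else:
        sd = PRIOR_SD["quant"] if prior_sd is None else prior_sd
    return wakefield_labf(beta=beta, se=se, prior_sd=sd)


def coloc_abf(
    labf1: np.ndarray,
    labf2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-6,
) -> ColocPosterior:
    """Five-hypothesis posterior from aligned per-variant log Bayes factors.

    All sums run in log space. With S1 = logΣexp(labf1), S2 analogous
    and S12 = logΣexp(labf1 + labf2), the unnormalized hypothesis masses
    are 1, p1·e^S1, p2·e^S2, p1·p2·(e^(S1+S2) − e^S12), p12·e^S12; the
    distinct-causal mass is exactly zero for a single-SNP region.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.size < 1:
        raise ValueError("labf vectors must be aligned and non-empty")
    for p in (p1, p2, p12):
        if not 0 < p < 1:
            raise ValueError("priors must be in (0, 1)")

    s1 = float(logsumexp(labf1))
    s2 = float(logsumexp(labf2))
    s12 = float(logsumexp(labf1 + labf2))

    log_h = np.empty(5)
    log_h[0] = 0.0
    log_h[1] = np.log(p1) + s1
    log_h[2] = np.log(p2) + s2
    # off-diagonal configuration sum: e^(S1+S2) − e^S12 ≥ 0
    gap = s12 - (s1 + s2)
    if gap >= 0:
        if gap > 1e-9 and labf1.size > 1:
            warnings.warn("negative distinct-causal mass clipped at 0", stacklevel=2)
        log_h[3] = -np.inf
    else:
        log_h[3] = np.log(p1) + np.log(p2) + s1 + s2 + np.log1p(-np.exp(gap))
    log_h[4] = np.log(p12) + s12

    pp = np.exp(log_h - logsumexp(log_h))
    pp /= pp.sum()
    return ColocPosterior(*pp, priors=(p1, p2, p12), n_overlap=labf1.size)


def _proxies_of(ld: pd.DataFrame, vid: str, r2_min: float) -> list[str]:
    if vid not in ld.index:
        return [vid]
    r = ld.loc[vid]
    return list(r.index[r.to_numpy() ** 2 >= r2_min])


def coloc_screen(
    pqtl_stats: RegionalSummaryStats,
    trait_stats: RegionalSummaryStats,
    ld: pd.DataFrame,
    p12: float = 1e-6,
    pp_threshold: float = 0.8,
    lead_p: float = 1e-6,
    proxy_r2: float = 0.8,
    min_overlap: int = 500,
    p1: float = 1e-4,
    p2: float = 1e-4,
) -> ColocRecord:
    """Phenome-wide colocalization of one protein–trait pair with the
    discovery gating rules.

    Steps: (1) intersect variants on id and harmonized alleles; (2)
    require ≥ ``min_overlap`` shared SNPs; (3) require suggestive trait
    association (p < ``lead_p``) at the lead cis-pQTL or an r² ≥
    ``proxy_r2`` proxy; (4) require the strongest cis-pQTL or such a
    proxy inside the overlap; (5) run the ABF posterior; (6) require
    sentinel–sentinel r² ≥ ``proxy_r2``; (7) record the trait effect
    direction per protein-increasing allele. The pair is declared
    colocalized iff every gate passes and PP4 ≥ ``pp_threshold``.
    """
    record = ColocRecord(protein_id=pqtl_stats.trait_id, trait_id=trait_stats.trait_id,
                         posterior=None)
    flags = {
        "lead_suggestive": False,
        "overlap_ge_min": False,
        "sentinel_ld_ge_0.8": False,
        "pp_ge_threshold": False,
    }
    record.passed_filters = flags

    aligned_trait, _ = harmonize_alleles(pqtl_stats.table, trait_stats.table)
    common = set(aligned_trait["variant_id"])
    pq = pqtl_stats.table[pqtl_stats.table["variant_id"].isin(common)].reset_index(drop=True)
    tr = aligned_trait.set_index("variant_id").loc[pq["variant_id"]].reset_index()
    flags["overlap_ge_min"] = len(pq) >= min_overlap

    lead_pqtl_id = str(pqtl_stats.lead["variant_id"])  # strongest over the full window
    needed = {lead_pqtl_id} | set(_proxies_of(ld, lead_pqtl_id, proxy_r2))
    missing_ld = lead_pqtl_id not in ld.index
    if missing_ld:
        record.evaluable = False
        record.reason = f"no LD entries for lead cis-pQTL {lead_pqtl_id}"
        return record

    # gate 3: suggestive trait association at the lead or a strong proxy
    trait_at = trait_stats.table.set_index("variant_id")
    probe_ps = [
        float(trait_at.loc[v, "pval"])
        for v in needed
        if v in trait_at.index
    ]
    flags["lead_suggestive"] = bool(probe_ps) and min(probe_ps) < lead_p

    # gate 4: strongest cis-pQTL or proxy must sit inside the overlap
    in_overlap = bool(needed & common)

    if not (flags["overlap_ge_min"] and flags["lead_suggestive"] and in_overlap):
        record.reason = "failed pre-colocalization gates"
        return record

    labf_p = labf_for_stats(pqtl_stats, table=pq)
    labf_t = labf_for_stats(trait_stats, table=tr)
    post = coloc_abf(labf_p, labf_t, p1=p1, p2=p2, p12=p12)
    post.validate()
    record.posterior = post
    flags["pp_ge_threshold"] = bool(post.pp4 >= pp_threshold)

    sent_p = str(pq.loc[pq["pval"].idxmin(), "variant_id"])
    sent_t = str(tr.loc[tr["pval"].idxmin(), "variant_id"])
    record.sentinel_pqtl, record.sentinel_trait = sent_p, sent_t
    if sent_p in ld.index and sent_t in ld.columns:
        r2 = float(ld.loc[sent_p, sent_t] ** 2)
        record.sentinel_r2 = r2
        flags["sentinel_ld_ge_0.8"] = bool(r2 >= proxy_r2)
    else:
        record.evaluable = False
        record.reason = "missing LD for sentinel variants"
        return record

    # direction of the trait effect per protein-increasing allele at the sentinel
    b_p = float(pq.loc[pq["variant_id"] == sent_p, "beta"].iloc[0])
    b_t = float(tr.loc[tr["variant_id"] == sent_p, "beta"].iloc[0])
    direction = np.sign(b_t) * (1 if b_p >= 0 else -1)
    record.effect_direction = int(direction)

    record.colocalized = all(flags.values())
    return record


def eqtl_coloc(
    pqtl_stats: RegionalSummaryStats,
    eqtl_stats: RegionalSummaryStats,
    ld: pd.DataFrame,
    p12: float = 1e-5,
    **kwargs,
) -> ColocRecord:
    """Protein–expression colocalization: same screen, relaxed p12 prior
    (1e-5) reflecting the higher prior of a shared signal at the encoding
    gene."""
    return coloc_screen(pqtl_stats, eqtl_stats, ld, p12=p12, **kwargs)


def multitrait_coloc(
    labf_matrix: np.ndarray | pd.DataFrame,
    p1: float = 1e-4,
    gamma: float = 1e-2,
    pp_threshold: float = 0.8,
) -> list[dict]:
    """Simplified multi-trait colocalization with divisive clustering
    (method "hyprcoloc-lite").

    For a trait set T the shared-signal mass is
    p1·γ^(|T|−1)·Σ_q exp(Σ_t labf_tq) against the all-independent mass
    Π_t (p1·Σ_q exp(labf_tq)) and the all-null mass 1:

        PP_shared = e_shared / (1 + e_indep + e_shared)

    The candidate SNP is argmax_q Σ_t labf_tq and
    ``proportion_explained`` is its share of the shared-signal sum.
    Starting from all traits, while PP_shared < threshold and |T| > 2
    the trait whose removal maximizes PP_shared is peeled off (ties to
    the lowest trait index); peeled traits seed the next cluster
    attempt. The hypothesis space deliberately omits partial-sharing
    configurations.
    """
    if isinstance(labf_matrix, pd.DataFrame):
        trait_names = list(labf_matrix.index)
        snp_names = list(labf_matrix.columns)
        B = labf_matrix.to_numpy(dtype=float)
    else:
        B = np.asarray(labf_matrix, dtype=float)
        trait_names = [f"trait{t}" for t in range(B.shape[0])]
        snp_names = [f"snp{q}" for q in range(B.shape[1])]
    m = B.shape[0]
    if m < 2:
        raise ValueError("multi-trait colocalization needs at least two traits")

    def pp_shared(traits: list[int]) -> tuple[float, int, float]:
        sub = B[traits]
        col = sub.sum(axis=0)
        log_e_shared = np.log(p1) + (len(traits) - 1) * np.log(gamma) + logsumexp(col)
        log_e_indep = sum(np.log(p1) + logsumexp(B[t]) for t in traits)
        denom = logsumexp([0.0, log_e_indep, log_e_shared])
        pp = float(np.exp(log_e_shared - denom))
        cand = int(np.argmax(col))
        prop = float(np.exp(col[cand] - logsumexp(col)))
        return pp, cand, prop

    clusters: list[dict] = []
    pool = list(range(m))
    while len(pool) >= 2:
        current = list(pool)
        removed: list[int] = []
        pp, cand, prop = pp_shared(current)
        while pp < pp_threshold and len(current) > 2:
            best = None
            for t in current:  # peel the trait whose removal helps most
                trial = [u for u in current if u != t]
                pp_t, _, _ = pp_shared(trial)
                if best is None or pp_t > best[0]:
                    best = (pp_t, t)
            pp, drop = best
            removed.append(drop)
            current = [u for u in current if u != drop]
            pp, cand, prop = pp_shared(current)
        if pp >= pp_threshold:
            clusters.append(
                {
                    "traits": [trait_names[t] for t in current],
                    "pp_shared": pp,
                    "candidate_snp": snp_names[cand],
                    "proportion_explained": prop,
                    "method": "hyprcoloc-lite",
                }
            )
        pool = removed  # peeled traits seed the next cluster attempt
    return clusters
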