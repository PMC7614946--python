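"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the pipeline consumes: LD-structured
genotype dosages in Hardy–Weinberg proportions, log-scale protein traits
driven by one to eight cis causal variants plus covariate effects,
paired traits with shared / distinct / absent causal variants, a
GWAS-catalog-like association table, and a gene-burden table. Every
generator is a pure function of its arguments including the seed.

Genotypes come from a Gaussian-copula threshold model: a latent standard
normal with block-constant correlation ``rho`` is cut at the two
Hardy–Weinberg quantiles of the variant's minor allele frequency, so the
marginal genotype distribution is exactly HWE while neighbouring
variants within a block are correlated. This realizes the LD regimes the
pipeline's rules reference (r² thresholds of 0.1 and 0.8) without a
coalescent simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cispqtl.containers import GenotypeMatrix, RegionalSummaryStats


@dataclass
class SimTruth:
    """Ground truth of a simulated region.

    ``causal_indices`` maps trait label -> list of causal variant column
    indices; ``effect_sizes`` holds the matching per-trait effects on the
    standardized-genotype scale (per-allele effects follow by dividing by
    sqrt(2·maf·(1−maf))). ``h2`` is the target fraction of trait variance
    (before covariates) explained by the causal variants jointly.
    """

    causal_indices: dict[str, list[int]]
    effect_sizes: dict[str, list[float]]
    h2: dict[str, float]
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    sharing_mode: str | None = None
    seed: int | None = None

    def validate(self, m: int) -> None:
        for trait, idx in self.causal_indices.items():
            if any(j < 0 or j >= m for j in idx):
                raise ValueError(f"causal index out of range for trait {trait!r}")
            if len(idx) != len(self.effect_sizes[trait]):
                raise ValueError(f"effect size count mismatch for trait {trait!r}")
        if self.sharing_mode == "shared":
            traits = list(self.causal_indices)
            if len(traits) == 2:
                a, b = traits
                if self.causal_indices[a] != self.causal_indices[b]:
                    raise ValueError("shared mode requires identical causal indices")


def hwe_thresholds(maf: float) -> tuple[float, float]:
    """Latent-normal cutpoints reproducing HWE genotype frequencies.

    P(dosage=0) = (1−p)², P(dosage≤1) = (1−p)² + 2p(1−p) for effect-allele
    frequency p.
    """
    q0 = (1.0 - maf) ** 2
    q1 = q0 + 2.0 * maf * (1.0 - maf)
    return stats.norm.ppf(q0), stats.norm.ppf(q1)


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    rho: float = 0.8,
    block_size: int = 20,
    seed: int = 0,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    pos_step: int = 750,
    variants: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Draw an LD-structured dosage matrix in Hardy–Weinberg proportions.

    Parameters
    ----------
    n, m:
        Sample and variant counts (n ≥ 2, m ≥ 1).
    maf_range:
        Uniform sampling range for per-variant effect-allele frequency;
        must lie within (0, 0.5].
    rho:
        Latent within-block correlation in [0, 1). Adjacent-variant
        genotype r² is a deterministic function of ``rho`` and the MAFs
        (checked against a large-n copula simulation in the tests).
    block_size:
        Variants per LD block; blocks are mutually independent.
    seed:
        Seed for the dedicated random stream; identical arguments give
        bit-identical output.
    variants:
        Optional variant table from an existing matrix; reusing it draws
        a fresh sample from the same population (same ids, positions and
        MAFs), as for a replication cohort.

    Notes
    -----
    Variants that come out monomorphic in the finite sample are redrawn
    (new independent latent noise, same block factor) so the empirical
    allele frequency is always strictly inside (0, 1). Effect/other
    alleles are written as A/G throughout: the generator never emits
    strand-ambiguous pairs.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 samples and m >= 1 variants")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    if not 0 <= rho < 1:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")

    rng = np.random.default_rng(seed)
    if variants is not None:
        if len(variants) != m:
            raise ValueError("variant table length does not match m")
        mafs = variants["maf"].to_numpy(dtype=float)
        rng.uniform(lo, hi, size=m)  # keep the stream layout identical
    else:
        mafs = rng.uniform(lo, hi, size=m)

    n_blocks = int(np.ceil(m / block_size))
    block_factor = rng.standard_normal((n, n_blocks))
    noise = rng.standard_normal((n, m))
    block_of = np.minimum(np.arange(m) // block_size, n_blocks - 1)
    latent = np.sqrt(rho) * block_factor[:, block_of] + np.sqrt(1.0 - rho) * noise

    dosages = np.empty((n, m), dtype=float)
    for j in range(m):
        t0, t1 = hwe_thresholds(mafs[j])
        col = (latent[:, j] > t0).astype(float) + (latent[:, j] > t1)
        tries = 0
        while (col.min() == col.max()) and tries < 200:
            # redraw the idiosyncratic part only, keeping the block factor
            z = np.sqrt(rho) * block_factor[:, block_of[j]] + np.sqrt(
                1.0 - rho
            ) * rng.standard_normal(n)
            col = (z > t0).astype(float) + (z > t1)
            tries += 1
        if col.min() == col.max():
            raise RuntimeError(
                f"variant {j} monomorphic after {tries} redraws; "
                "increase n or the lower MAF bound"
            )
        dosages[:, j] = col

    if variants is None:
        variants = pd.DataFrame(
            {
                "id": [f"rs{seed % 1000}_{j}" for j in range(m)],
                "chrom": chrom,
                "pos": start_pos + pos_step * np.arange(m),
                "effect_allele": "A",
                "other_allele": "G",
                "maf": mafs,
            }
        )
    else:
        variants = variants.reset_index(drop=True).copy()
    sex = rng.integers(0, 2, size=n).astype(float)
    G = GenotypeMatrix(
        dosages=dosages,
        variants=variants,
        samples=[f"S{i:05d}" for i in range(n)],
        sex=sex,
    )
    G.validate()
    return G


def simulate_covariates(
    n: int, sex: np.ndarray | None = None, n_plates: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Age, sex, and measurement-plate table matching the model's adjustments."""
    rng = np.random.default_rng(seed)
    if sex is None:
        sex = rng.integers(0, 2, size=n).astype(float)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "age": rng.uniform(40, 75, size=n).round(1),
            "sex": sex,
            "plate": [f"plate{p}" for p in rng.integers(0, n_plates, size=n)],
        }
    )


def simulate_protein_trait(
    G: GenotypeMatrix,
    truth: SimTruth,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    trait: str = "protein",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a protein abundance vector from a region's ground truth.

    The genetic component is Σ β_j · standardized(G_j) over the trait's
    causal variants; Gaussian noise is scaled so the genetic fraction of
    the pre-covariate variance equals the target heritability, and any
    covariate effects (keys matching covariate columns; ``plate`` uses a
    per-level effect drawn from N(0, effect²)) are added on top.

    Returns
    -------
    y, realized_r2:
        The trait vector and the realized marginal R² of the
        pre-covariate trait at each causal variant (empty if none).
    """
    truth.validate(G.m)
    rng = np.random.default_rng(seed)
    idx = truth.causal_indices.get(trait, [])
    betas = np.asarray(truth.effect_sizes.get(trait, []), dtype=float)
    h2 = truth.h2.get(trait, 0.0)
    if not 0 <= h2 < 1:
        raise ValueError(f"target heritability must be in [0, 1), got {h2}")
    if len(idx) == 0 or np.all(betas == 0) or h2 == 0:
        if h2 > 0 and (len(idx) == 0 or np.all(betas == 0)):
            raise ValueError("non-zero target heritability with no causal effects")
        genetic = np.zeros(G.n)
        noise_sd = 1.0
    else:
        Xs = G.standardized()[:, idx]
        genetic = Xs @ betas
        var_g = genetic.var()
        if var_g == 0:
            raise ValueError("causal variants carry no variance in this sample")
        noise_sd = float(np.sqrt(var_g * (1.0 - h2) / h2))
    y = genetic + noise_sd * rng.standard_normal(G.n)

    realized_r2 = np.array(
        [np.corrcoef(y, G.dosages[:, j])[0, 1] ** 2 for j in idx]
    )
    if len(idx) and np.all(betas == 0):
        realized_r2 = np.zeros(len(idx))

    cov_effects = truth.covariate_effects.get(trait, {})
    if cov_effects:
        if covariates is None:
            raise ValueError("covariate effects specified but no covariate table given")
        for name, eff in cov_effects.items():
            col = covariates[name]
            if col.dtype == object:
                levels = sorted(col.unique())
                level_effects = dict(
                    zip(levels, eff * rng.standard_normal(len(levels)))
                )
                y = y + col.map(level_effects).to_numpy(dtype=float)
            else:
                y = y + eff * col.to_numpy(dtype=float)
    return y, realized_r2


def liability_to_binary(liability: np.ndarray, case_fraction: float) -> np.ndarray:
    """Dichotomize a liability at the quantile giving the target case fraction."""
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must be in (0, 1)")
    threshold = np.quantile(liability, 1.0 - case_fraction)
    return (liability > threshold).astype(float)


def simulate_trait_pair(
    G: GenotypeMatrix,
    mode: str,
    h2_a: float,
    h2_b: float,
    seed: int = 0,
    distinct_r2_cap: float = 0.05,
    trait_b_type: str = "quant",
    case_fraction: float = 0.1,
) -> tuple[RegionalSummaryStats, RegionalSummaryStats, pd.DataFrame, SimTruth]:
    """Simulate two traits on one region and return their marginal scans.

    ``mode`` controls the causal architecture of the pair:

    - ``shared``: one causal variant drives both traits,
    - ``distinct``: each trait has its own causal variant, constrained to
      pairwise r² below ``distinct_r2_cap``,
    - ``independent``: trait a has a causal variant, trait b is pure noise.

    Binary trait b (``trait_b_type="binary"``) is produced by thresholding
    the quantitative liability at the ``case_fraction`` quantile and is
    analysed, as biobank pipelines often do for speed, by linear
    regression on the 0/1 outcome; the case fraction is carried in the
    summary container for downstream log-odds conversion.

    Returns summary statistics for both traits, the sample LD (r) matrix
    as a variant-id-labelled data frame, and the ground truth.
    """
    from cispqtl.assoc import marginal_scan

    if mode not in ("shared", "distinct", "independent"):
        raise ValueError(f"unknown sharing mode {mode!r}")
    rng = np.random.default_rng(seed)
    R = G.corr()

    idx_a = int(rng.integers(0, G.m))
    if mode == "shared":
        idx_b: int | None = idx_a
    elif mode == "distinct":
        candidates = np.flatnonzero(R[idx_a] ** 2 < distinct_r2_cap)
        if candidates.size == 0:
            raise ValueError(
                f"no variant with r^2 < {distinct_r2_cap} of the first causal; "
                "distinct mode unsatisfiable in this region"
            )
        idx_b = int(rng.choice(candidates))
    else:
        idx_b = None

    truth = SimTruth(
        causal_indices={
            "a": [idx_a],
            "b": [] if idx_b is None else [idx_b],
        },
        effect_sizes={"a": [1.0], "b": [] if idx_b is None else [1.0]},
        h2={"a": h2_a, "b": 0.0 if idx_b is None else h2_b},
        sharing_mode=mode,
        seed=seed,
    )
    seed_a, seed_b = int(rng.integers(2**31)), int(rng.integers(2**31))
    y_a, _ = simulate_protein_trait(G, truth, seed=seed_a, trait="a")
    y_b, _ = simulate_protein_trait(G, truth, seed=seed_b, trait="b")

    stats_a = marginal_scan(G, y_a, trait_id="trait_a")
    if trait_b_type == "binary":
        y_b = liability_to_binary(y_b, case_fraction)
        stats_b = marginal_scan(
            G, y_b, trait_id="trait_b", trait_type="binary", case_fraction=case_fraction
        )
    else:
        stats_b = marginal_scan(G, y_b, trait_id="trait_b")

    ld = pd.DataFrame(R, index=G.variant_ids, columns=G.variant_ids)
    return stats_a, stats_b, ld, truth


# ---------------------------------------------------------------------------
# Catalog and burden table emulation


CATALOG_COLUMNS = [
    "SNPS",
    "CHR_ID",
    "CHR_POS",
    "DISEASE/TRAIT",
    "REPORTED GENE(S)",
    "MAPPED_GENE",
    "RISK_ALLELE",
    "OR/BETA",
    "P-VALUE",
]


def simulate_catalog_and_burden(
    truth_leads: pd.DataFrame,
    genes: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    scenarios: list[str] | None = None,
    burden_spec: pd.DataFrame | None = None,
    n_unrelated: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit a GWAS-catalog-like table and a gene-burden table with truth labels.

    Parameters
    ----------
    truth_leads:
        One row per simulated credible set: columns ``set_id, lead_id,
        chrom, pos, protein_gene``.
    genes:
        Region gene context: columns ``protein_gene, nearest_gene, decoy_gene``.
    ld:
        Optional variant-id-labelled r matrix used to place proxy rows
        (rows at an r² ≥ 0.8 neighbour of the lead instead of the lead).
    scenarios:
        Catalog-row recipes cycled over the leads. Each is
        ``"<where>:<genes>"`` with ``where`` in ``{direct, proxy}`` and
        ``genes`` in ``{true, decoy, list}``; defaults to
        ``["direct:true", "proxy:decoy", "direct:list"]`` which realize the
        confirmed / novel-reassignment / refined classifications.
    burden_spec:
        Optional rows ``gene, trait, mask, beta, se, p``; when omitted a
        default table with one significant gene, duplicate masks for one
        gene-trait pair, and one null gene is produced.

    Returns
    -------
    catalog, burden, labels:
        The two tables plus a per-catalog-row ground-truth label frame
        (``set_id, scenario, expected_class``).
    """
    rng = np.random.default_rng(seed)
    if scenarios is None:
        scenarios = ["direct:true", "proxy:decoy", "direct:list"]

    gene_ctx = genes.set_index("protein_gene")
    cat_rows, label_rows = [], []
    for k, lead in enumerate(truth_leads.itertuples(index=False)):
        scen = scenarios[k % len(scenarios)]
        where, reported_kind = scen.split(":")
        ctx = gene_ctx.loc[lead.protein_gene]

        snp_id, pos = lead.lead_id, lead.pos
        if where == "proxy":
            if ld is not None and lead.lead_id in ld.index:
                r = ld.loc[lead.lead_id]
                proxies = r.index[(r.to_numpy() ** 2 >= 0.8) & (r.index != lead.lead_id)]
                if len(proxies):
                    snp_id = str(proxies[0])
                    pos = int(lead.pos) + 1  # placeholder coordinate for the proxy
            else:
                snp_id = f"{lead.lead_id}_proxy"

        if reported_kind == "true":
            reported, expected = lead.protein_gene, "confirmed"
        elif reported_kind == "decoy":
            reported, expected = ctx["decoy_gene"], "novel_reassignment"
        else:  # list
            reported = f"{lead.protein_gene}, {ctx['decoy_gene']}"
            expected = "refined"

        mapped = ctx["nearest_gene"] if reported_kind == "decoy" else lead.protein_gene
        cat_rows.append(
            {
                "SNPS": snp_id,
                "CHR_ID": lead.chrom,
                "CHR_POS": pos,
                "DISEASE/TRAIT": f"trait_{k}",
                "REPORTED GENE(S)": reported,
                "MAPPED_GENE": mapped,
                "RISK_ALLELE": "A",
                "OR/BETA": round(float(rng.uniform(0.05, 0.5)), 3),
                "P-VALUE": float(10 ** -rng.uniform(8.5, 30)),
            }
        )
        label_rows.append(
            {"set_id": lead.set_id, "scenario": scen, "expected_class": expected}
        )

    # unrelated filler rows: fail the catalog invariants or match nothing
    for u in range(n_unrelated):
        cat_rows.append(
            {
                "SNPS": f"rs_unrelated_{u}",
                "CHR_ID": "9",
                "CHR_POS": 10_000_000 + u,
                "DISEASE/TRAIT": f"unrelated_trait_{u}",
                "REPORTED GENE(S)": "OTHER1",
                "MAPPED_GENE": "OTHER1",
                "RISK_ALLELE": "A" if u % 2 else "",
                "OR/BETA": 0.1 if u % 2 else np.nan,
                "P-VALUE": 1e-9 if u != 1 else 1e-6,
            }
        )
    catalog = pd.DataFrame(cat_rows, columns=CATALOG_COLUMNS)

    if burden_spec is None:
        g = list(genes["protein_gene"])
        first = g[0]
        burden_spec = pd.DataFrame(
            [
                # duplicate masks for one gene-trait pair: keep-most-significant
                {"gene": first, "trait": "lipids", "mask": "pLoF",
                 "beta": 0.25, "se": 0.04, "p": 1e-8},
                {"gene": first, "trait": "lipids", "mask": "pLoF+missense",
                 "beta": 0.18, "se": 0.035, "p": 1e-7},
                {"gene": g[min(1, len(g) - 1)], "trait": "glucose", "mask": "pLoF",
                 "beta": 0.05, "se": 0.05, "p": 0.3},
            ]
        )
    return catalog, burden_spec.copy(), pd.DataFrame(label_rows)
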