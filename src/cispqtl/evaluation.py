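"""Simulation studies that characterize the pipeline's operating
behaviour: fine-mapping recovery and multi-signal separation, screen
calibration for colocalization, null calibration of the sex-interaction
test, and the pairwise-equivalence check of the multi-trait reduction.

Each study is a pure function of its arguments including the seed and
returns plain floats, so the same code backs the test suite and the
reproduction script. Problem sizes default to the desk-scale study
conditions documented in the methods note.
"""

from __future__ import annotations

import numpy as np

from cispqtl.coloc import (
    ColocPosterior,
    coloc_abf,
    coloc_screen,
    multitrait_coloc,
    wakefield_labf,
)
from cispqtl.finemap import select_L_grid, sex_interaction_test
from cispqtl.simulate import (
    SimTruth,
    simulate_genotypes,
    simulate_protein_trait,
    simulate_trait_pair,
)


def finemap_single_causal_study(
    n_regions: int = 200,
    n: int = 1000,
    m: int = 300,
    h2: float = 0.1,
    seed: int = 0,
) -> dict:
    """Credible-set coverage and set-count calibration on single-causal regions.

    Returns the fraction of regions whose 95% credible sets contain the
    true causal variant and the fraction where the grid search returns
    exactly one set.
    """
    rng = np.random.default_rng(seed)
    covered = single = 0
    for _ in range(n_regions):
        gseed, cseed, tseed = (int(s) for s in rng.integers(2**31, size=3))
        G = simulate_genotypes(n, m, seed=gseed)
        causal = int(np.random.default_rng(cseed).integers(0, m))
        truth = SimTruth({"p": [causal]}, {"p": [1.0]}, {"p": h2})
        y, _ = simulate_protein_trait(G, truth, seed=tseed, trait="p")
        _, sets = select_L_grid(G.dosages, y)
        if any(causal in cs.variant_indices for cs in sets):
            covered += 1
        if len(sets) == 1:
            single += 1
    return {
        "coverage_rate": covered / n_regions,
        "single_set_rate": single / n_regions,
        "n_regions": n_regions,
    }


def finemap_two_causal_study(
    n_regions: int = 100,
    n: int = 1000,
    m: int = 300,
    h2_each: float = 0.05,
    max_r2: float = 0.05,
    seed: int = 0,
) -> dict:
    """Separation of two low-LD causal variants into disjoint credible sets.

    Success means exactly two disjoint sets, one containing each causal,
    with cross-set r² bounded by the grid admissibility rule (asserted
    inside ``select_L_grid``).
    """
    rng = np.random.default_rng(seed)
    separated = 0
    for _ in range(n_regions):
        gseed, tseed = (int(s) for s in rng.integers(2**31, size=2))
        G = simulate_genotypes(n, m, seed=gseed)
        R = G.corr()
        local = np.random.default_rng(gseed + 1)
        for _ in range(100):  # rejection-sample a low-LD causal pair
            a, b = sorted(local.choice(m, size=2, replace=False))
            if R[a, b] ** 2 < max_r2:
                break
        else:
            continue
        truth = SimTruth({"p": [int(a), int(b)]}, {"p": [1.0, 1.0]},
                         {"p": 2 * h2_each})
        y, _ = simulate_protein_trait(G, truth, seed=tseed, trait="p")
        _, sets = select_L_grid(G.dosages, y)
        hit_a = any(a in cs.variant_indices for cs in sets)
        hit_b = any(b in cs.variant_indices for cs in sets)
        if len(sets) == 2 and hit_a and hit_b:
            separated += 1
    return {"separation_rate": separated / n_regions, "n_regions": n_regions}


def coloc_screen_calibration(
    n_reps: int = 200,
    n: int = 5000,
    m: int = 600,
    h2: float = 0.05,
    seed: int = 0,
) -> dict:
    """Declared-colocalization rates for shared- vs distinct-causal pairs."""
    rng = np.random.default_rng(seed)
    rates = {}
    for mode in ("shared", "distinct"):
        declared = 0
        for _ in range(n_reps):
            gseed, pseed = (int(s) for s in rng.integers(2**31, size=2))
            G = simulate_genotypes(n, m, seed=gseed)
            sa, sb, ld, _ = simulate_trait_pair(G, mode, h2, h2, seed=pseed)
            rec = coloc_screen(sa, sb, ld)
            declared += int(rec.colocalized)
        rates[f"{mode}_declared_rate"] = declared / n_reps
    rates["n_reps"] = n_reps
    return rates


def independent_pair_null_rate(
    n_reps: int = 100,
    n: int = 2000,
    m: int = 200,
    seed: int = 0,
    lead_p: float = 1e-6,
) -> float:
    """Fraction of independent-mode pairs whose null trait never reaches
    suggestive significance (the screen's entry gate)."""
    rng = np.random.default_rng(seed)
    quiet = 0
    for _ in range(n_reps):
        gseed, pseed = (int(s) for s in rng.integers(2**31, size=2))
        G = simulate_genotypes(n, m, seed=gseed)
        _, sb, _, _ = simulate_trait_pair(G, "independent", 0.05, 0.0, seed=pseed)
        if float(sb.table["pval"].min()) > lead_p:
            quiet += 1
    return quiet / n_reps


def sex_interaction_null_study(
    n_reps: int = 1000,
    n: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the genotype-by-sex interaction test under the null.

    Genotype and sex are fixed across replicates; the trait has a real
    genotype effect but identical slopes in both sexes.
    """
    rng = np.random.default_rng(seed)
    G = simulate_genotypes(n, 1, seed=int(rng.integers(2**31)))
    g = G.dosages[:, 0]
    sex = G.sex
    rejections = 0
    for _ in range(n_reps):
        y = 0.3 * g + rng.standard_normal(n)
        res = sex_interaction_test(g, y, sex)
        rejections += int(res["p_interaction"] < alpha)
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def multitrait_pairwise_agreement(
    n_reps: int = 20,
    n: int = 2000,
    m: int = 100,
    h2: float = 0.05,
    p12: float = 1e-6,
    p1: float = 1e-4,
    seed: int = 0,
) -> dict:
    """Agreement of the two-trait multi-trait reduction with the pairwise
    posterior on strong shared signals, under matched priors p1·γ = p12."""
    rng = np.random.default_rng(seed)
    gamma = p12 / p1
    max_diff = 0.0
    for _ in range(n_reps):
        gseed, pseed = (int(s) for s in rng.integers(2**31, size=2))
        G = simulate_genotypes(n, m, seed=gseed)
        sa, sb, _, _ = simulate_trait_pair(G, "shared", h2, h2, seed=pseed)
        la = wakefield_labf(sa)
        lb = wakefield_labf(sb)
        pp4 = coloc_abf(la, lb, p1=p1, p2=p1, p12=p12).pp4
        clusters = multitrait_coloc(np.vstack([la, lb]), p1=p1, gamma=gamma,
                                    pp_threshold=0.0)
        pp_shared = clusters[0]["pp_shared"] if clusters else 0.0
        max_diff = max(max_diff, abs(pp_shared - pp4))
    return {"max_abs_diff": max_diff, "n_reps": n_reps}


def brute_force_coloc(
    labf1: np.ndarray,
    labf2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-6,
) -> ColocPosterior:
    """Direct enumeration over all causal-variant configurations.

    Sums Bayes factors configuration by configuration in plain arithmetic
    (no log-space shortcuts): one causal SNP for each trait, diagonal
    configurations forming the shared hypothesis. Serves as the oracle
    for ``coloc_abf`` on small regions.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    q = labf1.size
    bf1 = np.exp(labf1)
    bf2 = np.exp(labf2)
    h0 = 1.0
    h1 = p1 * bf1.sum()
    h2 = p2 * bf2.sum()
    h3 = 0.0
    h4 = 0.0
    for i in range(q):
        for j in range(q):
            if i == j:
                h4 += p12 * bf1[i] * bf2[j]
            else:
                h3 += p1 * p2 * bf1[i] * bf2[j]
    total = h0 + h1 + h2 + h3 + h4
    return ColocPosterior(h0 / total, h1 / total, h2 / total, h3 / total,
                          h4 / total, priors=(p1, p2, p12), n_overlap=q)


def coloc_enumeration_check(n_instances: int = 50, q: int = 10, seed: int = 0) -> dict:
    """Maximum deviation of the log-space posterior from brute-force
    enumeration on random small instances."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_instances):
        labf1 = rng.uniform(-2, 12, size=q)
        labf2 = rng.uniform(-2, 12, size=q)
        fast = coloc_abf(labf1, labf2).as_array()
        slow = brute_force_coloc(labf1, labf2).as_array()
        max_err = max(max_err, float(np.abs(fast - slow).max()))
    return {"max_abs_err": max_err, "n_instances": n_instances}
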