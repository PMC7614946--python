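"""Shared in-memory containers for genotype and summary-statistic data.

Coordinates are 1-based inclusive (GWAS/VCF convention) on GRCh37-style
contigs. Dosages are expected-allele-count values in [0, 2] for the
effect allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

VARIANT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele", "maf"]

SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: Strand-ambiguous allele pairs that cannot be harmonized by flipping.
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GenotypeMatrix:
    """Sample-by-variant dosage matrix with variant metadata.

    Attributes
    ----------
    dosages:
        ``(n, m)`` array of effect-allele dosages in ``[0, 2]``.
    variants:
        Data frame with columns ``id, chrom, pos, effect_allele,
        other_allele, maf``; ``pos`` strictly increasing per chromosome.
    samples:
        Sample identifiers, length ``n``.
    sex:
        Optional per-sample binary indicator (1 = female by convention).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant table length does not match dosage columns")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample list length does not match dosage rows")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["id"])

    def validate(self) -> None:
        """Check generation invariants; raise ``ValueError`` on violation."""
        if np.isnan(self.dosages).any():
            raise ValueError("missing dosages present")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages outside [0, 2]")
        freqs = self.dosages.mean(axis=0) / 2.0
        if (freqs <= 0).any() or (freqs >= 1).any():
            raise ValueError("monomorphic variant present (empirical frequency 0 or 1)")
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError("positions not strictly increasing within chromosome")

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (mean 0, unit variance)."""
        X = self.dosages
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        if (sd == 0).any():
            raise ValueError("cannot standardize monomorphic variants")
        return (X - mu) / sd

    def corr(self) -> np.ndarray:
        """Pairwise genotype correlation (LD on the r scale)."""
        return np.corrcoef(self.dosages, rowvar=False)

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            variants=self.variants.reset_index(drop=True),
            samples=[self.samples[i] for i in np.atleast_1d(idx)],
            sex=None if self.sex is None else self.sex[idx],
        )


@dataclass
class RegionalSummaryStats:
    """Per-variant marginal association summaries for one trait in a region.

    ``table`` has columns ``variant_id, chrom, pos, effect_allele,
    other_allele, eaf, beta, se, pval, n``. For binary traits analysed by
    linear regression, ``case_fraction`` records the case proportion used
    to convert linear-scale coefficients to log odds ratios.
    """

    trait_id: str
    table: pd.DataFrame
    trait_type: str = "quant"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quant", "binary"):
            raise ValueError(f"trait_type must be quant or binary, got {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.case_fraction is None or not 0 < self.case_fraction < 1:
                raise ValueError("binary traits need a case_fraction in (0,1)")
        missing = [c for c in SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary table missing columns: {missing}")

    def validate(self, z_tol: float = 1e-6) -> list[str]:
        """Check invariants; return a list of warnings for z/p inconsistency."""
        t = self.table
        if (t["se"] <= 0).any():
            raise ValueError("non-positive standard errors present")
        if ((t["pval"] <= 0) | (t["pval"] > 1)).any():
            raise ValueError("p-values outside (0, 1]")
        z = np.abs(t["beta"] / t["se"])
        p_from_z = 2 * stats.norm.sf(z)
        bad = np.abs(p_from_z - t["pval"].to_numpy()) > z_tol
        warnings = []
        for vid in t.loc[bad, "variant_id"]:
            warnings.append(f"z/p inconsistency beyond tolerance at {vid}")
        return warnings

    @property
    def lead(self) -> pd.Series:
        """Row of the variant with the smallest p-value (the sentinel)."""
        return self.table.loc[self.table["pval"].idxmin()]


@dataclass
class RunManifest:
    """Provenance record: config, seeds, digests, and per-stage counts."""

    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def add_count(self, stage: str, key: str, value) -> None:
        self.counts.setdefault(stage, {})[key] = value

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seeds": self.seeds,
            "input_digests": self.input_digests,
            "counts": self.counts,
            "timestamps": self.timestamps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunManifest":
        return cls(
            config=d.get("config", {}),
            seeds=d.get("seeds", {}),
            input_digests=d.get("input_digests", {}),
            counts=d.get("counts", {}),
            timestamps=d.get("timestamps", {}),
        )
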