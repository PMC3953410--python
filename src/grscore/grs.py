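"""Genetic risk score construction.

The score is the unweighted count of BMI-increasing alleles over a SNP
subset: overall (all panel SNPs), EA (European-ancestry discovery set), EAA
(East-Asian discovery set), or a custom rsID list.  Missing genotypes are
mean-imputed with the SNP's average allele count on the analysis sample;
individuals missing more than ``max_missing`` subset genotypes are excluded
and reported rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .panel_io import GenotypeMatrix, SnpPanelRecord

__all__ = ["GrsVector", "GrsSummary", "compute_grs", "grs_summary"]

DEFAULT_MAX_MISSING = 3


@dataclass
class GrsVector:
    """Per-individual risk-allele counts for one SNP subset."""

    individual_ids: list[str]
    score: np.ndarray
    n_missing_imputed: np.ndarray
    subset_name: str
    snps_used: list[str]
    excluded: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        hi = 2.0 * len(self.snps_used)
        if self.score.size and (self.score.min() < 0 or self.score.max() > hi):
            raise ValueError("score outside [0, 2·n_snps]")

    def __len__(self) -> int:
        return len(self.individual_ids)


class GrsSummary(NamedTuple):
    mean: float
    sd: float
    min: float
    max: float
    n: int


def _resolve_subset(panel: Sequence[SnpPanelRecord],
                    subset: str | Sequence[str]) -> tuple[str, list[str]]:
    if isinstance(subset, str):
        name = subset
        if subset == "overall":
            ids = [r.rsid for r in panel]
        elif subset == "ea":
            ids = [r.rsid for r in panel if r.in_ea_set]
        elif subset == "eaa":
            ids = [r.rsid for r in panel if r.in_eaa_set]
        else:
            raise ValueError(f"unknown subset {subset!r}; use overall/ea/eaa or an rsID list")
    else:
        name, ids = "custom", list(subset)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rsIDs in custom subset")
    if not ids:
        raise ValueError(f"subset {name!r} selects no SNPs")
    return name, ids


def compute_grs(genotypes: GenotypeMatrix, panel: Sequence[SnpPanelRecord],
                subset: str | Sequence[str] = "overall",
                max_missing: int = DEFAULT_MAX_MISSING,
                impute_from_eaf: bool = False) -> GrsVector:
    """Sum effect-allele dosages over a subset, mean-imputing missing ones.

    The imputation mean is each SNP's average non-missing dosage computed on
    the delivered analysis sample (individuals within the missingness cap).
    ``impute_from_eaf=True`` substitutes the panel expectation 2·EAF instead,
    for scoring samples too small to estimate a mean.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be ≥ 0")
    name, ids = _resolve_subset(panel, subset)
    absent = [s for s in ids if s not in genotypes.snp_ids]
    if absent:
        raise ValueError(f"subset SNPs absent from genotype matrix: {absent}")
    cols = [genotypes.snp_ids.index(s) for s in ids]
    dose = genotypes.dosage[:, cols]
    miss = np.isnan(dose)
    n_miss = miss.sum(axis=1)
    keep = n_miss <= max_missing
    excluded = [(iid, int(k)) for iid, k, ok in
                zip(genotypes.individual_ids, n_miss, keep) if not ok]

    kept_dose = dose[keep]
    kept_miss = miss[keep]
    if impute_from_eaf:
        eaf = {r.rsid: r.eaf for r in panel}
        fill = np.array([2.0 * eaf[s] for s in ids])
    else:
        n_obs = (~kept_miss).sum(axis=0)
        if (n_obs == 0).any():
            bad = [ids[j] for j in np.flatnonzero(n_obs == 0)]
            raise ValueError(f"SNPs with no observed dosages (mean undefined): {bad}")
        fill = np.nansum(kept_dose, axis=0) / n_obs
    filled = np.where(kept_miss, fill, kept_dose)
    return GrsVector(
        individual_ids=[iid for iid, ok in zip(genotypes.individual_ids, keep) if ok],
        score=filled.sum(axis=1),
        n_missing_imputed=kept_miss.sum(axis=1).astype(int),
        subset_name=name,
        snps_used=ids,
        excluded=excluded,
    )


def grs_summary(grs: GrsVector) -> GrsSummary:
    """Sample mean, SD (n−1), min, max and n of the scores."""
    if len(grs) == 0:
        raise ValueError("empty score vector")
    if len(grs) < 2:
        raise ValueError("SD undefined for a single score")
    s = grs.score
    return GrsSummary(mean=float(s.mean()), sd=float(s.std(ddof=1)),
                      min=float(s.min()), max=float(s.max()), n=len(grs))
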