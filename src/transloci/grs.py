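"""Weighted genetic risk scores from discovery loci.

Variants are carried into a score only if they survive in *every* study
supplied: present, common (MAF >= 0.01), well imputed (info >= 0.8 where an
info metric exists) and allele-consistent with the discovery table.  Of each
correlated pair (r^2 > 0.1 in the pruning reference) the variant with the
larger discovery p is removed.  Scores are weighted sums of effect-allele
dosages using discovery betas and are standardized to mean 0, sd 1, so a
regression of a standardized biomarker on the score estimates their
correlation directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .assoc import LdMatrix, standardize
from .errors import ValidationError
from .io import GenotypePanel

GRS_SIGNIFICANCE_P = 0.0056  # 0.05 / 9: three scores by three biomarkers

MAF_MIN = 0.01
INFO_MIN = 0.8
PRUNE_R2_CAP = 0.1


@dataclass
class GrsModel:
    """A harmonized, filtered, LD-pruned weighted variant set."""

    trait: str
    variants: pd.DataFrame  # chrom, pos, rsid, effect_allele, other_allele, discovery_p
    weights: np.ndarray  # discovery betas, effect-allele oriented
    exclusion_report: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant", "reason"])
    )

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.variants):
            raise ValidationError("one weight per variant required")


def _study_maf(study, chrom: str, pos: int):
    """(present, maf, info) of a variant in a study panel or stats table."""
    if isinstance(study, GenotypePanel):
        hit = (study.variants["chrom"].astype(str) == chrom) & (study.variants["pos"] == pos)
        if not hit.any():
            return False, np.nan, np.nan
        j = int(np.flatnonzero(hit)[0])
        return True, float(study.mafs[j]), np.nan
    hit = (study["chrom"].astype(str) == chrom) & (study["pos"] == pos)
    if not hit.any():
        return False, np.nan, np.nan
    row = study.loc[hit].iloc[0]
    eaf = float(row["eaf"]) if np.isfinite(row.get("eaf", np.nan)) else np.nan
    maf = min(eaf, 1 - eaf) if np.isfinite(eaf) else np.nan
    info = float(row["info"]) if np.isfinite(row.get("info", np.nan)) else np.nan
    return True, maf, info


def _study_alleles(study, chrom: str, pos: int) -> set[str] | None:
    if isinstance(study, GenotypePanel):
        hit = (study.variants["chrom"].astype(str) == chrom) & (study.variants["pos"] == pos)
        if not hit.any():
            return None
        row = study.variants.loc[hit].iloc[0]
    else:
        hit = (study["chrom"].astype(str) == chrom) & (study["pos"] == pos)
        if not hit.any():
            return None
        row = study.loc[hit].iloc[0]
    return {str(row["ref"]), str(row["alt"])}


def filter_variants(
    discovery: pd.DataFrame,
    studies: Sequence,
    maf_min: float = MAF_MIN,
    info_min: float = INFO_MIN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersection filter across studies.

    ``discovery`` needs columns ``chrom, pos, effect_allele, other_allele,
    beta, p`` (plus optional rsid/trait).  A variant is kept iff it is
    present in every study, has MAF >= ``maf_min`` everywhere, info >=
    ``info_min`` where an info metric exists, and its allele pair matches
    the discovery alleles.  Returns (kept table, exclusion report).
    """
    reasons: list[tuple[str, str]] = []
    keep_rows = []
    for _, row in discovery.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        label = f"{chrom}:{pos}"
        disc_alleles = {str(row["effect_allele"]), str(row["other_allele"])}
        reason = None
        for study in studies:
            present, maf, info = _study_maf(study, chrom, pos)
            if not present:
                reason = "absent"
                break
            if np.isfinite(maf) and maf < maf_min:
                reason = "rare"
                break
            if np.isfinite(info) and info < info_min:
                reason = "badly_imputed"
                break
            alleles = _study_alleles(study, chrom, pos)
            if alleles is not None and alleles != disc_alleles:
                reason = "allele_mismatch"
                break
        if reason is None:
            keep_rows.append(row)
        else:
            reasons.append((label, reason))
    report = pd.DataFrame(reasons, columns=["variant", "reason"])
    kept = pd.DataFrame(keep_rows).reset_index(drop=True)
    if kept.empty:
        raise ValidationError("no variant survives the cross-study filters")
    return kept, report


def ld_prune(
    variants: pd.DataFrame,
    ld: LdMatrix,
    r2_cap: float = PRUNE_R2_CAP,
) -> pd.DataFrame:
    """Greedy best-p-first pruning of correlated pairs.

    Variants are visited in ascending discovery p (position tie-break); a
    variant correlated at r^2 > ``r2_cap`` with any already-kept variant is
    dropped — i.e. the larger-p member of every violating pair is removed.
    """
    order = variants.sort_values(["p", "chrom", "pos"]).index
    ld_index = {}
    for idx in order:
        row = variants.loc[idx]
        ld_index[idx] = ld.index_of(str(row["chrom"]), int(row["pos"]))
    kept: list = []
    for idx in order:
        i = ld_index[idx]
        if all(ld.r2[i, ld_index[k]] <= r2_cap for k in kept):
            kept.append(idx)
    pruned = variants.loc[sorted(kept, key=lambda i: (variants.loc[i, "chrom"], variants.loc[i, "pos"]))]
    # post-hoc assertion of the invariant
    ids = [ld_index[k] for k in pruned.index]
    sub = ld.r2[np.ix_(ids, ids)]
    off = sub[~np.eye(len(ids), dtype=bool)]
    if off.size and off.max() > r2_cap:
        raise AssertionError("pruned set violates the r^2 cap")  # pragma: no cover
    return pruned.reset_index(drop=True)


def build_model(
    trait: str,
    kept: pd.DataFrame,
    exclusion_report: pd.DataFrame | None = None,
) -> GrsModel:
    return GrsModel(
        trait=trait,
        variants=kept.reset_index(drop=True),
        weights=kept["beta"].to_numpy(dtype=float),
        exclusion_report=(
            exclusion_report
            if exclusion_report is not None
            else pd.DataFrame(columns=["variant", "reason"])
        ),
    )


def build_score(panel: GenotypePanel, model: GrsModel) -> np.ndarray:
    """Per-sample standardized weighted score.

    Model variants must all be present in the (harmonized) panel — missing
    variants are an error, not silently skipped, because cross-study
    comparability is the point of the intersection filter.  Dosages are
    oriented to the model effect allele before weighting.
    """
    cols = []
    pos_index = {
        (str(c), int(p)): j
        for j, (c, p) in enumerate(zip(panel.variants["chrom"], panel.variants["pos"]))
    }
    for _, row in model.variants.iterrows():
        key = (str(row["chrom"]), int(row["pos"]))
        if key not in pos_index:
            raise ValidationError(f"model variant {key} absent from scoring panel")
        j = pos_index[key]
        alt = str(panel.variants["alt"].iloc[j])
        ref = str(panel.variants["ref"].iloc[j])
        eff = str(row["effect_allele"])
        if eff == alt:
            cols.append(panel.dosages[:, j])
        elif eff == ref:
            cols.append(2.0 - panel.dosages[:, j])
        else:
            raise ValidationError(
                f"effect allele {eff} matches neither allele of panel variant {key}; "
                "harmonize the panel first"
            )
    raw = np.column_stack(cols) @ model.weights
    if raw.std() == 0:
        raise ValidationError("raw score has zero variance; cannot standardize")
    return standardize(raw)


@dataclass
class GrsAssociation:
    """Score-biomarker correlation estimate."""

    score_trait: str
    outcome_trait: str
    r: float
    se: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < GRS_SIGNIFICANCE_P


def associate_score(
    score: np.ndarray,
    phenotype: np.ndarray,
    score_trait: str = "",
    outcome_trait: str = "",
) -> GrsAssociation:
    """OLS of the standardized phenotype on the standardized score.

    The slope equals the sample Pearson correlation; the p-value is the
    score test ``z = r * sqrt(n)``.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if s.size != y.size:
        raise ValidationError("score and phenotype lengths differ")
    n = s.size
    s = standardize(s)
    y = standardize(y)
    r = float(s @ y / n)
    se = float(np.sqrt(max(1.0 - r**2, 0.0) / max(n - 2, 1)))
    z = r * np.sqrt(n)
    p = float(max(2.0 * ndtr(-abs(z)), np.finfo(float).tiny))
    return GrsAssociation(score_trait, outcome_trait, r=r, se=se, p=p, n=n)


def cross_trait_matrix(
    scores: dict[str, np.ndarray], phenotypes: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Score x biomarker correlation matrix (diagonal = target lipid)."""
    out = pd.DataFrame(index=list(scores), columns=list(phenotypes), dtype=float)
    for st, s in scores.items():
        for ot, y in phenotypes.items():
            out.loc[st, ot] = associate_score(s, y, st, ot).r
    return out
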