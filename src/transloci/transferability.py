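"""Credible-set reproducibility of established loci in a target study.

A discovery locus is *reproducible* in a target study when some member of
its credible set — the lead variant plus all variants correlated with it at
r^2 > 0.6 in an ancestry-matched reference panel — is associated in the
target at p < 1e-3 (score test).  Failing that, an association anywhere
within 25 Kb either side of the lead counts as a weaker, region-level hit.
The 1e-3 threshold is justified empirically per study: fewer than 5% of
random 50 Kb windows should attain a minimum p below it.

Loci with discovery p < 1e-100 are called *major*; rate tables stratify by
trait, major/minor status and outcome category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assoc import LdMatrix
from .errors import ConfigurationError, ValidationError
from .io import VariantKey

log = logging.getLogger(__name__)

MAJOR_P = 1e-100
DEFAULT_P_THRESHOLD = 1e-3
DEFAULT_REGION_HALFWIDTH = 25_000
DEFAULT_CREDIBLE_R2 = 0.6

CATEGORIES = ("credible_set_hit", "region_hit", "not_significant")


@dataclass(frozen=True)
class Locus:
    """An established discovery-study locus."""

    lead: VariantKey
    trait: str
    discovery_p: float

    def __post_init__(self) -> None:
        if not 0 < self.discovery_p < 1:
            raise ValidationError("discovery_p must lie in (0, 1)")

    @property
    def major(self) -> bool:
        return self.discovery_p < MAJOR_P


@dataclass
class CredibleSet:
    """Lead variant plus its r^2 > threshold LD companions."""

    locus: Locus
    members: list[VariantKey]
    reference_panel_label: str = ""

    def __post_init__(self) -> None:
        positions = {(v.chrom, v.pos) for v in self.members}
        if (self.locus.lead.chrom, self.locus.lead.pos) not in positions:
            raise ValidationError("credible set must contain its lead variant")


@dataclass
class ReproducibilityCall:
    """Outcome of classifying one locus in a target study.

    ``category`` is one of :data:`CATEGORIES`, or ``'indeterminate'`` when
    the target study has no variant at all within the locus region (surfaced
    explicitly rather than folded into not_significant).
    """

    locus: Locus
    category: str
    best_p_credible: float
    best_p_region: float


def dedup_loci(
    hits: Iterable[tuple[VariantKey, str, float]], window_bp: int = 50_000
) -> list[Locus]:
    """Keep only the most strongly associated variant per locus.

    Greedy pass in ascending discovery p; a hit within ``window_bp`` of an
    already-kept hit on the same chromosome for the same trait is absorbed.
    """
    entries = sorted(hits, key=lambda h: (h[2], h[0].chrom, h[0].pos))
    kept: list[Locus] = []
    for key, trait, p in entries:
        absorbed = any(
            k.trait == trait
            and k.lead.chrom == key.chrom
            and abs(k.lead.pos - key.pos) <= window_bp
            for k in kept
        )
        if not absorbed:
            kept.append(Locus(lead=key, trait=trait, discovery_p=p))
    return kept


def build_credible_set(
    locus: Locus,
    ld: LdMatrix,
    r2_threshold: float = DEFAULT_CREDIBLE_R2,
    reference_panel_label: str = "",
) -> CredibleSet:
    """Members are the lead plus variants with r^2 strictly above the
    threshold in the supplied reference panel (never target-panel LD)."""
    lead_idx = ld.index_of(locus.lead.chrom, locus.lead.pos)
    r2 = ld.r2[lead_idx]
    member_idx = sorted({lead_idx, *np.flatnonzero(r2 > r2_threshold)})
    return CredibleSet(
        locus=locus,
        members=[ld.variants[i] for i in member_idx],
        reference_panel_label=reference_panel_label,
    )


@dataclass
class EmpiricalThresholdResult:
    proportion: float
    passed: bool
    min_p: np.ndarray
    n_windows: int


def empirical_threshold(
    target: pd.DataFrame,
    n_windows: int = 1000,
    width_bp: int = 50_000,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    max_proportion: float = 0.05,
    seed=None,
) -> EmpiricalThresholdResult:
    """Calibrate the reproducibility p threshold on random windows.

    Draws ``n_windows`` windows of ``width_bp`` uniformly over the positions
    covered by the target summary statistics, records each window's minimum
    p, and passes when fewer than ``max_proportion`` of windows have a
    minimum below ``p_threshold``.
    """
    rng = np.random.default_rng(seed)
    spans = []
    for chrom, grp in target.groupby("chrom"):
        lo, hi = int(grp["pos"].min()), int(grp["pos"].max())
        if hi - lo >= width_bp:
            spans.append((chrom, lo, hi - width_bp))
    total = sum(hi - lo + 1 for _, lo, hi in spans)
    if total < n_windows:
        raise ConfigurationError(
            f"covered span ({total} candidate start positions) cannot host "
            f"{n_windows} windows; use fewer or narrower windows"
        )
    weights = np.array([hi - lo + 1 for _, lo, hi in spans], dtype=float)
    weights /= weights.sum()
    by_chrom = {c: g for c, g in target.groupby("chrom")}
    min_p = np.empty(n_windows)
    filled = 0
    attempts = 0
    while filled < n_windows:
        attempts += 1
        if attempts > 50 * n_windows:
            raise ConfigurationError("could not place windows containing variants")
        k = rng.choice(len(spans), p=weights)
        chrom, lo, hi = spans[k]
        start = int(rng.integers(lo, hi + 1))
        grp = by_chrom[chrom]
        inside = grp["p"][(grp["pos"] >= start) & (grp["pos"] <= start + width_bp)]
        if inside.empty:
            continue
        min_p[filled] = float(inside.min())
        filled += 1
    proportion = float(np.mean(min_p < p_threshold))
    return EmpiricalThresholdResult(
        proportion=proportion,
        passed=proportion < max_proportion,
        min_p=min_p,
        n_windows=n_windows,
    )


def classify_locus(
    cs: CredibleSet,
    target: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    region_halfwidth: int = DEFAULT_REGION_HALFWIDTH,
) -> ReproducibilityCall:
    """Table-1-style classification of one locus against target statistics.

    ``credible_set_hit`` if any credible-set member reaches p < threshold in
    the target; else ``region_hit`` if any variant within the +/-25 Kb region
    does; else ``not_significant``.  Credible-set members missing from the
    target are tolerated (logged).  A region with no target variant at all is
    ``indeterminate``.
    """
    lead = cs.locus.lead
    member_pos = {(v.chrom, v.pos) for v in cs.members}
    on_chrom = target[target["chrom"].astype(str) == str(lead.chrom)]
    in_region = on_chrom[
        (on_chrom["pos"] >= lead.pos - region_halfwidth)
        & (on_chrom["pos"] <= lead.pos + region_halfwidth)
    ]
    member_mask = [
        (str(c), int(p)) in member_pos
        for c, p in zip(on_chrom["chrom"], on_chrom["pos"])
    ]
    members_found = on_chrom.loc[member_mask]
    n_missing = len(member_pos) - len(members_found)
    if n_missing:
        log.debug(
            "locus %s:%s — %d credible-set member(s) absent from target",
            lead.chrom, lead.pos, n_missing,
        )
    best_p_credible = float(members_found["p"].min()) if len(members_found) else np.nan
    best_p_region = float(in_region["p"].min()) if len(in_region) else np.nan

    if in_region.empty and members_found.empty:
        category = "indeterminate"
    elif np.isfinite(best_p_credible) and best_p_credible < p_threshold:
        category = "credible_set_hit"
    elif np.isfinite(best_p_region) and best_p_region < p_threshold:
        category = "region_hit"
    else:
        category = "not_significant"
    return ReproducibilityCall(
        locus=cs.locus,
        category=category,
        best_p_credible=best_p_credible,
        best_p_region=best_p_region,
    )


def rate_table(calls: Sequence[ReproducibilityCall]) -> pd.DataFrame:
    """Percentage of loci per category, stratified by trait x major/minor.

    Indeterminate calls are excluded from the percentages (reported in the
    ``n_indeterminate`` column); within each stratum the three category
    percentages sum to 100 up to rounding.  Empty strata are NA.
    """
    rows = []
    traits = sorted({c.locus.trait for c in calls})
    for trait in traits:
        for major in (True, False):
            sub = [c for c in calls if c.locus.trait == trait and c.locus.major == major]
            det = [c for c in sub if c.category != "indeterminate"]
            row = {
                "trait": trait,
                "major": major,
                "n_loci": len(det),
                "n_indeterminate": len(sub) - len(det),
            }
            for cat in CATEGORIES:
                row[f"pct_{cat}"] = (
                    100.0 * sum(c.category == cat for c in det) / len(det)
                    if det
                    else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
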