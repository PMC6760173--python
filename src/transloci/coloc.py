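"""Trans-ethnic colocalization via joint likelihood mapping.

Tests whether the association signal at a locus is driven by the same causal
variant in two cohorts with different ancestry, comparing a reference
cohort's summary statistics (plus ancestry-matched LD) against a target
cohort's raw genotypes and phenotype.

Under the single-causal-variant model the score statistics are multivariate
normal, ``z ~ N(lam * r_.i, R)`` for causal variant i with non-centrality
``lam``.  Profiling over ``lam`` gives the causal likelihood

    L(i) proportional to exp(z_i^2 / 2),

normalized over the window.  The colocalization statistic contrasts the
target's likelihood mass inside versus outside the LD neighbourhood of the
reference lead ``m*`` (``N_theta(i) = {j : r^2(i, j) >= theta}``):

    Lambda = sum_{i in N1_theta(m*)} L1(i)
             * log[ L1(i) L2(i) / max_{j not in N2_theta(i)} L1(i) L2(j) ]

Positive Lambda indicates a shared signal.  Significance comes from a
permutation test: the target phenotype is shuffled, the target score scan
and Lambda recomputed (reference statistics and both LD matrices fixed), and
the add-one estimator ``p = (1 + #{Lambda_b >= Lambda_obs}) / (B + 1)``
reported; ties count toward the numerator.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

from .assoc import LdMatrix, ld_matrix, standardize, standardize_dosages, score_test_z
from .errors import ConfigurationError, ValidationError
from .io import GenotypePanel, VariantKey
from .transferability import Locus

DEFAULT_THETA = 0.8
MHC_CHROM = "6"
MHC_START = 28_477_797
MHC_END = 33_448_354

STATUS_OK = "ok"
STATUS_SINGLE_SNP = "failed_single_snp"
STATUS_NO_COMPLEMENT = "failed_no_complement"
STATUS_MHC = "excluded_mhc"
STATUS_TOO_FEW = "failed_too_few_variants"
STATUS_LEAD_MISSING = "failed_lead_missing"


@dataclass
class ColocInput:
    """Harmonized inputs for one locus/cohort pair.

    ``z1``/``ld1`` describe the reference cohort over the window (LD from an
    ancestry-matched panel); the target cohort contributes raw dosages and a
    prepared phenotype.  ``lead`` indexes the reference lead variant m*
    within the window.
    """

    z1: np.ndarray
    ld1: LdMatrix
    target_dosages: np.ndarray
    target_phenotype: np.ndarray
    lead: int
    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        m = len(self.z1)
        if self.ld1.r.shape != (m, m) or self.target_dosages.shape[1] != m:
            raise ValidationError("z1, ld1 and target panel must share variant keys")
        if not 0 < self.theta < 1:
            raise ConfigurationError("theta must lie in (0, 1)")
        if not 0 <= self.lead < m:
            raise ValidationError("lead index outside the window")


@dataclass
class ColocResult:
    lambda_stat: float
    p_jlim: float
    n_permutations: int
    status: str
    n_window_variants: int = 0
    lead: VariantKey | None = None

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def single_causal_likelihood(z: np.ndarray, ld: LdMatrix | None = None) -> np.ndarray:
    """Normalized profile likelihood of each window variant being causal.

    The profile over the non-centrality parameter reduces the MVN density to
    ``L(i) proportional to exp(z_i^2 / 2)`` regardless of R (the brute-force
    MVN evaluation is kept as a test oracle); the LD argument is accepted
    for interface symmetry.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValidationError("empty window")
    if not np.all(np.isfinite(z)):
        raise ValidationError("non-finite z in window")
    w = z**2 / 2.0
    w -= w.max()
    e = np.exp(w)
    return e / e.sum()


def _neighbourhood_masks(
    ld1_r2: np.ndarray, ld2_r2: np.ndarray, lead: int, theta: float
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Summation set N1_theta(m*) and, per member i, the complement of
    N2_theta(i) in the target LD."""
    summed = np.flatnonzero(ld1_r2[lead] >= theta)
    complements = [np.flatnonzero(ld2_r2[i] < theta) for i in summed]
    return summed, complements


def _lambda_terms(
    log_l2: np.ndarray,
    l1: np.ndarray,
    summed: np.ndarray,
    complements: list[np.ndarray],
) -> tuple[np.ndarray, bool]:
    """Weighted log-ratio terms; ``log_l2`` may be (m,) or (m, B).

    Returns the summed statistic per column and whether any member
    contributed (members with an empty complement carry no term).
    """
    cols = log_l2.shape[1] if log_l2.ndim == 2 else 1
    log_l2 = np.atleast_2d(log_l2.T).T  # (m, cols)
    total = np.zeros(cols)
    any_term = False
    for i, comp in zip(summed, complements):
        if comp.size == 0:
            continue
        any_term = True
        total += l1[i] * (log_l2[i] - log_l2[comp].max(axis=0))
    return total, any_term


def jlim_lambda(
    l1: np.ndarray,
    l2: np.ndarray,
    ld1: LdMatrix | np.ndarray,
    ld2: LdMatrix | np.ndarray,
    lead: int,
    theta: float = DEFAULT_THETA,
) -> tuple[float, str]:
    """The colocalization statistic Lambda for one pair of likelihoods.

    ``ld1``/``ld2`` may be :class:`LdMatrix` or plain r^2 arrays.  Returns
    ``(lambda, status)``; Lambda is NaN unless the status is ok.
    """
    r2_1 = ld1.r2 if isinstance(ld1, LdMatrix) else np.asarray(ld1, float)
    r2_2 = ld2.r2 if isinstance(ld2, LdMatrix) else np.asarray(ld2, float)
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if l1.size < 2:
        return np.nan, STATUS_SINGLE_SNP
    summed, complements = _neighbourhood_masks(r2_1, r2_2, lead, theta)
    log_l2 = np.log(np.maximum(l2, np.finfo(float).tiny))
    total, any_term = _lambda_terms(log_l2, l1, summed, complements)
    if not any_term:
        return np.nan, STATUS_NO_COMPLEMENT
    return float(total[0]), STATUS_OK


def permutation_p(inp: ColocInput, n_permutations: int = 1000, seed=None) -> ColocResult:
    """Permutation p-value for the observed Lambda.

    The observed statistic uses target score-test z's; each permutation
    shuffles the target phenotype across samples and recomputes the target
    scan and Lambda with L1, ld1 and ld2 held fixed.  The observed and
    permuted statistics share one vectorized code path, so the test is exact
    for an exchangeable null phenotype.
    """
    if n_permutations < 100:
        raise ConfigurationError("need at least 100 permutations")
    n = inp.target_dosages.shape[0]
    if n < 50:
        raise ConfigurationError("target panel must have at least 50 samples")
    rng = np.random.default_rng(seed)
    m = len(inp.z1)
    lead_key = inp.ld1.variants[inp.lead] if inp.ld1.variants is not None else None
    if m < 2:
        return ColocResult(np.nan, np.nan, 0, STATUS_SINGLE_SNP, m, lead_key)

    xs, sd = standardize_dosages(inp.target_dosages)
    if np.any(sd == 0):
        raise ValidationError("monomorphic variant in target window; filter first")
    ld2 = np.corrcoef(inp.target_dosages, rowvar=False) ** 2
    ys = standardize(inp.target_phenotype)

    summed, complements = _neighbourhood_masks(inp.ld1.r2, ld2, inp.lead, inp.theta)
    l1 = single_causal_likelihood(inp.z1)

    perms = np.empty((n, n_permutations), dtype=float)
    for b in range(n_permutations):
        perms[:, b] = ys[rng.permutation(n)]
    y_all = np.column_stack([ys, perms])
    z2 = score_test_z(xs, y_all)  # m x (B+1)
    # log L2 up to the per-column normalizer, which cancels in the ratio
    log_l2 = z2**2 / 2.0
    totals, any_term = _lambda_terms(log_l2, l1, summed, complements)
    if not any_term:
        return ColocResult(np.nan, np.nan, 0, STATUS_NO_COMPLEMENT, m, lead_key)
    lam_obs, lam_perm = float(totals[0]), totals[1:]
    p = (1.0 + np.sum(lam_perm >= lam_obs)) / (n_permutations + 1.0)
    return ColocResult(lam_obs, float(p), n_permutations, STATUS_OK, m, lead_key)


def in_mhc(chrom: str, start: int, end: int) -> bool:
    """Does [start, end] on ``chrom`` overlap the MHC region
    (chr6:28,477,797-33,448,354)?"""
    return str(chrom).removeprefix("chr") == MHC_CHROM and not (
        end < MHC_START or start > MHC_END
    )


def run_coloc(
    locus: Locus,
    ref_stats: pd.DataFrame,
    ref_ld_panel: GenotypePanel,
    target_panel: GenotypePanel,
    target_phenotype: np.ndarray,
    theta: float = DEFAULT_THETA,
    n_permutations: int = 1000,
    halfwidth: int = 25_000,
    min_shared: int = 5,
    seed=None,
) -> ColocResult:
    """Colocalization for one established locus.

    Builds the lead +/- ``halfwidth`` window (50 Kb total by default) over
    variants shared by the reference statistics, the reference LD panel and
    the target panel (polymorphic in both panels), excludes loci overlapping
    the MHC, and runs the permutation test.
    """
    lead = locus.lead
    if in_mhc(lead.chrom, lead.pos - halfwidth, lead.pos + halfwidth):
        return ColocResult(np.nan, np.nan, 0, STATUS_MHC, 0, lead)

    stats = ref_stats[
        (ref_stats["chrom"].astype(str) == str(lead.chrom))
        & (ref_stats["pos"] >= lead.pos - halfwidth)
        & (ref_stats["pos"] <= lead.pos + halfwidth)
    ]
    stat_by_pos = {int(p): i for i, p in zip(stats.index, stats["pos"])}

    ref_pos = {
        (str(c), int(p)): j
        for j, (c, p) in enumerate(zip(ref_ld_panel.variants["chrom"], ref_ld_panel.variants["pos"]))
    }
    tgt_pos = {
        (str(c), int(p)): j
        for j, (c, p) in enumerate(zip(target_panel.variants["chrom"], target_panel.variants["pos"]))
    }
    ref_sd = ref_ld_panel.dosages.std(axis=0)
    tgt_sd = target_panel.dosages.std(axis=0)

    shared: list[tuple[int, int, int]] = []  # (stats row, ref panel col, target col)
    for (c, p), j_ref in ref_pos.items():
        if c != str(lead.chrom) or p not in stat_by_pos or (c, p) not in tgt_pos:
            continue
        j_tgt = tgt_pos[(c, p)]
        if ref_sd[j_ref] == 0 or tgt_sd[j_tgt] == 0:
            continue
        shared.append((stat_by_pos[p], j_ref, j_tgt))
    shared.sort(key=lambda t: int(ref_stats["pos"].loc[t[0]]))

    if len(shared) < min_shared:
        return ColocResult(np.nan, np.nan, 0, STATUS_TOO_FEW, len(shared), lead)
    positions = [int(ref_stats["pos"].loc[i]) for i, _, _ in shared]
    if lead.pos not in positions:
        return ColocResult(np.nan, np.nan, 0, STATUS_LEAD_MISSING, len(shared), lead)

    z1 = ref_stats["z"].loc[[i for i, _, _ in shared]].to_numpy(dtype=float)
    ld1 = ld_matrix(ref_ld_panel, [j for _, j, _ in shared])
    dosages = target_panel.dosages[:, [j for _, _, j in shared]]
    inp = ColocInput(
        z1=z1,
        ld1=ld1,
        target_dosages=dosages,
        target_phenotype=np.asarray(target_phenotype, dtype=float),
        lead=positions.index(lead.pos),
        theta=theta,
    )
    return permutation_p(inp, n_permutations=n_permutations, seed=seed)
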