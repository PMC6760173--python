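"""Two-population genotype and phenotype simulation.

The generator emulates the two statistical features that trans-ethnic locus
analyses are sensitive to, without needing managed-access cohort data:

* **LD within a locus** — ancestral haplotypes are built as recombinant
  mosaics of a small founder set, so pairwise r^2 decays with distance at a
  rate set by ``recomb_rate``.
* **Cross-population divergence** — each study population draws its
  per-variant allele frequency from the Balding-Nichols drift distribution
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the ancestral frequency ``p``, and
  its haplotypes are resampled from the ancestral pool with per-entry allele
  flips that move every variant to its drifted frequency.  The flips also
  perturb haplotype structure, so LD divergence between populations grows
  with F alongside frequency divergence.

Phenotypes follow the additive single-variant model
``y_i = beta * (x_i - 1) + eta_i`` with ``eta_i ~ N(0, sigma^2)`` i.i.d.,
where ``x_i`` is the alt-allele dosage at the causal variant.  ``sigma^2``
defaults to 1 so phenotypes are on the standardized-trait scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ScenarioError, SimulationError
from .io import GenotypePanel

# non-palindromic ref/alt pairs assigned to simulated variants
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class PopulationModel:
    """Parameters of the ancestral haplotype pool.

    ``recomb_rate`` is the per-base founder-switch probability of the mosaic
    process; ``divergence_f`` the Balding-Nichols drift parameter used when
    populations are derived from the pool; ``maf_floor`` the minimum
    ancestral allele frequency.
    """

    n_variants: int = 100
    n_ancestral_haplotypes: int = 500
    n_founders: int = 12
    divergence_f: float = 0.1
    recomb_rate: float = 3e-5
    maf_floor: float = 0.05
    window_bp: int = 50_000
    chrom: str = "1"
    start_pos: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_variants < 2:
            raise ConfigurationError("n_variants must be >= 2")
        if self.n_founders < 1:
            raise ConfigurationError("at least one founder haplotype is required")
        if not 0 <= self.divergence_f < 1:
            raise ConfigurationError("divergence_f must lie in [0, 1)")
        if not 0 <= self.maf_floor < 0.5:
            raise ConfigurationError("maf_floor must lie in [0, 0.5)")
        if self.recomb_rate < 0:
            raise ConfigurationError("recomb_rate must be non-negative")


@dataclass
class HaplotypePool:
    """Binary ancestral haplotypes plus variant metadata."""

    haplotypes: np.ndarray  # n_haplotypes x n_variants, 0/1
    variants: pd.DataFrame  # chrom, pos, ref, alt, rsid
    ancestral_freqs: np.ndarray  # design frequencies the founders were drawn at

    @property
    def freqs(self) -> np.ndarray:
        """Realized alt-allele frequency in the pool."""
        return self.haplotypes.mean(axis=0)


def simulate_ancestral_haplotypes(model: PopulationModel, seed=None) -> HaplotypePool:
    """Build the ancestral haplotype pool as founder mosaics.

    With ``recomb_rate == 0`` every pool haplotype is an exact copy of a
    founder; as the rate grows the mosaic segments shrink and pairwise LD
    approaches linkage equilibrium.
    """
    rng = _as_rng(seed)
    v = model.n_variants
    h = model.n_ancestral_haplotypes
    k = model.n_founders
    p = rng.uniform(model.maf_floor, 1.0 - model.maf_floor, size=v)
    founders = (rng.random((k, v)) < p[None, :]).astype(np.int8)

    spacing = max(1, model.window_bp // v)
    pos = model.start_pos + np.arange(v) * spacing
    switch_p = 1.0 - np.exp(-model.recomb_rate * np.diff(pos))

    idx = np.empty((h, v), dtype=np.int64)
    idx[:, 0] = rng.integers(0, k, size=h)
    for j in range(1, v):
        switch = rng.random(h) < switch_p[j - 1]
        fresh = rng.integers(0, k, size=h)
        idx[:, j] = np.where(switch, fresh, idx[:, j - 1])
    haplotypes = founders[idx, np.arange(v)[None, :]]

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=v)
    variants = pd.DataFrame(
        {
            "chrom": model.chrom,
            "pos": pos,
            "ref": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "alt": [_ALLELE_PAIRS[i][1] for i in pair_idx],
            "rsid": [f"sim{model.chrom}_{p_}" for p_ in pos],
        }
    )
    return HaplotypePool(haplotypes=haplotypes, variants=variants, ancestral_freqs=p)


def derive_population(
    pool: HaplotypePool,
    divergence_f: float,
    n_samples: int,
    seed=None,
    label: str = "",
) -> GenotypePanel:
    """Draw one study population from the ancestral pool under drift F.

    Population allele frequencies are Balding-Nichols draws around the
    realized pool frequencies (``F = 0`` leaves them unchanged); genotypes
    pair resampled pool haplotypes whose entries are flipped just enough to
    realize the drifted frequencies in expectation.
    """
    if not 0 <= divergence_f < 1:
        raise ConfigurationError("divergence_f must lie in [0, 1)")
    if n_samples < 2:
        raise ConfigurationError("n_samples must be >= 2")
    rng = _as_rng(seed)
    p = pool.freqs
    if divergence_f > 0:
        f = divergence_f
        scale = (1.0 - f) / f
        interior = (p > 0) & (p < 1)
        q = p.copy()
        q[interior] = rng.beta(p[interior] * scale, (1.0 - p[interior]) * scale)
    else:
        q = p.copy()

    idx = rng.integers(0, pool.haplotypes.shape[0], size=2 * n_samples)
    haps = pool.haplotypes[idx].astype(np.int8)

    with np.errstate(divide="ignore", invalid="ignore"):
        up = np.where(p < 1, np.clip((q - p) / (1.0 - p), 0, 1), 0.0)
        down = np.where(p > 0, np.clip((p - q) / p, 0, 1), 0.0)
    u = rng.random(haps.shape)
    flip_up = (haps == 0) & (u < up[None, :])
    flip_down = (haps == 1) & (u < down[None, :])
    haps[flip_up] = 1
    haps[flip_down] = 0

    dosages = (haps[0::2] + haps[1::2]).astype(float)
    return GenotypePanel(
        sample_ids=[f"{label or 'S'}{i}" for i in range(n_samples)],
        variants=pool.variants.copy(),
        dosages=dosages,
        population_label=label,
        pop_freqs=q,
    )


@dataclass
class PhenotypeSimSpec:
    """Single-causal-variant additive phenotype model."""

    beta: float
    causal_index: int
    sigma2: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ConfigurationError("sigma2 must be positive")


def simulate_phenotype(panel: GenotypePanel, spec: PhenotypeSimSpec, rng=None) -> np.ndarray:
    """``y = beta * (x - 1) + eta`` with ``eta ~ N(0, sigma^2)`` i.i.d."""
    if not 0 <= spec.causal_index < panel.n_variants:
        raise SimulationError(f"causal_index {spec.causal_index} out of range")
    x = panel.dosages[:, spec.causal_index]
    if x.std() == 0:
        raise SimulationError("causal variant is monomorphic in this panel")
    rng = _as_rng(spec.seed if rng is None else rng)
    eta = rng.normal(0.0, np.sqrt(spec.sigma2), size=panel.n_samples)
    return spec.beta * (x - 1.0) + eta


@dataclass
class ScenarioSpec:
    """Paired-cohort simulation scenario.

    ``kind='shared'`` uses one causal variant in both cohorts;
    ``kind='distinct'`` uses two causal variants.  For distinct scenarios,
    ``distinct_mode='in_window'`` draws both causals inside the locus with
    reference-panel r^2 below ``max_r2_distinct``, while
    ``distinct_mode='unlinked'`` places the target-cohort causal at an
    unlinked locus (a genome-scale discordant draw at desk scale): its
    dosage is an independent Hardy-Weinberg variant.
    """

    kind: Literal["shared", "distinct"]
    beta: float
    max_r2_distinct: float = 0.2
    window_bp: int = 50_000
    sigma2: float = 1.0
    maf_min: float = 0.05
    distinct_mode: Literal["in_window", "unlinked"] = "in_window"


@dataclass
class Scenario:
    """Realized scenario: phenotypes plus ground truth."""

    spec: ScenarioSpec
    y_ref: np.ndarray
    y_target: np.ndarray
    causal_ref: int
    causal_target: int | None  # None when the target causal is unlinked
    causal_r2: float | None  # reference-panel r^2 between the causal pair
    x_target_causal: np.ndarray


def _r2_with(dosages: np.ndarray, j: int) -> np.ndarray:
    x = dosages - dosages.mean(axis=0, keepdims=True)
    sd = x.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x.T @ x[:, j]) / (dosages.shape[0] * sd * sd[j])
    r[~np.isfinite(r)] = 0.0
    return r**2


def make_scenario(
    spec: ScenarioSpec,
    panel_ref: GenotypePanel,
    panel_target: GenotypePanel,
    seed=None,
) -> Scenario:
    """Draw causal variants (uniformly among MAF > ``maf_min`` candidates)
    and simulate phenotypes for both cohorts."""
    rng = _as_rng(seed)
    if panel_ref.n_variants != panel_target.n_variants or not panel_ref.variants[
        ["chrom", "pos"]
    ].equals(panel_target.variants[["chrom", "pos"]]):
        raise ScenarioError("panels must share variant keys")
    eligible = np.flatnonzero(
        (panel_ref.mafs > spec.maf_min) & (panel_target.mafs > spec.maf_min)
    )
    if eligible.size == 0:
        raise ScenarioError("no variant with MAF above the floor in both panels")

    c1 = int(rng.choice(eligible))
    causal_target: int | None
    causal_r2: float | None
    if spec.kind == "shared":
        causal_target, causal_r2 = c1, 1.0
        x2 = panel_target.dosages[:, c1]
    elif spec.distinct_mode == "in_window":
        r2 = _r2_with(panel_ref.dosages, c1)
        cand = eligible[r2[eligible] < spec.max_r2_distinct]
        cand = cand[cand != c1]
        if cand.size == 0:
            raise ScenarioError(
                "no candidate causal pair below the LD ceiling "
                f"r^2 < {spec.max_r2_distinct}; widen the window"
            )
        causal_target = int(rng.choice(cand))
        causal_r2 = float(r2[causal_target])
        x2 = panel_target.dosages[:, causal_target]
    else:  # unlinked
        q = rng.uniform(spec.maf_min, 1.0 - spec.maf_min)
        x2 = rng.binomial(2, q, size=panel_target.n_samples).astype(float)
        if x2.std() == 0:  # pragma: no cover - vanishing probability
            x2[rng.integers(panel_target.n_samples)] = 1.0
        causal_target, causal_r2 = None, None

    y_ref = simulate_phenotype(
        panel_ref, PhenotypeSimSpec(spec.beta, c1, spec.sigma2), rng=rng
    )
    eta = rng.normal(0.0, np.sqrt(spec.sigma2), size=panel_target.n_samples)
    y_target = spec.beta * (x2 - 1.0) + eta
    return Scenario(
        spec=spec,
        y_ref=y_ref,
        y_target=y_target,
        causal_ref=c1,
        causal_target=causal_target,
        causal_r2=causal_r2,
        x_target_causal=x2,
    )
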