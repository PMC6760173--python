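"""Core association statistics.

Phenotype preparation (rank-based inverse normal transform, covariate
residualization, Friedewald LDL derivation), vectorized per-variant score
tests and LD estimation.

The score test used throughout is the correlation form: for standardized
trait ``y`` and dosage ``x``, ``z = r_xy * sqrt(n)`` with a two-sided normal
tail p-value.  ``beta`` and ``se`` are the matching univariate OLS quantities
on the standardized trait, so ``z == beta / se`` exactly.  Association in
the source study was mixed-model based; on unrelated (synthetic) samples the
OLS score test is the appropriate equivalent and is what every downstream
stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .errors import ConfigurationError, TransformError, ValidationError
from .io import GenotypePanel, SUMSTAT_COLUMNS, VariantKey

BLOM_OFFSET = 0.375  # Blom's c = 3/8

#: Friedewald triglyceride validity limit and divisor per unit system
_FRIEDEWALD = {"mg_dl": (400.0, 5.0), "mmol_l": (4.52, 2.2)}


def inverse_normal_transform(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset by default).

    ``out_i = ndtri((rank_i - c) / (n - 2c + 1))``; ties get average ranks,
    so the transform is deterministic and rank-preserving.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise TransformError("need a 1-d vector with n >= 3")
    if not np.all(np.isfinite(x)):
        raise TransformError("input contains non-finite values")
    if np.all(x == x[0]):
        raise TransformError("all values identical; ranks are undefined")
    ranks = rankdata(x, method="average")
    q = (ranks - offset) / (x.size - 2.0 * offset + 1.0)
    return ndtri(q)


def friedewald_ldl(total_chol, hdl, tg, units: str) -> np.ndarray:
    """LDL = TC - HDL - TG/5 (mg/dL) or TC - HDL - TG/2.2 (mmol/L).

    Entries with triglycerides above the validity limit (400 mg/dL /
    4.52 mmol/L) are returned as NaN; the formula is invalid there.
    Units must be stated explicitly, never guessed.
    """
    if units not in _FRIEDEWALD:
        raise ConfigurationError(f"units must be one of {sorted(_FRIEDEWALD)}")
    limit, divisor = _FRIEDEWALD[units]
    tc = np.asarray(total_chol, dtype=float)
    hd = np.asarray(hdl, dtype=float)
    tri = np.asarray(tg, dtype=float)
    if np.any(tc < 0) or np.any(hd < 0) or np.any(tri < 0):
        raise ValidationError("lipid measurements must be non-negative")
    ldl = tc - hd - tri / divisor
    return np.where(tri > limit, np.nan, ldl)


def residualize(y, covariates=None, names: Sequence[str] | None = None) -> np.ndarray:
    """Residuals of ``y`` after OLS on covariates plus an intercept.

    With no covariates this mean-centers ``y``.  Rank-deficient designs
    raise an error naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if covariates is None:
        return y - y.mean()
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != n:
        c = c.T
    x = np.column_stack([np.ones(n), c])
    names = list(names) if names is not None else [f"covariate_{j}" for j in range(c.shape[1])]
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            names[j]
            for j in range(c.shape[1])
            if np.linalg.matrix_rank(np.delete(x, j + 1, axis=1)) == rank
        ]
        raise ValidationError(f"collinear covariate columns: {collinear}")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef


def standardize(x) -> np.ndarray:
    """Scale to mean 0, sd 1 (population sd)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValidationError("cannot standardize a zero-variance vector")
    return (x - x.mean()) / sd


@dataclass
class LdMatrix:
    """Pearson dosage correlations for a variant subset."""

    variants: list[VariantKey] | None
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.variants is not None and self.r.shape != (
            len(self.variants),
            len(self.variants),
        ):
            raise ValidationError("LD matrix shape does not match variant list")

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def index_of(self, chrom: str, pos: int) -> int:
        for i, v in enumerate(self.variants):
            if v.chrom == str(chrom) and v.pos == int(pos):
                return i
        raise KeyError(f"variant {chrom}:{pos} not in LD matrix")


def ld_matrix(panel: GenotypePanel, subset: Sequence[int] | None = None) -> LdMatrix:
    """Pearson correlation of dosage columns; r^2 is the elementwise square."""
    idx = np.arange(panel.n_variants) if subset is None else np.asarray(subset, int)
    d = panel.dosages[:, idx]
    if d.shape[0] < 2:
        raise ValidationError("need at least 2 samples to estimate LD")
    if np.any(d.std(axis=0) == 0):
        bad = idx[np.flatnonzero(d.std(axis=0) == 0)]
        raise ValidationError(f"monomorphic variant(s) in LD subset: {bad.tolist()[:5]}")
    r = np.corrcoef(d, rowvar=False)
    keys = [panel.variant_keys()[i] for i in idx]
    return LdMatrix(variants=keys, r=r)


def regularize_ld(r: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Shrink toward the identity: ``(R + ridge*I) / (1 + ridge)``.

    Keeps unit diagonal and guarantees eigenvalues >= ridge/(1+ridge) for a
    PSD input, making downstream inversion safe.
    """
    m = r.shape[0]
    return (r + ridge * np.eye(m)) / (1.0 + ridge)


def standardize_dosages(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize a dosage matrix; returns (X_std, sd) with sd=0
    columns zeroed out (callers must exclude them from scoring)."""
    mu = dosages.mean(axis=0, keepdims=True)
    sd = dosages.std(axis=0)
    safe = np.where(sd == 0, 1.0, sd)
    xs = (dosages - mu) / safe[None, :]
    xs[:, sd == 0] = 0.0
    return xs, sd


def score_test_z(x_std: np.ndarray, y_std: np.ndarray) -> np.ndarray:
    """Vectorized score statistics ``Z = X'Y / sqrt(n)`` for standardized
    inputs.  ``y_std`` may be a matrix of phenotype columns (n x B), which is
    the permutation-friendly form: one matmul scores every permutation."""
    n = x_std.shape[0]
    return (x_std.T @ y_std) / np.sqrt(n)


def score_test_scan(panel: GenotypePanel, y) -> pd.DataFrame:
    """Per-variant score-test scan; returns a summary-statistics table.

    ``y`` is standardized internally (idempotent for already-prepared
    phenotypes).  Zero-variance variants are excluded with a warning column
    rather than scored.
    """
    ys = standardize(y)
    n = panel.n_samples
    if ys.size != n:
        raise ValidationError("phenotype length does not match panel samples")
    xs, sd = standardize_dosages(panel.dosages)
    poly = sd > 0
    z = np.full(panel.n_variants, np.nan)
    z[poly] = score_test_z(xs[:, poly], ys)
    p = 2.0 * ndtr(-np.abs(z))
    r = z / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = r / sd
        se = 1.0 / (sd * np.sqrt(n))
    freqs = panel.freqs
    df = panel.variants.copy().reset_index(drop=True)
    df["effect_allele"] = df["alt"]
    df["beta"] = beta
    df["se"] = se
    df["z"] = z
    df["p"] = p
    df["eaf"] = freqs
    df["n"] = n
    df["info"] = np.nan
    df = df.loc[poly, list(SUMSTAT_COLUMNS)].reset_index(drop=True)
    # clamp p away from 0 so the (0, 1] invariant holds at extreme z
    df["p"] = df["p"].clip(lower=np.finfo(float).tiny)
    return df
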