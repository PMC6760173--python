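"""Readers, writers and allele harmonization for external data representations.

Two tabular contracts are used throughout the package:

* **Summary statistics** are a :class:`pandas.DataFrame` with the canonical
  columns ``chrom, pos, rsid, ref, alt, effect_allele, beta, se, z, p, eaf,
  n, info``.  ``beta`` is the per-allele effect on a standardized trait,
  ``z`` the score statistic and ``p`` its two-sided normal tail.  Optional
  columns (``rsid``, ``eaf``, ``n``, ``info``) are present but may hold NaN.
* **Genotypes** are a :class:`GenotypePanel`: a dense samples x variants
  dosage matrix (alt-allele counts or imputed dosages in [0, 2]) plus a
  variant table and a population label.

Coordinates are 1-based inclusive (VCF convention) everywhere; window
arithmetic downstream uses closed intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import SchemaError, UnsupportedFormatError, ValidationError

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical summary-statistics columns, in output order
SUMSTAT_COLUMNS = (
    "chrom", "pos", "rsid", "ref", "alt", "effect_allele",
    "beta", "se", "z", "p", "eaf", "n", "info",
)
_MANDATORY = ("chrom", "pos", "ref", "alt", "beta", "se", "p")
_NUMERIC = ("pos", "beta", "se", "z", "p", "eaf", "n", "info")


class VariantKey(NamedTuple):
    """Identity of a biallelic variant: 1-based position plus alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None

    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypePanel:
    """Dense dosage matrix with variant metadata for one population.

    ``dosages`` is ``n_samples x n_variants`` with entries in [0, 2];
    ``variants`` is a DataFrame with columns ``chrom, pos, ref, alt, rsid``.
    ``pop_freqs``, when set by the simulator, holds the population (parameter)
    alt-allele frequencies as opposed to the realized sample frequencies.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    population_label: str = ""
    pop_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValidationError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def freqs(self) -> np.ndarray:
        """Realized alt-allele frequency per variant, mean(dosage)/2."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def mafs(self) -> np.ndarray:
        f = self.freqs
        return np.minimum(f, 1.0 - f)

    def variant_keys(self) -> list[VariantKey]:
        return [
            VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt),
                       None if pd.isna(r.rsid) else str(r.rsid))
            for r in self.variants.itertuples()
        ]

    def subset_variants(self, index: Sequence[int]) -> "GenotypePanel":
        index = np.asarray(index, dtype=int)
        return GenotypePanel(
            sample_ids=self.sample_ids,
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
            population_label=self.population_label,
            pop_freqs=None if self.pop_freqs is None else self.pop_freqs[index],
        )

    def subset_samples(self, index: Sequence[int]) -> "GenotypePanel":
        index = np.asarray(index, dtype=int)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in index],
            variants=self.variants.copy(),
            dosages=self.dosages[index, :],
            population_label=self.population_label,
            pop_freqs=self.pop_freqs,
        )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _check_alleles(df: pd.DataFrame) -> None:
    for col in ("ref", "alt"):
        vals = df[col].astype(str)
        bad = ~vals.str.fullmatch(r"[ACGT]+")
        if bad.any():
            raise ValidationError(
                f"column '{col}' contains non-ACGT or empty alleles in rows "
                f"{df.index[bad].tolist()[:5]}"
            )


def _check_duplicates(df: pd.DataFrame) -> None:
    key = [
        (c, p, tuple(sorted((r, a))))
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    dup = pd.Series(key).duplicated()
    if dup.any():
        dups = sorted({key[i] for i in np.flatnonzero(dup.to_numpy())})
        raise ValidationError(f"duplicate variant keys: {dups[:5]}")


def validate_summary_stats(df: pd.DataFrame, p_rtol: float = 1e-6) -> None:
    """Check the SummaryStats invariants.

    ``p_rtol`` is the relative tolerance for agreement between ``p`` and the
    two-sided normal tail of ``z``.  Internally produced tables satisfy 1e-6;
    externally read tables with rounded p-values need a looser tolerance.
    """
    _check_alleles(df)
    _check_duplicates(df)
    if (df["pos"] < 1).any():
        raise ValidationError("positions must be >= 1 (1-based coordinates)")
    p = df["p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        bad = np.flatnonzero((p <= 0) | (p > 1) | ~np.isfinite(p))
        raise ValidationError(f"p-values outside (0, 1] in rows {bad.tolist()[:5]}")
    ea = df["effect_allele"].astype(str)
    mismatch = ~((ea == df["ref"].astype(str)) | (ea == df["alt"].astype(str)))
    if mismatch.any():
        raise ValidationError(
            "effect_allele must be one of ref/alt; offending rows "
            f"{df.index[mismatch].tolist()[:5]}"
        )
    if "eaf" in df and df["eaf"].notna().any():
        eaf = df["eaf"].to_numpy(dtype=float)
        bad = np.isfinite(eaf) & ((eaf <= 0) | (eaf >= 1))
        if bad.any():
            raise ValidationError(
                f"effect-allele frequencies outside (0, 1) in rows "
                f"{np.flatnonzero(bad).tolist()[:5]}"
            )
    z = df["z"].to_numpy(dtype=float)
    ok = np.isfinite(z)
    # clamp the normal tail to the smallest positive float: stored p-values
    # are clamped the same way so the (0, 1] invariant can hold at extreme z
    p_from_z = np.maximum(2.0 * ndtr(-np.abs(z[ok])), np.finfo(float).tiny)
    rel = np.abs(p_from_z - p[ok]) / np.maximum(p[ok], np.finfo(float).tiny)
    if np.any(rel > p_rtol):
        worst = float(rel.max())
        raise ValidationError(
            f"|z| does not reproduce p within rtol={p_rtol:g} "
            f"(worst relative deviation {worst:.3g})"
        )


def read_summary_stats(
    path,
    dialect: Mapping[str, str] | None = None,
    p_rtol: float = 1e-2,
) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics table.

    ``dialect`` maps canonical column names (see :data:`SUMSTAT_COLUMNS`) to
    the column names used in the file; canonical names already present in the
    header need not be mapped.  ``z`` is derived as ``beta/se`` when absent,
    and ``effect_allele`` defaults to ``alt``.  Row order is preserved.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    dialect = dict(dialect or {})
    rename = {v: k for k, v in dialect.items() if v in raw.columns}
    raw = raw.rename(columns=rename)
    for col in _MANDATORY:
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column '{col}' in {path}")
    df = pd.DataFrame(index=raw.index)
    for col in SUMSTAT_COLUMNS:
        if col in raw.columns:
            df[col] = raw[col]
        else:
            df[col] = np.nan
    for col in _NUMERIC:
        orig = df[col].copy()
        df[col] = pd.to_numeric(df[col], errors="coerce")
        garbled = df[col].isna() & orig.notna() & (orig.astype(str).str.strip() != "")
        if garbled.any():
            line = int(df.index[garbled][0]) + 2  # +1 header, +1 one-based
            raise ValidationError(
                f"unparseable numeric value {orig[garbled].iloc[0]!r} in column "
                f"'{col}' at line {line} of {path}"
            )
    df["pos"] = df["pos"].astype(int)
    for col in ("chrom", "ref", "alt"):
        df[col] = df[col].astype(str).str.upper()
    df["chrom"] = df["chrom"].str.removeprefix("CHR")
    if df["effect_allele"].isna().all():
        df["effect_allele"] = df["alt"]
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    if df["z"].isna().all():
        df["z"] = df["beta"] / df["se"]
    validate_summary_stats(df, p_rtol=p_rtol)
    return df


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write summary statistics losslessly (round-trips to 1e-12)."""
    out = df.loc[:, list(SUMSTAT_COLUMNS)]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _finalize_panel(
    sample_ids: list[str],
    variants: list[dict],
    dosages: np.ndarray,
    population_label: str,
) -> GenotypePanel:
    vdf = pd.DataFrame(variants, columns=["chrom", "pos", "ref", "alt", "rsid"])
    keys = list(zip(vdf["chrom"], vdf["pos"], vdf["ref"], vdf["alt"]))
    dup = pd.Series(keys).duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"duplicate variant keys in genotype input: "
            f"{sorted(set(k for k, d in zip(keys, dup) if d))[:5]}"
        )
    poly = dosages.std(axis=0) > 0
    n_mono = int((~poly).sum())
    if n_mono:
        warnings.warn(
            f"dropped {n_mono} monomorphic variant(s) from genotype input",
            stacklevel=3,
        )
    return GenotypePanel(
        sample_ids=sample_ids,
        variants=vdf.loc[poly].reset_index(drop=True),
        dosages=dosages[:, poly],
        population_label=population_label,
    )


def _read_vcf(path, population_label: str) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[dict] = []
    columns: list[np.ndarray] = []
    n_imputed = 0
    for var in vcf:
        if len(var.ALT) != 1:
            raise UnsupportedFormatError(
                f"multi-allelic site at {var.CHROM}:{var.POS}; split before loading"
            )
        ds = None
        try:
            fmt = var.FORMAT
        except Exception:  # pragma: no cover - cyvcf2 without FORMAT
            fmt = []
        if "DS" in fmt:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            gts = var.genotypes
            ds = np.empty(len(gts), dtype=float)
            for i, g in enumerate(gts):
                alleles = g[:-1]  # last element is the phasing flag
                if len(alleles) != 2:
                    raise UnsupportedFormatError(
                        f"mixed ploidy at {var.CHROM}:{var.POS} (sample "
                        f"{sample_ids[i]} has {len(alleles)} allele(s))"
                    )
                if any(a < 0 for a in alleles):
                    ds[i] = np.nan
                else:
                    ds[i] = sum(1 for a in alleles if a == 1)
        missing = ~np.isfinite(ds)
        if missing.any():
            if missing.all():
                ds[:] = 0.0
            else:
                ds[missing] = ds[~missing].mean()
            n_imputed += int(missing.sum())
        variants.append(
            dict(chrom=str(var.CHROM).removeprefix("chr"), pos=int(var.POS),
                 ref=str(var.REF).upper(), alt=str(var.ALT[0]).upper(),
                 rsid=var.ID)
        )
        columns.append(ds)
    dosages = (
        np.column_stack(columns) if columns
        else np.empty((len(sample_ids), 0))
    )
    if n_imputed:
        log.info("mean-imputed %d missing genotype(s) from %s", n_imputed, path)
    return _finalize_panel(sample_ids, variants, dosages, population_label)


def _read_dosage_matrix(path, population_label: str) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id":
        raise SchemaError("dosage matrix must have 'sample_id' as first column")
    sample_ids = df["sample_id"].astype(str).tolist()
    variants = []
    for col in df.columns[1:]:
        parts = col.split(":")
        if len(parts) not in (4, 5):
            raise SchemaError(
                f"variant column '{col}' is not 'chrom:pos:ref:alt[:rsid]'"
            )
        variants.append(
            dict(chrom=parts[0], pos=int(parts[1]), ref=parts[2].upper(),
                 alt=parts[3].upper(), rsid=parts[4] if len(parts) == 5 else None)
        )
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    missing = ~np.isfinite(dosages)
    if missing.any():
        col_means = np.nanmean(np.where(missing, np.nan, dosages), axis=0)
        col_means = np.nan_to_num(col_means)
        dosages = np.where(missing, col_means[None, :], dosages)
        log.info("mean-imputed %d missing dosage(s) from %s", int(missing.sum()), path)
    return _finalize_panel(sample_ids, variants, dosages, population_label)


def read_genotypes(path, format: str | None = None, population_label: str = "") -> GenotypePanel:
    """Read genotypes from a VCF (GT or DS) or a plain dosage-matrix TSV.

    GT calls are converted to alt-allele counts; missing entries are imputed
    to the variant mean dosage (logged); monomorphic variants are dropped
    with a warning.
    """
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz", ".bcf")) else "dosage_matrix"
    if format == "vcf":
        return _read_vcf(path, population_label)
    if format == "dosage_matrix":
        return _read_dosage_matrix(path, population_label)
    raise UnsupportedFormatError(f"unknown genotype format {format!r}")


def write_dosage_matrix(panel: GenotypePanel, path) -> None:
    cols = {}
    for j, key in enumerate(panel.variant_keys()):
        name = key.label() + (f":{key.rsid}" if key.rsid else "")
        cols[name] = panel.dosages[:, j]
    out = pd.DataFrame({"sample_id": panel.sample_ids, **cols})
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

def _orientation(t_eff: str, t_oth: str, r_eff: str, r_oth: str) -> str:
    """Resolve one of the 8 allele-orientation cases.

    Returns 'same', 'swap', 'same_flip', 'swap_flip', 'palindromic' or
    'mismatch'.  Palindromic pairs (A/T, C/G) are unresolvable because their
    strand flip equals their allele swap.
    """
    alleles = {t_eff, t_oth, r_eff, r_oth}
    if not alleles <= set("ACGT") or t_eff == t_oth or r_eff == r_oth:
        return "mismatch"
    if t_eff == COMPLEMENT[t_oth] or r_eff == COMPLEMENT[r_oth]:
        return "palindromic"
    if (t_eff, t_oth) == (r_eff, r_oth):
        return "same"
    if (t_eff, t_oth) == (r_oth, r_eff):
        return "swap"
    c_eff, c_oth = COMPLEMENT[t_eff], COMPLEMENT[t_oth]
    if (c_eff, c_oth) == (r_eff, r_oth):
        return "same_flip"
    if (c_eff, c_oth) == (r_oth, r_eff):
        return "swap_flip"
    return "mismatch"


def _match_reference(
    chrom: pd.Series, pos: pd.Series, rsid: pd.Series, reference: pd.DataFrame
) -> list[tuple[str, str] | None]:
    """Per target row, the reference (effect, other) alleles or None.

    Identity is resolved by (chrom, pos) first with rsid as a fallback key.
    """
    ref = reference.copy()
    ref["chrom"] = ref["chrom"].astype(str)
    by_pos = {(c, p): i for i, (c, p) in enumerate(zip(ref["chrom"], ref["pos"]))}
    by_rsid = {}
    if "rsid" in ref.columns:
        by_rsid = {
            r: i for i, r in enumerate(ref["rsid"]) if isinstance(r, str) and r
        }
    out: list[tuple[str, str] | None] = []
    for c, p, r in zip(chrom.astype(str), pos, rsid):
        i = by_pos.get((c, int(p)))
        if i is None and isinstance(r, str):
            i = by_rsid.get(r)
        out.append(
            None
            if i is None
            else (
                str(ref["effect_allele"].iloc[i]).upper(),
                str(ref["other_allele"].iloc[i]).upper(),
            )
        )
    return out


def harmonize_summary_stats(
    target: pd.DataFrame, reference: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Orient a summary-statistics table to a reference variant table.

    ``reference`` needs columns ``chrom, pos, effect_allele, other_allele``
    (``rsid`` optional, used as a fallback key).  Allele swaps flip the signs
    of ``beta`` and ``z`` and complement ``eaf``; unambiguous strand flips
    are resolved; palindromic and mismatched variants are excluded.  Returns
    the harmonized table and an exclusion report (columns variant, reason).
    """
    df = target.copy().reset_index(drop=True)
    matched = _match_reference(df["chrom"], df["pos"], df["rsid"], reference)
    keep = np.ones(len(df), dtype=bool)
    reasons: list[tuple[str, str]] = []
    for i in range(len(df)):
        label = f"{df['chrom'][i]}:{df['pos'][i]}:{df['ref'][i]}:{df['alt'][i]}"
        if matched[i] is None:
            keep[i] = False
            reasons.append((label, "unmatched"))
            continue
        r_eff, r_oth = matched[i]
        t_oth = df["ref"][i] if df["effect_allele"][i] == df["alt"][i] else df["alt"][i]
        orient = _orientation(df["effect_allele"][i], t_oth, r_eff, r_oth)
        if orient in ("palindromic", "mismatch"):
            keep[i] = False
            reasons.append((label, "palindromic" if orient == "palindromic" else "allele_mismatch"))
            continue
        if orient in ("swap", "swap_flip"):
            df.loc[i, "beta"] = -df.loc[i, "beta"]
            df.loc[i, "z"] = -df.loc[i, "z"]
            if np.isfinite(df.loc[i, "eaf"]):
                df.loc[i, "eaf"] = 1.0 - df.loc[i, "eaf"]
        # re-express alleles on the reference strand and effect orientation
        df.loc[i, "effect_allele"] = r_eff
        df.loc[i, "ref"] = r_oth
        df.loc[i, "alt"] = r_eff
    report = pd.DataFrame(reasons, columns=["variant", "reason"])
    return df.loc[keep].reset_index(drop=True), report


def harmonize_panel(
    panel: GenotypePanel, reference: pd.DataFrame
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Orient a genotype panel so the counted (alt) allele is the reference
    effect allele; swapped variants get dosage 2 - dosage."""
    vdf = panel.variants.copy().reset_index(drop=True)
    dosages = panel.dosages.copy()
    matched = _match_reference(vdf["chrom"], vdf["pos"], vdf["rsid"], reference)
    keep = np.ones(len(vdf), dtype=bool)
    reasons: list[tuple[str, str]] = []
    for i in range(len(vdf)):
        label = f"{vdf['chrom'][i]}:{vdf['pos'][i]}:{vdf['ref'][i]}:{vdf['alt'][i]}"
        if matched[i] is None:
            keep[i] = False
            reasons.append((label, "unmatched"))
            continue
        r_eff, r_oth = matched[i]
        orient = _orientation(str(vdf["alt"][i]), str(vdf["ref"][i]), r_eff, r_oth)
        if orient in ("palindromic", "mismatch"):
            keep[i] = False
            reasons.append((label, "palindromic" if orient == "palindromic" else "allele_mismatch"))
            continue
        if orient in ("swap", "swap_flip"):
            dosages[:, i] = 2.0 - dosages[:, i]
        vdf.loc[i, "alt"] = r_eff
        vdf.loc[i, "ref"] = r_oth
    report = pd.DataFrame(reasons, columns=["variant", "reason"])
    idx = np.flatnonzero(keep)
    out = GenotypePanel(
        sample_ids=panel.sample_ids,
        variants=vdf.loc[idx].reset_index(drop=True),
        dosages=dosages[:, idx],
        population_label=panel.population_label,
    )
    return out, report


def harmonize_alleles(target, reference: pd.DataFrame):
    """Dispatch to :func:`harmonize_summary_stats` or :func:`harmonize_panel`."""
    if isinstance(target, GenotypePanel):
        return harmonize_panel(target, reference)
    return harmonize_summary_stats(target, reference)


def write_exclusion_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
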