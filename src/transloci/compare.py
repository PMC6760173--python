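"""Transferable versus non-transferable loci, and BMI pleiotropy counts.

A locus is *transferable* when its reproducibility call is a credible-set
hit and its colocalization permutation p is below 0.05.  It is
*non-transferable* when every evidence stream argues against sharing:
colocalization non-significant or failed, no variant in the region
associated at p < 1e-3, and the discovery lead not rare in the target
population (so lack of signal is not a power artefact).  Everything else —
conflicting or missing evidence — is surfaced as indeterminate.

The packaged lookup ``data/bmi_lipid_lookup.tsv`` lists established lipid
loci with clear evidence for or against transferability to the Ugandan
cohort, together with their BMI associations from a large European-ancestry
meta-analysis (N >= 484,680), and supports the pleiotropy contrast: of each
label, how many loci are BMI-associated at a Bonferroni-adjusted threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import floor, log10
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coloc import ColocResult, STATUS_OK
from .errors import ConfigurationError, ValidationError
from .transferability import ReproducibilityCall

RARE_MAF = 0.01  # "not rare" bound, matching the GRS rarity filter

LABELS = ("transferable", "non_transferable", "indeterminate")


@dataclass
class TransferabilityLabel:
    locus_id: str
    trait: str
    label: str
    repro_category: str | None
    coloc_p: float
    coloc_status: str | None
    lead_maf: float


def label_loci(
    repro: Mapping[str, ReproducibilityCall],
    coloc: Mapping[str, ColocResult],
    target_mafs: Mapping[str, float],
    rare_threshold: float = RARE_MAF,
    coloc_alpha: float = 0.05,
) -> list[TransferabilityLabel]:
    """Combine evidence streams into one label per locus.

    All three mappings are keyed by a locus identifier (e.g.
    ``"trait:chrom:pos"``).  A locus missing any stream is indeterminate.
    """
    labels = []
    for locus_id, call in repro.items():
        res = coloc.get(locus_id)
        maf = target_mafs.get(locus_id, np.nan)
        if res is None or not np.isfinite(maf):
            labels.append(
                TransferabilityLabel(
                    locus_id, call.locus.trait, "indeterminate",
                    call.category, np.nan, None if res is None else res.status, maf,
                )
            )
            continue
        coloc_sig = res.status == STATUS_OK and res.p_jlim < coloc_alpha
        coloc_against = res.status != STATUS_OK or res.p_jlim > coloc_alpha
        if call.category == "credible_set_hit" and coloc_sig:
            label = "transferable"
        elif call.category == "not_significant" and coloc_against and maf >= rare_threshold:
            label = "non_transferable"
        else:
            label = "indeterminate"
        labels.append(
            TransferabilityLabel(
                locus_id, call.locus.trait, label, call.category,
                res.p_jlim, res.status, maf,
            )
        )
    return labels


@dataclass
class BonferroniThreshold:
    alpha: float
    m: int
    threshold: float  # full precision alpha / m
    rounded: float  # two significant figures, as reported

    def __float__(self) -> float:
        return self.threshold


def _round_sig(x: float, digits: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + digits - 1)


def bonferroni(alpha: float, m: int) -> BonferroniThreshold:
    """Per-test threshold ``alpha / m``, reported at two significant figures
    alongside full precision (0.05/9 -> 0.0056; 0.05/21 -> 0.0024)."""
    if m < 1:
        raise ConfigurationError("number of tests must be >= 1")
    t = alpha / m
    return BonferroniThreshold(alpha=alpha, m=m, threshold=t, rounded=_round_sig(t, 2))


def load_bmi_lookup() -> pd.DataFrame:
    """The packaged lipid-locus / BMI association lookup.

    Columns: ``transferable`` (yes/no, relative to the Ugandan cohort),
    ``trait``, ``rsid``, ``chrom``, ``pos``, ``annotation`` (proximal gene),
    ``beta``, ``se``, ``p`` (BMI association).
    """
    with resources.files("transloci.data").joinpath("bmi_lipid_lookup.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return df


def count_pleiotropy(
    records: pd.DataFrame,
    threshold: float,
    labels: Sequence[TransferabilityLabel] | None = None,
) -> pd.DataFrame:
    """Per transferability label: how many loci are BMI-associated.

    ``records`` needs ``p`` (BMI p-value) and either a ``transferable``
    yes/no column (as in the packaged lookup) or, when ``labels`` is given,
    a ``locus_id`` column to join the labels on.  Returns one row per label
    with the associated count and the denominator.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    df = records.copy()
    if labels is not None:
        lab = {l.locus_id: l.label for l in labels}
        df["label"] = df["locus_id"].map(lab)
    elif "transferable" in df.columns:
        df["label"] = np.where(
            df["transferable"].astype(str).str.lower().isin(("yes", "true", "1")),
            "transferable",
            "non_transferable",
        )
    else:
        raise ValidationError("records need a 'transferable' column or explicit labels")
    rows = []
    for label, grp in df.groupby("label"):
        rows.append(
            dict(
                label=label,
                n_bmi_associated=int((grp["p"] < threshold).sum()),
                n_total=len(grp),
            )
        )
    out = pd.DataFrame(rows, columns=["label", "n_bmi_associated", "n_total"])
    return out.sort_values("label").reset_index(drop=True)


def nearest_gene(
    loci: pd.DataFrame, genes: pd.DataFrame
) -> pd.Series:
    """Nearest gene per locus from a caller-supplied BED-like table.

    ``genes`` needs columns ``chrom, start, end, name`` (BED half-open
    coordinates); distance is zero inside a gene body.
    """
    out = []
    for _, row in loci.iterrows():
        sub = genes[genes["chrom"].astype(str) == str(row["chrom"])]
        if sub.empty:
            out.append(None)
            continue
        pos = int(row["pos"])
        d = np.maximum(sub["start"] + 1 - pos, 0) + np.maximum(pos - sub["end"], 0)
        out.append(str(sub["name"].iloc[int(np.argmin(d.to_numpy()))]))
    return pd.Series(out, index=loci.index, name="nearest_gene")
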