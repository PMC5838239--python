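"""Genus-level metabarcoding summaries for ribotype read-count tables.

Operates on long-format tables of 18S-V9 ribotype read counts (one row per
sample × ribotype) with sample metadata: depth layer (SRF, DCM or the
~700 m mesopelagic MESO), size fraction and taxonomic group.  Provides the
summaries used to place a genus in a global survey: relative read abundance
against a diatom or an all-photosynthetic denominator, exponentiated
Shannon diversity (the effective number of equally common ribotypes),
ribotype richness, genus abundance ranks per depth selection, and per-
stratum abundance breakdowns.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "PHOTOSYNTHETIC_GROUPS",
    "DIATOM_GROUP",
    "DEPTH_LAYERS",
    "relative_abundance",
    "exp_shannon",
    "richness",
    "genus_rank",
    "fraction_by_stratum",
]

#: The nine photosynthetic groups forming the "total phytoplankton"
#: denominator.  Diatoms are the Bacillariophyta.
PHOTOSYNTHETIC_GROUPS = frozenset(
    {
        "Bacillariophyta",
        "Chlorophyceae",
        "Cryptophyta",
        "Dictyochophyceae",
        "Dinophyceae",
        "Haptophyta",
        "Mamiellophyceae",
        "Pelagophyceae",
        "Raphidophyceae",
    }
)

DIATOM_GROUP = "Bacillariophyta"

DEPTH_LAYERS = ("SRF", "DCM", "MESO")


def _denominator_mask(table: pd.DataFrame, denominator: str,
                      groups=PHOTOSYNTHETIC_GROUPS) -> pd.Series:
    if denominator == "diatoms":
        return table["taxon_group"] == DIATOM_GROUP
    if denominator == "photosynthetic":
        return table["taxon_group"].isin(groups)
    raise ValueError("denominator must be 'diatoms' or 'photosynthetic'")


def relative_abundance(
    table: pd.DataFrame,
    genus: str,
    denominator: str = "diatoms",
    groups=PHOTOSYNTHETIC_GROUPS,
) -> pd.Series:
    """Per-sample read fraction of ``genus`` against a denominator set.

    The denominator is the total diatom read count or the total read count
    of the nine photosynthetic groups in the same sample.  Samples whose
    denominator is zero are reported as missing (NaN), not as zero; a genus
    absent from the table yields zeros with a notice, since absence of reads
    is itself data.
    """
    samples = pd.Index(sorted(table["sample"].unique()), name="sample")
    mask = _denominator_mask(table, denominator, groups)
    denom = (table[mask].groupby("sample", sort=True)["reads"].sum()
             .reindex(samples, fill_value=0))
    if genus not in set(table["genus"]):
        warnings.warn(f"genus {genus!r} not present in table; "
                      "relative abundances are all zero", stacklevel=2)
    num = (
        table[table["genus"] == genus]
        .groupby("sample", sort=True)["reads"]
        .sum()
        .reindex(denom.index, fill_value=0)
    )
    out = num / denom.where(denom > 0)
    out.name = f"{genus}_vs_{denominator}"
    return out


def exp_shannon(counts) -> float:
    """Exponentiated Shannon–Wiener diversity exp(H'), natural log.

    ``p_i`` are read proportions over the positive counts; zero-count
    ribotypes contribute nothing.  Equals 1 for a single ribotype and n for
    n equally abundant ribotypes (the "effective number" of ribotypes).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("empty sample: all read counts are zero")
    p = counts / counts.sum()
    return float(np.exp(-(p * np.log(p)).sum()))


def richness(counts) -> int:
    """Number of ribotypes with at least one read."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("read counts must be negative-free")
    return int((counts > 0).sum())


def _depth_mask(table: pd.DataFrame, depth_layer: str) -> pd.Series:
    if depth_layer == "photic":
        return table["depth_layer"].isin(("SRF", "DCM"))
    if depth_layer in DEPTH_LAYERS:
        return table["depth_layer"] == depth_layer
    raise ValueError(f"unknown depth layer {depth_layer!r}")


def genus_rank(
    table: pd.DataFrame,
    genus: str,
    depth_layer: str = "MESO",
    among: str = "diatoms",
    pooling: str = "pooled",
) -> int | None:
    """Abundance rank (1 = most abundant) of ``genus`` in a depth selection.

    ``depth_layer`` is one of SRF, DCM, MESO or ``"photic"`` (SRF ∪ DCM);
    ``among`` restricts the ranked set to diatom genera or all
    photosynthetic genera.  With ``pooling="pooled"`` genera are ordered by
    total reads over all selected samples; ``pooling="mean"`` orders by the
    mean per-sample relative abundance instead.  Tied genera share the
    smaller rank and the following rank is skipped (competition ranking).
    Returns ``None`` ("unranked") if the genus has no reads in the
    selection.
    """
    sel = table[_depth_mask(table, depth_layer) & _denominator_mask(table, among)]
    if len(sel) == 0:
        return None
    if pooling == "pooled":
        totals = sel.groupby("genus")["reads"].sum()
    elif pooling == "mean":
        per_sample = sel.pivot_table(index="sample", columns="genus",
                                     values="reads", aggfunc="sum", fill_value=0)
        frac = per_sample.div(per_sample.sum(axis=1), axis=0)
        totals = frac.mean(axis=0)
    else:
        raise ValueError("pooling must be 'pooled' or 'mean'")
    totals = totals[totals > 0]
    if genus not in totals.index:
        return None
    ranks = totals.rank(method="min", ascending=False)
    return int(ranks.loc[genus])


def fraction_by_stratum(
    table: pd.DataFrame,
    genus: str,
    denominator: str = "diatoms",
) -> pd.DataFrame:
    """Relative abundance of ``genus`` in every size-fraction × depth stratum.

    Reads are pooled within each stratum before forming the fraction.
    Returns a tidy frame with columns ``size_fraction``, ``depth_layer``
    and ``fraction``; strata with a zero denominator are reported missing.
    """
    mask = _denominator_mask(table, denominator)
    denom = table[mask].groupby(["size_fraction", "depth_layer"])["reads"].sum()
    num = (
        table[table["genus"] == genus]
        .groupby(["size_fraction", "depth_layer"])["reads"]
        .sum()
        .reindex(denom.index, fill_value=0)
    )
    out = (num / denom.where(denom > 0)).rename("fraction").reset_index()
    return out
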