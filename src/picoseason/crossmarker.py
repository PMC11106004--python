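"""Linking 16S plastid ASVs to 18S-defined species.

Some plastid 16S ASVs cannot be placed to species level because the species
are uncultured and only defined by 18S sequences.  When both markers were
sequenced from the same samples, an unplaced 16S ASV and a candidate
species' 18S ASVs should track the same organism: their relative abundances
out of all reads of the shared genus should co-vary across samples.  This
module computes those within-genus fractions and their Spearman
correlation, flagging a pair as linked when the correlation is positive and
significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from picoseason.stats import spearman

__all__ = [
    "CrossMarkerLink",
    "LinkParams",
    "genus_relative_abundance",
    "link_candidates",
]


@dataclass(frozen=True)
class LinkParams:
    """min_genus_reads — the genus read count a sample needs, in each
    marker, to enter the comparison (guards against noisy fractions from
    tiny denominators); alpha — significance level for the link call;
    min_samples — below this many qualifying samples the link is
    indeterminate."""

    min_genus_reads: int = 10
    alpha: float = 0.05
    min_samples: int = 3

    def __post_init__(self) -> None:
        if self.min_genus_reads < 1:
            raise ValueError("min_genus_reads must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class CrossMarkerLink:
    """Result of one 16S ASV vs 18S species comparison."""

    asv16_id: str
    species18_label: str
    n_samples: int
    rho: Optional[float]
    p_value: Optional[float]
    linked: bool


def _genus_ids(taxonomy: pd.DataFrame, genus: str) -> set:
    tax = taxonomy.set_index("asv_id") if "asv_id" in taxonomy.columns else taxonomy
    ids = set(tax.index[tax["genus"] == genus])
    if not ids:
        raise ValueError(f"genus {genus!r} absent from taxonomy")
    return ids


def genus_relative_abundance(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    genus: str,
    unit: Iterable[str],
) -> pd.Series:
    """Per-sample fraction of ``unit`` ASV reads out of all reads of the
    genus.  ``unit`` is one or more ASV ids (a single 16S ASV, or the set
    of 18S ASVs mapped to one candidate species).  Samples with zero genus
    reads are absent from the result, not zero.
    """
    genus_ids = _genus_ids(taxonomy, genus)
    unit_ids = set(unit) if not isinstance(unit, str) else {unit}
    g = table[table["asv_id"].isin(genus_ids)]
    denom = g.groupby("sample_id")["count"].sum()
    denom = denom[denom > 0]
    num = (
        g[g["asv_id"].isin(unit_ids)].groupby("sample_id")["count"].sum()
        .reindex(denom.index, fill_value=0)
    )
    return num / denom


def genus_reads(table: pd.DataFrame, taxonomy: pd.DataFrame, genus: str) -> pd.Series:
    """Per-sample total read count of the genus (zero-count samples absent)."""
    genus_ids = _genus_ids(taxonomy, genus)
    g = table[table["asv_id"].isin(genus_ids)]
    return g.groupby("sample_id")["count"].sum()


def link_candidates(
    table16: pd.DataFrame,
    table18: pd.DataFrame,
    taxonomy: pd.DataFrame,
    genus: str,
    pairs: Sequence[tuple[str, str, Iterable[str]]],
    params: LinkParams = LinkParams(),
) -> list[CrossMarkerLink]:
    """Correlate within-genus fractions of 16S ASVs with candidate 18S
    species across shared samples.

    ``pairs`` holds (asv16_id, species18_label, 18S asv_id set).  For each
    pair the sample set is: samples where the 16S ASV or the 18S species is
    detected in at least one of the two markers, and the genus read count
    reaches ``min_genus_reads`` in both markers.  A sample passing the
    genus-read filter but lacking the unit in one marker enters with
    fraction 0 there.  The two fraction vectors are compared by Spearman
    correlation with a two-sided p; ``linked`` requires p < alpha and a
    positive rho (a negative co-occurrence cannot indicate identity).
    Fewer than ``min_samples`` qualifying samples, or constant fractions,
    leave the link indeterminate (no rho).
    """
    reads16 = genus_reads(table16, taxonomy, genus)
    reads18 = genus_reads(table18, taxonomy, genus)
    qualified = set(reads16.index[reads16 >= params.min_genus_reads]) & set(
        reads18.index[reads18 >= params.min_genus_reads]
    )
    links = []
    for asv16_id, label, asv18_ids in pairs:
        asv18_ids = list(asv18_ids)
        det16 = set(
            table16.loc[
                (table16["asv_id"] == asv16_id) & (table16["count"] > 0), "sample_id"
            ]
        )
        det18 = set(
            table18.loc[
                table18["asv_id"].isin(asv18_ids) & (table18["count"] > 0), "sample_id"
            ]
        )
        samples = sorted((det16 | det18) & qualified)
        if len(samples) < params.min_samples:
            links.append(CrossMarkerLink(asv16_id, label, len(samples), None, None, False))
            continue
        f16 = genus_relative_abundance(table16, taxonomy, genus, [asv16_id])
        f18 = genus_relative_abundance(table18, taxonomy, genus, asv18_ids)
        x = f16.reindex(samples, fill_value=0.0).to_numpy()
        y = f18.reindex(samples, fill_value=0.0).to_numpy()
        try:
            rho, p = spearman(x, y)
        except ValueError:  # constant fractions: correlation undefined
            links.append(CrossMarkerLink(asv16_id, label, len(samples), None, None, False))
            continue
        links.append(CrossMarkerLink(
            asv16_id, label, len(samples), rho, p,
            bool(p < params.alpha and rho > 0),
        ))
    return links
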