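"""Peptide-to-site aggregation and per-sample oxidation percentages.

The site-level statistic is the paired half-sample ratio:

    oxidation % = 100 · (oxidized-fraction S/N) / (total-fraction S/N)

per cysteine site and biological sample.  PSM reporter values are rolled up
to sites by summation (the conventional TMT roll-up — sums preserve
linearity), peptides carrying more than one cysteine are excluded because
the tag cannot be localised, and ratios above 100% are kept (clamping would
bias the downstream t-test) but counted for QC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError
from .io import PlexDesign, PsmQuantRecord, sample_group_map


@dataclass
class SiteQuantTable:
    """Per-site, per-sample summed reporter S/N for both half-samples.

    ``oxidized`` and ``total`` are aligned DataFrames (rows: site_id,
    columns: sample_id); NaN marks an absent (never-quantified) cell.
    """

    oxidized: pd.DataFrame
    total: pd.DataFrame
    psm_counts: pd.Series            # contributing single-Cys PSMs per site
    groups: dict[str, str]           # sample_id → group
    n_excluded_multi_cys: int = 0

    @property
    def site_ids(self) -> list[str]:
        return list(self.oxidized.index)

    @property
    def samples(self) -> list[str]:
        return list(self.oxidized.columns)


@dataclass
class OxidationProfile:
    """Per-site × per-sample oxidation percentage.

    ``values`` has NaN wherever either parent S/N is absent or the total is
    zero; ``n_over_100`` counts cells where noise pushed the ratio past
    100% (kept, flagged)."""

    values: pd.DataFrame
    groups: dict[str, str]
    n_over_100: int = 0

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def n_quantified(self) -> pd.DataFrame:
        """Per-site count of quantified replicates in each group."""
        out = {}
        for g in sorted(set(self.groups.values())):
            cols = self.group_columns(g)
            out[g] = self.values[cols].notna().sum(axis=1)
        return pd.DataFrame(out)


def aggregate_psms_to_sites(
    psms: Sequence[PsmQuantRecord], designs: Sequence[PlexDesign]
) -> SiteQuantTable:
    """Sum reporter S/N over PSMs per (site, sample, fraction).

    Multi-cysteine peptides are excluded (ambiguous tag localisation) and
    counted in ``n_excluded_multi_cys``; a site left with zero contributing
    PSMs is absent from the table.  A PSM referencing a channel its plex
    design does not define raises :class:`DesignError`.
    """
    channel_lookup: dict[tuple[str, str], tuple[str, str]] = {}
    sample_order: list[str] = []
    for d in designs:
        for ch, (sample, fraction) in d.channel_map.items():
            channel_lookup[(d.plex_id, ch)] = (sample, fraction)
        for s in d.samples:
            if s not in sample_order:
                sample_order.append(s)

    sums: dict[str, dict[str, dict[str, float]]] = {"oxidized": {}, "total": {}}
    counts: dict[str, int] = {}
    site_order: list[str] = []
    n_excluded = 0
    for psm in psms:
        if psm.n_cysteines > 1:
            n_excluded += 1
            continue
        sid = psm.site_id
        if sid not in counts:
            site_order.append(sid)
            counts[sid] = 0
        counts[sid] += 1
        for ch, value in psm.channel_values.items():
            key = (psm.plex_id, ch)
            if key not in channel_lookup:
                raise DesignError(
                    f"PSM for site {sid} references channel {ch!r} absent "
                    f"from plex {psm.plex_id!r} design"
                )
            sample, fraction = channel_lookup[key]
            cell = sums[fraction].setdefault(sid, {})
            cell[sample] = cell.get(sample, 0.0) + value

    def frame(fraction: str) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(sums[fraction], orient="index")
        df = df.reindex(index=site_order, columns=sample_order)
        df.index.name = "site_id"
        return df.astype(float)

    return SiteQuantTable(
        oxidized=frame("oxidized"),
        total=frame("total"),
        psm_counts=pd.Series(counts).reindex(site_order),
        groups=sample_group_map(designs),
        n_excluded_multi_cys=n_excluded,
    )


def median_center_channels(sites: SiteQuantTable) -> SiteQuantTable:
    """Optional per-channel loading normalisation: scale each sample×fraction
    column so its median matches the grand median of that fraction.
    Default-off; the ratio statistic is within-sample, so this only matters
    when labelling efficiency differs grossly between half-samples."""
    def center(df: pd.DataFrame) -> pd.DataFrame:
        grand = np.nanmedian(df.values)
        meds = df.median(axis=0, skipna=True)
        return df * (grand / meds)

    return SiteQuantTable(
        oxidized=center(sites.oxidized),
        total=center(sites.total),
        psm_counts=sites.psm_counts,
        groups=sites.groups,
        n_excluded_multi_cys=sites.n_excluded_multi_cys,
    )


def compute_oxidation_percent(sites: SiteQuantTable) -> OxidationProfile:
    """oxidation % = 100 · oxidized / total per site and sample; absent
    where either parent is absent or the total S/N is zero."""
    total = sites.total.where(sites.total > 0)
    values = 100.0 * sites.oxidized / total
    n_over = int((values > 100.0).sum().sum())
    return OxidationProfile(values=values, groups=sites.groups, n_over_100=n_over)


def filter_quantified_sites(
    profile: OxidationProfile, min_reps: int = 2
) -> OxidationProfile:
    """Keep sites with ≥ ``min_reps`` quantified replicates in *each* group
    (row order preserved).  ``min_reps`` < 2 is rejected: the per-site
    t-test needs at least two observations per group."""
    if min_reps < 2:
        raise ConfigError("min_reps must be ≥ 2 (t-test requires ≥ 2 per group)")
    nq = profile.n_quantified()
    keep = (nq >= min_reps).all(axis=1)
    return OxidationProfile(
        values=profile.values.loc[keep],
        groups=profile.groups,
        n_over_100=profile.n_over_100,
    )
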