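"""Differential-oxidation calling, protein hotspot ranking, domain mapping.

A cysteine is called as showing *increased oxidation* when all three of the
composite criteria hold:

1. two-tailed Student's t-test (pooled variance) P < alpha (default 0.05),
2. relative oxidation increase (Δ / control mean) ≥ rel_min (default 25%),
3. absolute increase Δ within the top ``top_frac`` (default 15%) of all
   tested sites ranked by Δ descending.

Raw P values gate the calls — the composite rule is deliberately a raw-P
rule; a Benjamini–Hochberg FDR column is emitted for reference only.
Direction is enforced by criteria 2–3, not by a one-tailed test.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyResultError, InsufficientReplicatesError
from .io import DomainAnnotation, ProteinDb, parse_site_id


def test_site(
    control: Sequence[float], depleted: Sequence[float]
) -> tuple[float, float, float]:
    """Per-site test: returns (delta_abs, rel_increase, p_value).

    delta_abs    — depleted mean − control mean, percentage points.
    rel_increase — delta_abs / control mean; +inf when the control mean is 0
                   and the depleted mean positive; 0 when both are 0.
    p_value      — two-tailed Student's t with pooled variance on
                   n1 + n2 − 2 df.  Degenerate zero-variance inputs: equal
                   means → p = 1, different means → p = 0.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(depleted, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError(
            f"need ≥ 2 replicates per group, got {n1} control / {n2} depleted"
        )
    m1 = a.mean()
    m2 = b.mean()
    delta = m2 - m1

    if m1 == 0.0:
        rel = math.inf if m2 > 0 else 0.0
    else:
        rel = delta / m1

    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if pooled_var == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        t = delta / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return float(delta), float(rel), float(p)


def test_all_sites(profile) -> pd.DataFrame:
    """Run :func:`test_site` for every site of an oxidation profile that has
    been filtered to ≥ 2 quantified replicates per group.

    Returns one row per site: mean_control, mean_depleted, n_control,
    n_depleted, delta_abs, rel_increase, p_value, bh_fdr.
    """
    ctrl_cols = profile.group_columns("control")
    dep_cols = profile.group_columns("depleted")
    rows = []
    for sid, row in profile.values.iterrows():
        c = row[ctrl_cols].dropna().to_numpy(dtype=float)
        d = row[dep_cols].dropna().to_numpy(dtype=float)
        delta, rel, p = test_site(c, d)
        rows.append(
            {
                "site_id": sid,
                "mean_control": c.mean(),
                "mean_depleted": d.mean(),
                "n_control": len(c),
                "n_depleted": len(d),
                "delta_abs": delta,
                "rel_increase": rel,
                "p_value": p,
            }
        )
    if not rows:
        raise EmptyResultError("no sites to test")
    df = pd.DataFrame(rows).set_index("site_id")
    df["bh_fdr"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df


def call_increased_oxidation(
    results: pd.DataFrame,
    alpha: float = 0.05,
    rel_min: float = 0.25,
    top_frac: float = 0.15,
) -> pd.DataFrame:
    """Apply the three-criterion composite call to a tested-site table.

    The top set comprises the ``ceil(top_frac · N)`` sites with the largest
    delta_abs among *all* tested sites, ties at the boundary broken by
    site_id (lexicographic ascending) for cross-platform determinism.
    Adds columns: delta_rank (1 = largest increase), percentile_rank
    (delta_rank / N), in_top_set, called.
    """
    if len(results) == 0:
        raise EmptyResultError("cannot call oxidation on an empty result set")
    df = results.copy()
    n = len(df)
    order = sorted(
        df.index, key=lambda sid: (-df.at[sid, "delta_abs"], sid)
    )
    rank = {sid: i + 1 for i, sid in enumerate(order)}
    df["delta_rank"] = [rank[sid] for sid in df.index]
    df["percentile_rank"] = df["delta_rank"] / n
    top_n = math.ceil(top_frac * n)
    df["in_top_set"] = df["delta_rank"] <= top_n
    df["called"] = (
        (df["p_value"] < alpha)
        & (df["rel_increase"] >= rel_min)
        & df["in_top_set"]
    )
    return df


def called_fraction(results: pd.DataFrame) -> float:
    return float(results["called"].mean())


def rank_proteins(results: pd.DataFrame, db: ProteinDb | None = None) -> pd.DataFrame:
    """Rank proteins by the number of called cysteine sites.

    Sort: count descending, then accession ascending; ranks 1..N over
    proteins with ≥ 1 called site.  Empty when nothing is called.
    """
    called = results.index[results["called"]] if "called" in results else results.index
    counts: dict[str, int] = {}
    for sid in called:
        acc, _ = parse_site_id(sid)
        counts[acc] = counts.get(acc, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "protein_accession": [acc for acc, _ in items],
            "n_called_sites": [c for _, c in items],
            "rank": range(1, len(items) + 1),
        }
    )


def map_sites_to_domains(
    site_ids: Sequence[str], annot: DomainAnnotation
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign each site the unique (non-overlapping, inclusive-ended) domain
    interval containing its position, else ``"unannotated"``.

    Returns (per-site table, per-domain counts)."""
    rows = []
    for sid in site_ids:
        acc, pos = parse_site_id(sid)
        label = annot.lookup(acc, pos)
        rows.append({"site_id": sid, "domain_label": label or "unannotated"})
    df = pd.DataFrame(rows, columns=["site_id", "domain_label"])
    counts = (
        df.groupby("domain_label")["site_id"].count().sort_values(ascending=False)
        if len(df)
        else pd.Series(dtype=int)
    )
    return df, counts
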