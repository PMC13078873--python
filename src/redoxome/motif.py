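"""Probability-logo statistics for sequences flanking modified cysteines.

For each flank position p (−w..−1, +1..+w; the cysteine is fixed at 0 and
not tested) and each of the 20 residues r, the foreground count k of r at p
among n_p foreground sequences is compared with the background frequency p0
of r at p via the exact binomial tail:

    over-represented  (k/n_p ≥ p0):  score = −log10 P[X ≥ k]
    under-represented (k/n_p < p0):  score = +log10 P[X ≤ k]   (≤ 0)

with X ~ Binomial(n_p, p0).  Positive scores mark enrichment, negative
depletion.  Significance uses a Bonferroni correction over all
R·W = 20 × 2w residue-by-position tests: threshold = −log10(alpha / (R·W)).
At the standard ±6 window and alpha = 0.05 this is −log10(0.05/240) = 3.68,
the familiar probability-logo red line.

Tails are computed by explicit summation of exact probability-mass terms
(no normal approximation): foreground sets here number in the hundreds, so
exactness is cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConsistencyError, EmptyResultError
from .io import AMINO_ACIDS, ProteinDb, parse_site_id


@dataclass
class FlankSet:
    """Fixed-width windows (2w+1 residues) centred on a cysteine.

    Positions are indexed −w..+w with the cysteine at 0; windows running
    past a protein terminus are padded with 'X', and 'X' cells are excluded
    from all counts downstream."""

    w: int
    sequences: list[str]
    site_ids: list[str] | None = None

    def __post_init__(self) -> None:
        width = 2 * self.w + 1
        for s in self.sequences:
            if len(s) != width:
                raise ConsistencyError(
                    f"flank {s!r} has length {len(s)}, expected {width}"
                )
            if s[self.w] != "C":
                raise ConsistencyError(f"flank {s!r} is not centred on 'C'")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def positions(self) -> list[int]:
        """Tested positions: −w..−1, +1..+w (0 excluded)."""
        return [p for p in range(-self.w, self.w + 1) if p != 0]

    def column(self, position: int) -> list[str]:
        i = position + self.w
        return [s[i] for s in self.sequences]


def extract_flanks(
    site_ids: Sequence[str], db: ProteinDb, w: int = 6
) -> FlankSet:
    """Extract the ±w window around each cysteine site from its protein,
    'X'-padding where the window runs past a terminus."""
    if w < 1:
        raise ValueError("window half-width w must be ≥ 1")
    seqs = []
    for sid in site_ids:
        acc, pos = parse_site_id(sid)
        seq = db[acc]
        if seq[pos - 1] != "C":
            raise ConsistencyError(
                f"site {sid} points at residue {seq[pos - 1]!r}, not 'C'"
            )
        start = pos - 1 - w
        end = pos - 1 + w + 1
        left_pad = max(0, -start)
        right_pad = max(0, end - len(seq))
        window = (
            "X" * left_pad
            + seq[max(0, start) : min(len(seq), end)]
            + "X" * right_pad
        )
        seqs.append(window)
    return FlankSet(w=w, sequences=seqs, site_ids=list(site_ids))


def _binom_tail(k: int, n: int, p0: float, upper: bool) -> float:
    """Exact binomial tail P[X ≥ k] (upper) or P[X ≤ k] by summation of
    probability-mass terms evaluated in log space."""
    if p0 == 0.0:
        if upper:
            return 1.0 if k == 0 else 0.0
        return 1.0
    if p0 == 1.0:
        if upper:
            return 1.0
        return 1.0 if k == n else 0.0
    ks = np.arange(k, n + 1) if upper else np.arange(0, k + 1)
    logpmf = (
        gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(n - ks + 1)
        + ks * math.log(p0)
        + (n - ks) * math.log1p(-p0)
    )
    return float(min(1.0, math.fsum(np.exp(logpmf))))


def binomial_logodds(k: int, n_p: int, p0: float) -> float:
    """Signed probability-logo score for a foreground count.

    k/n_p ≥ p0 (ties count as over-representation): −log10 P[X ≥ k];
    otherwise +log10 P[X ≤ k], i.e. a negative magnitude.  Certain events
    (P = 1) score 0.  +inf is possible only at degenerate p0 ∈ {0, 1}.
    """
    if k < 0 or n_p < 0 or k > n_p:
        raise ValueError(f"need 0 ≤ k ≤ n_p, got k={k}, n_p={n_p}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"background frequency p0={p0} outside [0, 1]")
    if n_p == 0:
        return 0.0
    over = (k / n_p) >= p0
    if over:
        tail = _binom_tail(k, n_p, p0, upper=True)
        if tail >= 1.0:
            return 0.0
        return math.inf if tail == 0.0 else -math.log10(tail)
    tail = _binom_tail(k, n_p, p0, upper=False)
    if tail >= 1.0:
        return 0.0
    return -math.inf if tail == 0.0 else math.log10(tail)


def significance_threshold(alpha: float = 0.05, R: int = 20, W: int = 12) -> float:
    """Bonferroni cutoff on |score|: −log10(alpha / (R·W)) over R residues ×
    W tested positions; 3.68 at alpha = 0.05 with a ±6 window (W = 12)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    if R < 1 or W < 1:
        raise ValueError("R and W must be ≥ 1")
    return -math.log10(alpha / (R * W))


@dataclass
class MotifResult:
    """Full motif analysis output.

    ``cells``: one row per (position, residue) with counts, background
    frequency, signed log-odds score and significance flag.  ``pwm``:
    per-position foreground residue frequencies ('X' mass excluded, columns
    sum to 1)."""

    cells: pd.DataFrame
    pwm: pd.DataFrame
    threshold: float
    alpha: float
    n_foreground: int
    n_background: int
    w: int

    def significant(self) -> pd.DataFrame:
        sig = self.cells[self.cells["significant"]]
        return sig.reindex(sig["score"].abs().sort_values(ascending=False).index)


def build_motif_result(
    fg: FlankSet, bg: FlankSet, alpha: float = 0.05
) -> MotifResult:
    """Score every (position, residue) cell of the foreground flanks against
    background frequencies taken from ``bg`` at the same position."""
    if len(fg) == 0:
        raise EmptyResultError("empty foreground flank set")
    if len(bg) == 0:
        raise EmptyResultError("empty background flank set")
    if fg.w != bg.w:
        raise ValueError(f"window mismatch: foreground w={fg.w}, background w={bg.w}")

    threshold = significance_threshold(alpha, R=len(AMINO_ACIDS), W=2 * fg.w)
    rows = []
    pwm_cols: dict[int, pd.Series] = {}
    for p in fg.positions:
        fg_col = [c for c in fg.column(p) if c != "X"]
        bg_col = [c for c in bg.column(p) if c != "X"]
        n_p = len(fg_col)
        n_bg = len(bg_col)
        fg_counts = {r: 0 for r in AMINO_ACIDS}
        for c in fg_col:
            fg_counts[c] += 1
        bg_counts = {r: 0 for r in AMINO_ACIDS}
        for c in bg_col:
            bg_counts[c] += 1
        for r in AMINO_ACIDS:
            k = fg_counts[r]
            p0 = bg_counts[r] / n_bg if n_bg else 0.0
            score = binomial_logodds(k, n_p, p0) if n_p else 0.0
            rows.append(
                {
                    "position": p,
                    "residue": r,
                    "k": k,
                    "n_p": n_p,
                    "p0": p0,
                    "score": score,
                    "significant": bool(abs(score) >= threshold),
                }
            )
        pwm_cols[p] = pd.Series(
            {r: (fg_counts[r] / n_p if n_p else 0.0) for r in AMINO_ACIDS}
        )

    cells = pd.DataFrame(rows)
    pwm = pd.DataFrame(pwm_cols)
    pwm.index.name = "residue"
    return MotifResult(
        cells=cells,
        pwm=pwm,
        threshold=threshold,
        alpha=alpha,
        n_foreground=len(fg),
        n_background=len(bg),
        w=fg.w,
    )
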