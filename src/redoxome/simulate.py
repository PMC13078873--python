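"""Synthetic redoxome experiments with known ground truth.

The generator emulates the paired half-sample TMT design used for
quantifying reversible cysteine oxidation: each biological sample is split
into an *oxidized*-enriched half (free thiols blocked, reversibly oxidized
thiols reduced and tagged) and a *total* half (all thiols tagged), each
labelled on its own multiplex channel.  For a site with true oxidation
fraction ``f`` and total abundance ``A``, the oxidized channel has expected
reporter S/N ``f·A`` and the total channel ``A``; independent multiplicative
log-normal noise with a chosen coefficient of variation is applied per
channel, so the downstream ratio estimator is unbiased up to noise.

Planted structure, mirroring the biology the analysis is built to detect:

* a small fraction of sites carries an additive increase ``delta`` of the
  true oxidation fraction in the GSH-depleted group,
* a designated hotspot protein concentrates several planted sites (the
  FASN-like top candidate a protein ranking should recover),
* planted sites carry basic residues (K/R) at flank positions −5 and −6
  with a configurable probability, giving the motif stage a known signal.

Proteins are assembled from 15-residue single-cysteine blocks spaced so
every site yields a single-Cys tryptic-like peptide; flank residues are
drawn uniformly from the 19 non-cysteine amino acids so background flank
frequencies are analytically known (1/19 ≈ 0.053 per residue) and no extra
cysteines confound the multi-Cys exclusion rule downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .io import PlexDesign, PlexEntry, ProteinDb, PsmQuantRecord, site_id

#: TMTpro 16-plex reporter channel names.
TMT16_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
)

#: Flank alphabet: the 19 standard residues other than cysteine.
FLANK_ALPHABET = "ADEFGHIKLMNPQRSTVWY"

_BLOCK_FLANK = 7          # residues on each side of the Cys within a block
_BLOCK_LEN = 2 * _BLOCK_FLANK + 1
_SITES_PER_PROTEIN = 5    # background proteins
_BASE_ABUNDANCE = 100.0   # median total-channel S/N


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic redoxome experiment.

    Defaults reproduce the study conditions the analysis targets: two groups
    of 7 biological replicates, ~10,000 detected cysteine sites of which
    1.8% carry a planted oxidation increase, baseline oxidation fractions
    drawn from Beta(2, 18) (mean 10%), an additive effect of 0.15 on the
    fraction scale, 10 planted sites concentrated on one hotspot protein,
    and an 80% chance that a planted site's flanks carry K/R at positions
    −5 and −6.
    """

    n_per_group: int = 7
    n_sites: int = 10_000
    frac_planted: float = 0.018
    beta_a: float = 2.0
    beta_b: float = 18.0
    delta: float = 0.15
    abundance_sigma: float = 0.8
    noise_cv: float = 0.10
    hotspot_sites: int = 10
    motif_bias: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be ≥ 2 (the t-test needs ≥ 2)")
        if not 0.0 <= self.frac_planted <= 1.0:
            raise ConfigError("frac_planted must lie in [0, 1]")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be ≥ 1")
        if not 0.0 <= self.delta < 1.0:
            raise ConfigError("delta must lie in [0, 1)")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be ≥ 0")
        if not 0.0 <= self.motif_bias <= 1.0:
            raise ConfigError("motif_bias must lie in [0, 1]")
        if self.hotspot_sites < 0:
            raise ConfigError("hotspot_sites must be ≥ 0")
        if self.hotspot_sites > self.n_sites:
            raise ConfigError("hotspot_sites cannot exceed n_sites")
        n_planted = int(round(self.frac_planted * self.n_sites))
        if self.frac_planted > 0 and n_planted < self.hotspot_sites:
            raise ConfigError(
                f"frac_planted·n_sites = {n_planted} planted sites cannot "
                f"cover hotspot_sites = {self.hotspot_sites}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated experiment."""

    planted_sites: set[str]
    f_control: dict[str, float]    # site_id → true control oxidation fraction
    f_depleted: dict[str, float]
    hotspot_accession: str
    flanks: dict[str, str]         # site_id → ±6 window (13-mer, C centred)

    def as_frame(self):
        import pandas as pd

        sids = sorted(self.f_control)
        return pd.DataFrame(
            {
                "site_id": sids,
                "planted": [s in self.planted_sites for s in sids],
                "f_control": [self.f_control[s] for s in sids],
                "f_depleted": [self.f_depleted[s] for s in sids],
                "flank": [self.flanks[s] for s in sids],
            }
        )


def _build_design(cfg: SimConfig) -> list[PlexDesign]:
    """Assign samples to 16-plex runs, both fractions of a sample always on
    the same plex (8 sample slots per plex)."""
    samples = [(f"C{i+1}", "control") for i in range(cfg.n_per_group)] + [
        (f"D{i+1}", "depleted") for i in range(cfg.n_per_group)
    ]
    designs = []
    per_plex = len(TMT16_CHANNELS) // 2
    for p_start in range(0, len(samples), per_plex):
        chunk = samples[p_start : p_start + per_plex]
        plex_id = f"plex{p_start // per_plex + 1}"
        entries = []
        for i, (sample, group) in enumerate(chunk):
            entries.append(
                PlexEntry(TMT16_CHANNELS[2 * i], sample, group, "oxidized")
            )
            entries.append(
                PlexEntry(TMT16_CHANNELS[2 * i + 1], sample, group, "total")
            )
        designs.append(PlexDesign(plex_id, entries))
    return designs


def _draw_flank(rng: np.random.Generator, planted: bool, bias: float) -> str:
    """13-mer window around the Cys (position 0), drawn i.i.d. uniform over
    the 19 non-Cys residues; planted sites receive K/R at −5 and −6 with
    probability ``bias``."""
    letters = [
        FLANK_ALPHABET[i]
        for i in rng.integers(0, len(FLANK_ALPHABET), size=2 * _BLOCK_FLANK)
    ]
    left = letters[:_BLOCK_FLANK]   # positions −7..−1
    right = letters[_BLOCK_FLANK:]  # positions +1..+7
    if planted and rng.random() < bias:
        basic = "KR"
        left[1] = basic[rng.integers(0, 2)]  # position −6
        left[2] = basic[rng.integers(0, 2)]  # position −5
    right[-1] = "K"  # tryptic-like C-terminal residue (outside the ±6 window)
    return "".join(left) + "C" + "".join(right)


def generate_experiment(
    cfg: SimConfig,
) -> tuple[ProteinDb, list[PlexDesign], list[PsmQuantRecord], SyntheticTruth]:
    """Generate a full synthetic experiment: protein FASTA-equivalent db,
    plex design(s), per-plex PSM quant records, and the ground truth.

    Identical ``cfg`` (including seed) gives byte-identical outputs.
    """
    return _generate(cfg, null=False)


def generate_null_experiment(
    cfg: SimConfig,
) -> tuple[ProteinDb, list[PlexDesign], list[PsmQuantRecord], SyntheticTruth]:
    """Same generative process with no group effect anywhere (delta = 0 for
    every site); the truth's planted set is empty."""
    return _generate(cfg, null=True)


def _generate(cfg: SimConfig, null: bool):
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_planted = 0 if null else int(round(cfg.frac_planted * cfg.n_sites))
    n_bg_sites = cfg.n_sites - cfg.hotspot_sites
    n_bg_proteins = math.ceil(n_bg_sites / _SITES_PER_PROTEIN) if n_bg_sites else 0

    hotspot_acc = "SYNHOT1"
    width = max(4, len(str(n_bg_proteins)))
    bg_accs = [f"SYN{i+1:0{width}d}" for i in range(n_bg_proteins)]

    # --- site layout: (accession, index-within-protein) per global site ---
    layout: list[tuple[str, int]] = [
        (hotspot_acc, j) for j in range(cfg.hotspot_sites)
    ]
    for i in range(n_bg_sites):
        layout.append((bg_accs[i // _SITES_PER_PROTEIN], i % _SITES_PER_PROTEIN))

    # --- choose planted sites: all hotspot slots + background sites with at
    # most 2 planted sites per protein, so the hotspot protein dominates the
    # ranking by construction ---
    planted_idx: set[int] = set()
    if n_planted:
        planted_idx.update(range(min(cfg.hotspot_sites, n_planted)))
        remaining = n_planted - len(planted_idx)
        per_protein: dict[str, int] = {}
        order = rng.permutation(np.arange(cfg.hotspot_sites, cfg.n_sites))
        for idx in order:
            if remaining == 0:
                break
            acc = layout[int(idx)][0]
            if per_protein.get(acc, 0) >= 2:
                continue
            planted_idx.add(int(idx))
            per_protein[acc] = per_protein.get(acc, 0) + 1
            remaining -= 1
        if remaining:
            raise ConfigError(
                "cannot place all planted sites at ≤ 2 per background protein"
            )

    # --- true oxidation fractions ---
    f0 = rng.beta(cfg.beta_a, cfg.beta_b, size=cfg.n_sites)
    f_ctrl = f0.copy()
    f_dep = f0.copy()
    if not null:
        for idx in planted_idx:
            f_dep[idx] = min(f0[idx] + cfg.delta, 0.99)

    # --- flanks and protein assembly ---
    flanks: list[str] = []
    blocks_by_acc: dict[str, list[str]] = {}
    positions: list[tuple[str, int]] = []  # (accession, 1-based Cys position)
    for idx, (acc, within) in enumerate(layout):
        flank15 = _draw_flank(rng, planted=idx in planted_idx, bias=cfg.motif_bias)
        blocks_by_acc.setdefault(acc, []).append(flank15)
        cys_pos = within * _BLOCK_LEN + _BLOCK_FLANK + 1  # 1-based
        positions.append((acc, cys_pos))
        flanks.append(flank15[1:-1])  # the ±6 window

    db = ProteinDb({acc: "".join(blocks) for acc, blocks in blocks_by_acc.items()})

    designs = _build_design(cfg)

    # --- reporter values ---
    abundance = _BASE_ABUNDANCE * np.exp(
        cfg.abundance_sigma * rng.standard_normal(cfg.n_sites)
    )
    sigma_n = math.sqrt(math.log1p(cfg.noise_cv**2))

    def noise(shape) -> np.ndarray:
        if sigma_n == 0.0:
            return np.ones(shape)
        # mean-one log-normal so expected S/N is exactly f·A and A
        return np.exp(sigma_n * rng.standard_normal(shape) - sigma_n**2 / 2)

    group_f = {"control": f_ctrl, "depleted": f_dep}
    psms: list[PsmQuantRecord] = []
    for design in designs:
        entries = design.entries
        eps = noise((cfg.n_sites, len(entries)))
        for idx in range(cfg.n_sites):
            acc, cys_pos = positions[idx]
            # peptide = the site's 15-mer single-Cys block
            block_start = (cys_pos - 1) - _BLOCK_FLANK
            peptide = db[acc][block_start : block_start + _BLOCK_LEN]
            values = {}
            for j, e in enumerate(entries):
                f = group_f[e.group][idx]
                expected = abundance[idx] * (f if e.fraction == "oxidized" else 1.0)
                values[e.channel_id] = float(expected * eps[idx, j])
            psms.append(
                PsmQuantRecord(
                    peptide_sequence=peptide,
                    protein_accession=acc,
                    site_position=cys_pos,
                    plex_id=design.plex_id,
                    channel_values=values,
                )
            )

    sids = [site_id(acc, pos) for acc, pos in positions]
    truth = SyntheticTruth(
        planted_sites={sids[i] for i in planted_idx},
        f_control={sids[i]: float(f_ctrl[i]) for i in range(cfg.n_sites)},
        f_depleted={sids[i]: float(f_dep[i]) for i in range(cfg.n_sites)},
        hotspot_accession=hotspot_acc,
        flanks={sids[i]: flanks[i] for i in range(cfg.n_sites)},
    )
    return db, designs, psms, truth
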