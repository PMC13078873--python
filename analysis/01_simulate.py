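#!/usr/bin/env python
"""Generate the synthetic GSH-depletion redoxome experiment.

Two groups (control vs glutathione-depleted) of 7 liver samples, each split
into oxidized-enriched and total half-samples across two TMT 16-plexes;
2,000 cysteine sites (a desk-scale stand-in for the ~10,000-site default),
1.8% carrying a planted +0.15 oxidation-fraction increase, 10 of them on
one hotspot protein, with K/R biased into flank positions −5/−6 of planted
sites.  Writes FASTA + design + PSM table + ground truth under
results/experiment/.
"""

from pathlib import Path

from redoxome.io import write_fasta, write_plex_design, write_psm_table, write_table
from redoxome.simulate import SimConfig, generate_experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "experiment"

cfg = SimConfig(n_sites=2000, n_per_group=7, frac_planted=0.018, delta=0.15,
                noise_cv=0.10, hotspot_sites=10, motif_bias=0.8, seed=2024)

db, designs, psms, truth = generate_experiment(cfg)
OUT.mkdir(parents=True, exist_ok=True)
write_fasta(db, OUT / "proteins.fasta")
write_plex_design(designs, OUT / "plex_design.tsv")
write_psm_table(psms, OUT / "psm_table.tsv",
                channels=[e.channel_id for e in designs[0].entries])
write_table(truth.as_frame(), OUT / "truth.tsv")

print(f"simulated {cfg.n_sites} cysteine sites on {len(db)} proteins, "
      f"{len(psms)} PSMs across {len(designs)} plexes")
print(f"planted {len(truth.planted_sites)} sites "
      f"({100 * len(truth.planted_sites) / cfg.n_sites:.1f}%), "
      f"10 on hotspot {truth.hotspot_accession}")
print(f"outputs → {OUT}")
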