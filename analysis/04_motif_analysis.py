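#!/usr/bin/env python
"""Probability-logo motif statistics on flanks of called cysteines.

Foreground: ±6 windows around called sites; background: all detected
(tested) sites.  Each (position, residue) cell gets an exact binomial
log-odds score; |score| ≥ −log10(0.05/240) = 3.68 is significant after
Bonferroni correction.  Expects enrichment of the basic residues K/R at
positions −5/−6 — the planted susceptibility motif.  Writes score matrix
and PWM under results/motif/.
"""

from pathlib import Path

from redoxome.io import read_fasta, read_table, write_table
from redoxome.motif import build_motif_result, extract_flanks

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "motif"

db = read_fasta(ROOT / "experiment" / "proteins.fasta")
results = read_table(ROOT / "differential" / "differential.tsv")
called = sorted(results.loc[results.called, "site_id"])
detected = sorted(results.site_id)

fg = extract_flanks(called, db, w=6)
bg = extract_flanks(detected, db, w=6)
mres = build_motif_result(fg, bg, alpha=0.05)

OUT.mkdir(parents=True, exist_ok=True)
write_table(mres.cells, OUT / "motif_cells.tsv")
write_table(mres.pwm.reset_index(), OUT / "motif_pwm.tsv")

sig = mres.significant()
over = sig[sig.score > 0]
print(f"{len(fg)} foreground vs {len(bg)} background flanks; "
      f"threshold |score| ≥ {mres.threshold:.2f}")
print(f"{len(sig)} significant cells ({len(over)} overrepresented):")
print(over[["position", "residue", "k", "n_p", "p0", "score"]]
      .head(8).to_string(index=False))
print(f"outputs → {OUT}")
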