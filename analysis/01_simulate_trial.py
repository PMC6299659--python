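"""Generate the desk-scale synthetic progeny trial used by the later steps.

Emulates the study design — a partial diallel of 55 parents and 128
full-sib families planted at two sites — at a marker count that keeps every
later analysis step tractable on one CPU.  Writes VCF + pedigree CSV +
phenotype CSV + true breeding values under results/trial/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sprucegs.simdata import SimConfig, simulate_trial, write_trial

OUT = Path(__file__).resolve().parents[1] / "scratch" / "derived" / "trial"

cfg = SimConfig(
    n_markers=2000,
    n_qtl=500,
    n_parents=55,
    n_families=128,
    progeny_range=(5, 6),  # ~1400 genotyped progeny, the study's scale
    seed=1,
)

ped, geno, pheno, truth = simulate_trial(cfg)
paths = write_trial(geno, ped, pheno, OUT)
tbv = pd.concat(
    {t: pd.DataFrame(v, index=truth.ids, columns=["site1", "site2"])
     for t, v in truth.tbv.items()},
    axis=1,
)
tbv.to_csv(OUT / "true_breeding_values.csv")

n1 = (pheno.frame["site"] == "site1").sum()
n2 = (pheno.frame["site"] == "site2").sum()
print(f"simulated {len(ped.founder_ids)} parents, "
      f"{pheno.frame['family'].nunique()} families, "
      f"{n1} + {n2} trees at the two sites, {geno.n_markers} markers")
print(f"traits: {', '.join(pheno.traits)}")
for p in paths.values():
    print(f"wrote {p}")
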