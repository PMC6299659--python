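"""Relatedness-structure and marker-subset cross-validation experiments.

GBLUP/ABLUP accuracy under full-sib, half-sib and unrelated TS/VS
structures; GBLUP accuracy with random vs largest-positive-effect marker
subsets; and family/trees-per-family subsampling curves.  Appends to
results/cv_structure_summary.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sprucegs.cv_engine import CVScenario, prepare_bundle, run_scenario
from sprucegs.metrics import summarize
from sprucegs.relationship import RelationshipMatrix
from sprucegs.simdata import GenotypeMatrix, read_trial

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "derived"
SEED = 1


def load_relmat(name, kind):
    frame = pd.read_csv(
        Path(__file__).resolve().parents[1] / "scratch" / "derived" / name,
        sep="\t", index_col=0)
    return RelationshipMatrix(frame.index.to_numpy(dtype=object),
                              frame.to_numpy(), kind)


_, ped, pheno = read_trial(SCRATCH / "trial")
dos = pd.read_csv(
    Path(__file__).resolve().parents[1] / "scratch" / "derived" / "filtered_dosages.csv",
    index_col=0)
geno = GenotypeMatrix(dos.index.to_numpy(dtype=object),
                      dos.columns.to_numpy(dtype=object), dos.to_numpy())
A = load_relmat("A_matrix.tsv", "A")
G = load_relmat("G_matrix.tsv", "G")

scenarios = (
    [CVScenario(model=m, scope="joint", split=("relatedness", mode),
                n_replicates=5, seed=SEED)
     for m in ("ablup", "gblup")
     for mode in ("full_sib", "half_sib", "unrelated")]
    + [CVScenario(model="gblup", scope="joint", split=("ratio", "9:1"),
                  marker_subset=(mode, m), n_replicates=5, seed=SEED)
       for mode in ("random", "largest_positive")
       for m in (100, 250, 500, 1000)]
    + [CVScenario(model="gblup", scope="joint", split=("families", nf),
                  n_replicates=5, seed=SEED)
       for nf in (10, 30, 60, 90, 120)]
    + [CVScenario(model="gblup", scope="joint",
                  split=("trees_per_family", nt), n_replicates=5, seed=SEED)
       for nt in (2, 5, 8, 12)]
)

records = []
bundle = prepare_bundle("height", ped, geno, pheno, A, G)
for scn in scenarios:
    print(f"running {scn.model} {scn.label}")
    records.extend(run_scenario(scn, bundle, strict=False))

summary = summarize(records)
summary.to_csv(ROOT / "cv_structure_summary.csv", index=False)
cols = ["scenario", "model", "accuracy_mean", "accuracy_n_undefined",
        "predictive_ability_mean"]
print(summary[cols].round(3).to_string(index=False))
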