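"""Build the pedigree (A) and genomic (G) relationship matrices.

A comes from the tabular method on the full pedigree; G is the VanRaden
matrix on the QC'd, imputed dosages.  Prints the mean diagonal and the
agreement between A and G over full-sib pairs.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sprucegs.relationship import a_matrix, g_matrix
from sprucegs.simdata import GenotypeMatrix, family_of, read_trial

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "derived"

_, ped, _ = read_trial(SCRATCH / "trial")
dos = pd.read_csv(SCRATCH / "filtered_dosages.csv", index_col=0)
geno = GenotypeMatrix(dos.index.to_numpy(dtype=object),
                      dos.columns.to_numpy(dtype=object), dos.to_numpy())

A = a_matrix(ped)
G = g_matrix(geno)
pd.DataFrame(A.values, index=A.ids, columns=A.ids).to_csv(
    SCRATCH / "A_matrix.tsv", sep="\t"
)
pd.DataFrame(G.values, index=G.ids, columns=G.ids).to_csv(
    SCRATCH / "G_matrix.tsv", sep="\t"
)

posA = {s: i for i, s in enumerate(A.ids)}
posG = {s: i for i, s in enumerate(G.ids)}
fam = family_of(ped)
diffs = []
for f in fam.unique():
    members = fam.index[fam == f].to_numpy()[:4]
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a = A.values[posA[members[i]], posA[members[j]]]
            g = G.values[posG[members[i]], posG[members[j]]]
            diffs.append(abs(g - a))

print(f"A: {A.values.shape[0]} individuals, mean diagonal "
      f"{np.mean(np.diag(A.values)):.3f}")
print(f"G: {G.values.shape[0]} samples, mean diagonal "
      f"{np.mean(np.diag(G.values)):.3f}")
print(f"mean |G - A| over full-sib pairs: {np.mean(diffs):.3f}")
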