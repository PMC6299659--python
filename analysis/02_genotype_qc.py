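"""Quality-control the trial VCF and impute the remaining missing calls.

Applies the seven-step filter (indels, biallelic, GQ < 6, DP < 2,
individual call rate < 50%, variant call rate < 90%, MAF < 1%) and mean
imputation; writes the QC report and the filtered dosage matrix.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sprucegs.geno_qc import QCThresholds, filter_variants, impute_missing

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "derived"

geno, report = filter_variants(SCRATCH / "trial" / "genotypes.vcf", QCThresholds())
geno = impute_missing(geno, method="mean", seed=1, report=report)

(ROOT / "qc_report.json").write_text(report.to_json())
SCRATCH.mkdir(parents=True, exist_ok=True)
pd.DataFrame(
    geno.dosages, index=geno.samples, columns=geno.markers
).to_csv(SCRATCH / "filtered_dosages.csv")

print(report.to_json())
print(f"retained {geno.n_markers} markers x {geno.n_samples} samples")
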