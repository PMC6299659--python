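"""Post-calling genotype quality control and imputation.

Applies, in a fixed order, the variant/sample filters used for the exome
capture data the pipeline emulates:

1. drop indels;
2. keep only biallelic records;
3. set genotypes with GQ < 6 missing;
4. set genotypes with DP < 2 missing;
5. drop samples with individual call rate < 50%;
6. drop variants with call rate < 90%;
7. drop variants with minor allele frequency < 0.01.

All inequalities are strict, exactly as enumerated.  MAF for step 7 is
recomputed after sample removal so frequencies reflect retained samples.
Technical-replicate discordance and mean/random imputation complete the
module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from ._errors import ParseError, QCError
from .simdata import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    gq_min: int = 6
    dp_min: int = 2
    ind_call_min: float = 0.50
    var_call_min: float = 0.90
    maf_min: float = 0.01
    drop_indels: bool = True
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        for name in ("ind_call_min", "var_call_min", "maf_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise QCError(f"{name} must be in [0,1], got {v}")
        if self.gq_min < 0 or self.dp_min < 0:
            raise QCError("integer thresholds must be >= 0")


@dataclass
class QCReport:
    """Bookkeeping of every removal; removed + retained = input, per axis."""

    n_input_records: int = 0
    n_indels_removed: int = 0
    n_multiallelic_removed: int = 0
    n_low_var_call_removed: int = 0
    n_low_maf_removed: int = 0
    n_variants_retained: int = 0
    n_input_samples: int = 0
    n_samples_removed: int = 0
    n_samples_retained: int = 0
    n_genotypes_masked_gq: int = 0
    n_genotypes_masked_dp: int = 0
    fraction_imputed: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def log_summary(self) -> None:
        log.info(
            "QC: %d records in; removed %d indels, %d multiallelic, "
            "%d low call rate, %d low MAF; %d variants retained",
            self.n_input_records,
            self.n_indels_removed,
            self.n_multiallelic_removed,
            self.n_low_var_call_removed,
            self.n_low_maf_removed,
            self.n_variants_retained,
        )
        log.info(
            "QC: %d/%d samples retained; %d genotypes masked by GQ, %d by DP",
            self.n_samples_retained,
            self.n_input_samples,
            self.n_genotypes_masked_gq,
            self.n_genotypes_masked_dp,
        )


def _minor_freq(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per marker from non-missing calls (NaN if none)."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_variants(
    vcf_path, thr: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the seven-step filter to a VCF and return retained dosages.

    A VCF without GT is fatal; absent GQ/DP fields skip those steps with a
    logged warning.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:
        raise ParseError(f"cannot parse VCF {vcf_path}: {exc}") from exc

    samples = np.array(vcf.samples, dtype=object)
    report = QCReport(n_input_samples=len(samples))

    rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray | None] = []
    dp_rows: list[np.ndarray | None] = []
    markers: list[str] = []
    saw_gq = saw_dp = True
    for var in vcf:
        report.n_input_records += 1
        if thr.drop_indels and var.is_indel:
            report.n_indels_removed += 1
            continue
        if thr.biallelic_only and len(var.ALT) != 1:
            report.n_multiallelic_removed += 1
            continue
        gt = np.asarray(var.gt_types, dtype=float)
        if gt.size != len(samples):
            raise ParseError(f"record {var.ID or var.POS}: GT field missing or short")
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        try:
            gq = var.format("GQ")
            gq = None if gq is None else np.asarray(gq, dtype=float).reshape(-1)
        except KeyError:
            gq = None
        try:
            dp = var.format("DP")
            dp = None if dp is None else np.asarray(dp, dtype=float).reshape(-1)
        except KeyError:
            dp = None
        saw_gq &= gq is not None
        saw_dp &= dp is not None
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(dos)
        gq_rows.append(gq)
        dp_rows.append(dp)

    if not rows:
        raise QCError("no variant records survive the record-level filters")
    dosages = np.vstack(rows).T  # samples × markers
    if not saw_gq:
        log.warning("VCF lacks GQ for some records; GQ masking skipped")
    if not saw_dp:
        log.warning("VCF lacks DP for some records; DP masking skipped")

    # steps 3-4: per-genotype masking (strict <)
    for j, (gq, dp) in enumerate(zip(gq_rows, dp_rows)):
        col = dosages[:, j]
        if saw_gq and gq is not None:
            mask = (gq < thr.gq_min) & ~np.isnan(col)
            report.n_genotypes_masked_gq += int(mask.sum())
            col[mask] = np.nan
        if saw_dp and dp is not None:
            mask = (dp < thr.dp_min) & ~np.isnan(col)
            report.n_genotypes_masked_dp += int(mask.sum())
            col[mask] = np.nan

    # step 5: individual call rate < 50%
    call_rate = 1.0 - np.isnan(dosages).mean(axis=1)
    keep_samples = call_rate >= thr.ind_call_min
    report.n_samples_removed = int((~keep_samples).sum())
    report.n_samples_retained = int(keep_samples.sum())
    if report.n_samples_retained == 0:
        raise QCError("all samples removed by the individual call-rate filter")
    dosages = dosages[keep_samples]
    samples = samples[keep_samples]

    # step 6: variant call rate < 90%
    var_call = 1.0 - np.isnan(dosages).mean(axis=0)
    keep_call = var_call >= thr.var_call_min
    report.n_low_var_call_removed = int((~keep_call).sum())

    # step 7: MAF < 1%, recomputed on retained samples
    maf = _minor_freq(dosages)
    with np.errstate(invalid="ignore"):
        keep_maf = maf >= thr.maf_min
    keep_maf &= ~np.isnan(maf)
    report.n_low_maf_removed = int((keep_call & ~keep_maf).sum())

    keep = keep_call & keep_maf
    report.n_variants_retained = int(keep.sum())
    report.log_summary()
    geno = GenotypeMatrix(
        samples, np.array(markers, dtype=object)[keep], dosages[:, keep]
    )
    return geno, report


def replicate_discordance(
    geno: GenotypeMatrix, pairs: list[tuple[str, str]]
) -> float:
    """Mean over pairs of the fraction of jointly called markers that disagree."""
    pos = {s: i for i, s in enumerate(geno.samples)}
    rates = []
    for a, b in pairs:
        if a not in pos or b not in pos:
            raise QCError(f"replicate pair ({a}, {b}) not fully present")
        da, db = geno.dosages[pos[a]], geno.dosages[pos[b]]
        joint = ~np.isnan(da) & ~np.isnan(db)
        if joint.sum() == 0:
            log.warning("pair (%s, %s): no jointly called markers; excluded", a, b)
            continue
        rates.append(float(np.mean(da[joint] != db[joint])))
    if not rates:
        raise QCError("no replicate pair has jointly called markers")
    return float(np.mean(rates))


def impute_missing(
    geno: GenotypeMatrix,
    method: str = "mean",
    seed: int = 0,
    report: QCReport | None = None,
) -> GenotypeMatrix:
    """Fill missing dosages: ``mean`` → 2p (real-valued), ``random`` → HWE draw.

    Markers that are 100% missing are dropped with a warning.  Allele
    frequencies come from the non-missing calls of each marker.
    """
    if method not in ("mean", "random"):
        raise QCError(f"unknown imputation method {method!r}")
    dos = geno.dosages.copy()
    miss = np.isnan(dos)
    all_missing = miss.all(axis=0)
    if all_missing.any():
        log.warning("dropping %d markers with no called genotypes", all_missing.sum())
        dos = dos[:, ~all_missing]
        miss = miss[:, ~all_missing]
        markers = geno.markers[~all_missing]
    else:
        markers = geno.markers
    frac = float(miss.mean())
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    if method == "mean":
        fill = np.broadcast_to(2.0 * p, dos.shape)
        dos[miss] = fill[miss]
    else:
        rng = np.random.default_rng(seed)
        u = rng.random(dos.shape)
        pm = np.broadcast_to(p, dos.shape)
        hom_ref = (1.0 - pm) ** 2
        het = 2.0 * pm * (1.0 - pm)
        draw = np.where(u < hom_ref, 0.0, np.where(u < hom_ref + het, 1.0, 2.0))
        dos[miss] = draw[miss]
    if report is not None:
        report.fraction_imputed = frac
    log.info("imputed %.2f%% of genotypes (%s)", 100 * frac, method)
    return GenotypeMatrix(geno.samples.copy(), markers.copy(), dos)
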