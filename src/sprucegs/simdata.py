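"""Synthetic two-site partial-diallel progeny trials.

Generates data with the statistical structure the downstream analysis
assumes: a partial-diallel pedigree (by default 55 parents, 128 full-sib
families, 5–20 progeny per family per site at 2 sites), unlinked biallelic
SNP genotypes realized by gene dropping through the pedigree, and per-site
phenotypes built from QTL effects whose across-site correlation equals a
configurable type-B genetic correlation target, plus post-block effects and
residual noise scaled to hit a target narrow-sense heritability.

Trials round-trip through standard formats: VCF v4.2 genotypes, a pedigree
CSV (``id,sire,dam``, ``0`` = unknown) and a phenotype CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, ParseError, PedigreeError

log = logging.getLogger(__name__)

UNKNOWN_PARENT = "0"

#: Trait presets calibrated to the study's reported genetic architecture:
#: a low-heritability growth trait with strong G×E and moderate-heritability
#: wood traits with weak G×E.  (name, per-site narrow-sense h², type-B).
DEFAULT_TRAIT_SPECS: tuple[tuple[str, float, float], ...] = (
    ("height", 0.15, 0.45),
    ("pilodyn", 0.40, 0.90),
    ("velocity", 0.50, 0.85),
    ("moe", 0.45, 0.90),
)

# Nominal trait scales (mean, phenotypic SD) used only to put phenotypes on
# familiar measurement scales: height cm, Pilodyn mm, velocity km/s, MOE GPa.
TRAIT_SCALES: dict[str, tuple[float, float]] = {
    "height": (450.0, 77.0),
    "pilodyn": (22.0, 2.3),
    "velocity": (5.0, 0.27),
    "moe": (11.0, 4.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic trial."""

    n_markers: int
    n_qtl: int
    n_parents: int = 55
    n_families: int = 128
    progeny_range: tuple[int, int] = (5, 20)
    n_sites: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    trait_specs: tuple[tuple[str, float, float], ...] = DEFAULT_TRAIT_SPECS
    n_blocks_per_site: int = 44
    block_variance_fraction: float = 0.10
    site_offset_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl > self.n_markers:
            raise ConfigurationError(
                f"n_qtl={self.n_qtl} exceeds n_markers={self.n_markers}"
            )
        max_pairs = self.n_parents * (self.n_parents - 1) // 2
        if self.n_families > max_pairs:
            raise ConfigurationError(
                f"n_families={self.n_families} exceeds the {max_pairs} distinct "
                f"parent pairs available from {self.n_parents} parents"
            )
        lo, hi = self.progeny_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"invalid progeny_range {self.progeny_range}")
        lo_f, hi_f = self.maf_range
        if not (0.0 < lo_f <= hi_f <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5]: {self.maf_range}")
        for name, h2, type_b in self.trait_specs:
            if not (0.0 <= h2 < 1.0):
                raise ConfigurationError(f"h2 for {name!r} outside [0,1): {h2}")
            if not (0.0 <= type_b <= 1.0):
                raise ConfigurationError(f"type-B for {name!r} outside [0,1]: {type_b}")
            if h2 == 0.0 and type_b > 0.0:
                raise ConfigurationError(
                    f"trait {name!r}: type-B > 0 is meaningless with h2 = 0"
                )

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage random stream derived from the global seed."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2**31)
        return np.random.default_rng([self.seed, stage_key])


@dataclass
class Pedigree:
    """Individual/sire/dam records in parents-before-offspring order.

    Founders carry ``UNKNOWN_PARENT`` for both parents.  Progeny additionally
    carry the site at which the tree grows (this is a trial property; founders
    have an empty site label).
    """

    frame: pd.DataFrame  # columns: id, sire, dam, generation, site

    def __post_init__(self) -> None:
        ids = self.frame["id"]
        if ids.duplicated().any():
            raise PedigreeError("duplicate individual ids in pedigree")
        seen: set[str] = set()
        for row in self.frame.itertuples(index=False):
            known = [p for p in (row.sire, row.dam) if p != UNKNOWN_PARENT]
            if len(known) == 1:
                raise PedigreeError(
                    f"{row.id}: exactly one known parent (design has none)"
                )
            for p in known:
                if p == row.id:
                    raise PedigreeError(f"{row.id} is its own parent")
                if p not in seen:
                    raise PedigreeError(
                        f"parent {p!r} of {row.id!r} does not precede it"
                    )
            seen.add(row.id)

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy()

    @property
    def founder_ids(self) -> np.ndarray:
        mask = (self.frame["sire"] == UNKNOWN_PARENT) & (
            self.frame["dam"] == UNKNOWN_PARENT
        )
        return self.frame.loc[mask, "id"].to_numpy()

    @property
    def progeny_ids(self) -> np.ndarray:
        mask = (self.frame["sire"] != UNKNOWN_PARENT) | (
            self.frame["dam"] != UNKNOWN_PARENT
        )
        return self.frame.loc[mask, "id"].to_numpy()

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer row indices of (sire, dam) per individual; −1 for unknown."""
        pos = {iid: i for i, iid in enumerate(self.ids)}
        sire = np.array([pos.get(s, -1) for s in self.frame["sire"]], dtype=np.int64)
        dam = np.array([pos.get(d, -1) for d in self.frame["dam"]], dtype=np.int64)
        return sire, dam


@dataclass
class GenotypeMatrix:
    """Samples × markers dosage matrix; entries in {0,1,2} or NaN (missing)."""

    samples: np.ndarray
    markers: np.ndarray
    dosages: np.ndarray  # float array, NaN = missing

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.markers = np.asarray(self.markers, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ConfigurationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples × {len(self.markers)} markers"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per marker from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_oriented(self) -> "GenotypeMatrix":
        """Flip marker coding so the counted allele is the minor one (p ≤ 0.5)."""
        p = self.allele_freq()
        flip = p > 0.5
        dos = self.dosages.copy()
        dos[:, flip] = 2.0 - dos[:, flip]
        return GenotypeMatrix(self.samples, self.markers, dos)

    def subset(self, sample_ids=None, marker_ids=None) -> "GenotypeMatrix":
        dos = self.dosages
        samples, markers = self.samples, self.markers
        if sample_ids is not None:
            pos = {s: i for i, s in enumerate(samples)}
            idx = np.array([pos[s] for s in sample_ids])
            dos = dos[idx]
            samples = samples[idx]
        if marker_ids is not None:
            pos = {m: i for i, m in enumerate(markers)}
            idx = np.array([pos[m] for m in marker_ids])
            dos = dos[:, idx]
            markers = markers[idx]
        return GenotypeMatrix(samples, markers, dos)


@dataclass
class PhenotypeTable:
    """One row per tree per site with family/layout columns and trait values."""

    frame: pd.DataFrame  # tree, family, dam, sire, site, block, <traits...>
    traits: tuple[str, ...]

    LAYOUT_COLUMNS = ("tree", "family", "dam", "sire", "site", "block")

    def __post_init__(self) -> None:
        missing = [c for c in self.LAYOUT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"phenotype table lacks columns {missing}")
        if self.frame.duplicated(["tree", "site"]).any():
            raise ConfigurationError("more than one row per tree per site")

    @property
    def sites(self) -> list[str]:
        return sorted(self.frame["site"].unique())


@dataclass
class TrueValues:
    """Generative ground truth for parameter-recovery checks.

    Per trait: per-site true breeding values for every pedigree individual,
    the per-site marker-effect vectors (zero off-QTL), QTL indices, and the
    variance components the phenotypes were built from.
    """

    ids: np.ndarray
    tbv: dict[str, np.ndarray]  # trait -> (n_individuals, n_sites)
    marker_effects: dict[str, np.ndarray]  # trait -> (n_markers, n_sites)
    qtl_indices: dict[str, np.ndarray]
    variances: dict[str, dict[str, float]]  # additive/residual/block per trait


# ---------------------------------------------------------------------------
# Pedigree construction
# ---------------------------------------------------------------------------

def make_diallel_pedigree(cfg: SimConfig) -> Pedigree:
    """Build a partial-diallel pedigree: founders plus per-site progeny.

    Families are distinct unordered parent pairs sampled uniformly from all
    pairs; per-family-per-site sizes are uniform on the configured range.
    """
    rng = cfg.rng("pedigree")
    n = cfg.n_parents
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen = rng.choice(len(pairs), size=cfg.n_families, replace=False)
    families = [pairs[k] for k in chosen]

    founder_ids = [f"P{i + 1:03d}" for i in range(n)]
    rows: list[tuple[str, str, str, int, str]] = [
        (fid, UNKNOWN_PARENT, UNKNOWN_PARENT, 0, "") for fid in founder_ids
    ]
    lo, hi = cfg.progeny_range
    tree_no = 0
    for fam_idx, (i, j) in enumerate(families):
        sire, dam = founder_ids[i], founder_ids[j]
        for site in range(cfg.n_sites):
            size = int(rng.integers(lo, hi + 1))
            for _ in range(size):
                tree_no += 1
                rows.append(
                    (f"T{tree_no:05d}", sire, dam, 1, f"site{site + 1}")
                )
        del fam_idx
    frame = pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "site"])
    return Pedigree(frame)


def family_of(ped: Pedigree) -> pd.Series:
    """Family label per progeny id (sorted parent pair joined by 'x')."""
    prog = ped.frame[ped.frame["sire"] != UNKNOWN_PARENT]
    fam = prog.apply(lambda r: "x".join(sorted([r["sire"], r["dam"]])), axis=1)
    fam.index = prog["id"].to_numpy()
    return fam


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def drop_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Realize unlinked biallelic genotypes by gene dropping.

    Founders receive two alleles i.i.d. Bernoulli(p) per locus with p drawn
    uniformly from ``maf_range``; each non-founder inherits one allele chosen
    at random from each parent's pair, independently per locus.
    """
    rng = cfg.rng("genedrop")
    m = cfg.n_markers
    n_ind = len(ped.ids)
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)

    a1 = np.zeros((n_ind, m), dtype=np.int8)
    a2 = np.zeros((n_ind, m), dtype=np.int8)
    sire_idx, dam_idx = ped.parent_indices()
    for i in range(n_ind):
        si, di = sire_idx[i], dam_idx[i]
        if si < 0 and di < 0:
            a1[i] = rng.random(m) < p
            a2[i] = rng.random(m) < p
        else:
            # one gamete from each parent, picking either of its two alleles
            pick1 = rng.random(m) < 0.5
            a1[i] = np.where(pick1, a1[si], a2[si])
            pick2 = rng.random(m) < 0.5
            a2[i] = np.where(pick2, a1[di], a2[di])
    dosage = (a1 + a2).astype(float)
    markers = np.array([f"M{j + 1:06d}" for j in range(m)], dtype=object)
    return GenotypeMatrix(ped.ids.copy(), markers, dosage)


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    geno: GenotypeMatrix, ped: Pedigree, cfg: SimConfig
) -> tuple[PhenotypeTable, TrueValues]:
    """Simulate per-site phenotypes with target h² and type-B correlation.

    For each trait, ``n_qtl`` markers receive per-site effects drawn from a
    bivariate (generally equicorrelated multivariate) normal whose across-site
    correlation equals the type-B target.  True breeding values are centered
    dosages times the per-site effect vector, scaled so the founder-population
    additive variance is 1; residual variance is then (1−h²)/h², post-block
    effects are i.i.d. normal with variance equal to ``block_variance_fraction``
    of (σ²_a + σ²_e), and sites get fixed offsets.  Output traits are mapped
    onto nominal measurement scales (cm, mm, km/s, GPa).
    """
    rng = cfg.rng("phenotypes")
    founder_set = set(ped.founder_ids)
    founder_mask = np.array([s in founder_set for s in geno.samples])
    dos = geno.dosages
    p_founder = dos[founder_mask].mean(axis=0) / 2.0
    centered = dos - 2.0 * p_founder
    het = 2.0 * p_founder * (1.0 - p_founder)

    prog_mask = ped.frame["sire"].to_numpy() != UNKNOWN_PARENT
    prog = ped.frame[prog_mask]
    n_sites = cfg.n_sites
    site_labels = [f"site{s + 1}" for s in range(n_sites)]

    # trial layout: random block per tree within its site
    blocks = {
        lab: rng.integers(1, cfg.n_blocks_per_site + 1, size=(prog["site"] == lab).sum())
        for lab in site_labels
    }

    layout_rows = []
    block_counter = {lab: 0 for lab in site_labels}
    for row in prog.itertuples(index=False):
        lab = row.site
        b = blocks[lab][block_counter[lab]]
        block_counter[lab] += 1
        layout_rows.append(
            (
                row.id,
                "x".join(sorted([row.sire, row.dam])),
                row.dam,
                row.sire,
                lab,
                f"{lab}_b{b:02d}",
            )
        )
    frame = pd.DataFrame(layout_rows, columns=list(PhenotypeTable.LAYOUT_COLUMNS))

    tbv_store: dict[str, np.ndarray] = {}
    eff_store: dict[str, np.ndarray] = {}
    qtl_store: dict[str, np.ndarray] = {}
    var_store: dict[str, dict[str, float]] = {}
    trait_names = []

    sample_pos = {s: i for i, s in enumerate(geno.samples)}
    tree_rows = np.array([sample_pos[t] for t in frame["tree"]])
    site_codes = np.array([site_labels.index(s) for s in frame["site"]])

    for name, h2, type_b in cfg.trait_specs:
        trait_names.append(name)
        qtl = rng.choice(geno.n_markers, size=cfg.n_qtl, replace=False)
        qtl.sort()
        if type_b == 1.0:
            # degenerate case: the same effect vector expressed at every site
            raw = np.repeat(rng.standard_normal((cfg.n_qtl, 1)), n_sites, axis=1)
        else:
            corr = np.full((n_sites, n_sites), type_b) + (1.0 - type_b) * np.eye(
                n_sites
            )
            chol = np.linalg.cholesky(corr)
            raw = rng.standard_normal((cfg.n_qtl, n_sites)) @ chol.T
        if h2 == 0.0:
            raw[:] = 0.0
        else:
            # scale each site's effects so founder additive variance = 1
            for s in range(n_sites):
                va = float(het[qtl] @ raw[:, s] ** 2)
                raw[:, s] /= np.sqrt(va)
        effects = np.zeros((geno.n_markers, n_sites))
        effects[qtl] = raw
        tbv = centered @ effects  # (n_individuals, n_sites)

        if h2 > 0:
            sigma_e2 = (1.0 - h2) / h2
        else:
            sigma_e2 = 1.0
        sigma_b2 = cfg.block_variance_fraction * (1.0 + sigma_e2)

        # block effects per (site, block) level
        block_levels = frame["block"].unique()
        block_eff = dict(
            zip(block_levels, rng.normal(0.0, np.sqrt(sigma_b2), len(block_levels)))
        )
        site_off = rng.normal(0.0, cfg.site_offset_sd, n_sites)

        g = tbv[tree_rows, site_codes] if h2 > 0 else np.zeros(len(frame))
        y = (
            site_off[site_codes]
            + np.array([block_eff[b] for b in frame["block"]])
            + g
            + rng.normal(0.0, np.sqrt(sigma_e2), len(frame))
        )
        mu, sd = TRAIT_SCALES.get(name, (0.0, 1.0))
        scale = sd / np.sqrt(1.0 + sigma_e2)
        frame[name] = mu + scale * y

        tbv_store[name] = tbv * scale
        eff_store[name] = effects * scale
        qtl_store[name] = qtl
        var_store[name] = {
            "additive": 0.0 if h2 == 0.0 else scale**2,
            "residual": scale**2 * sigma_e2,
            "block": scale**2 * sigma_b2,
        }

    pheno = PhenotypeTable(frame, tuple(trait_names))
    truth = TrueValues(geno.samples.copy(), tbv_store, eff_store, qtl_store, var_store)
    return pheno, truth


# ---------------------------------------------------------------------------
# Trial I/O: VCF v4.2 + pedigree CSV + phenotype CSV
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=sprucegs-simdata
##contig=<ID=1>
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of Samples With Data">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
"""

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(
    geno: GenotypeMatrix,
    path: str | Path,
    gq: np.ndarray | None = None,
    dp: np.ndarray | None = None,
) -> None:
    """Write dosages as a plain-text VCF v4.2 with GT:GQ:DP fields.

    ``gq``/``dp`` are optional per-genotype integer arrays (samples × markers);
    they default to constant 99 / 30.
    """
    path = Path(path)
    n, m = geno.dosages.shape
    if gq is None:
        gq = np.full((n, m), 99, dtype=int)
    if dp is None:
        dp = np.full((n, m), 30, dtype=int)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in geno.samples)
            + "\n"
        )
        for j in range(m):
            col = geno.dosages[:, j]
            calls = []
            for i in range(n):
                d = col[i]
                gt = "./." if np.isnan(d) else _GT_CODE[float(round(d))]
                calls.append(f"{gt}:{gq[i, j]}:{dp[i, j]}")
            fh.write(
                f"1\t{j + 1}\t{geno.markers[j]}\tA\tC\t.\tPASS\tNS={n}\tGT:GQ:DP\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT dosages from a VCF (no filtering; see ``geno_qc`` for QC)."""
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = np.array(vcf.samples, dtype=object)
    markers: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = np.asarray(var.gt_types, dtype=float)  # 0 HOM_REF,1 HET,2 UNK,3 HOM_ALT
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
    if not markers:
        raise ParseError(f"VCF {path} contains no variant records")
    dosages = np.vstack(rows).T
    return GenotypeMatrix(samples, np.array(markers, dtype=object), dosages)


def _toposort_pedigree(frame: pd.DataFrame) -> pd.DataFrame:
    """Order records parents-first; raise PedigreeError on cycles."""
    ids = list(frame["id"])
    pos = {iid: k for k, iid in enumerate(ids)}
    children: dict[int, list[int]] = {k: [] for k in range(len(ids))}
    indeg = [0] * len(ids)
    for k, row in enumerate(frame.itertuples(index=False)):
        for par in (row.sire, row.dam):
            if par != UNKNOWN_PARENT:
                if par not in pos:
                    raise PedigreeError(f"parent {par!r} of {row.id!r} has no record")
                children[pos[par]].append(k)
                indeg[k] += 1
    import heapq

    ready = [k for k in range(len(ids)) if indeg[k] == 0]
    heapq.heapify(ready)  # stable: lowest original index first
    order: list[int] = []
    while ready:
        k = heapq.heappop(ready)
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(order) != len(ids):
        raise PedigreeError("pedigree contains a cycle")
    return frame.iloc[order].reset_index(drop=True)


def write_trial(
    geno: GenotypeMatrix,
    ped: Pedigree,
    pheno: PhenotypeTable,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write genotypes (VCF), pedigree CSV and phenotype CSV to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "pedigree": outdir / "pedigree.csv",
        "phenotypes": outdir / "phenotypes.csv",
    }
    write_vcf(geno, paths["vcf"])
    ped.frame[["id", "sire", "dam"]].to_csv(paths["pedigree"], index=False)
    pheno.frame.to_csv(paths["phenotypes"], index=False)
    return paths


def read_trial(indir: str | Path) -> tuple[GenotypeMatrix, Pedigree, PhenotypeTable]:
    """Read a trial directory written by :func:`write_trial` (or compatible)."""
    indir = Path(indir)
    geno = read_vcf(indir / "genotypes.vcf")
    pedframe = pd.read_csv(indir / "pedigree.csv", dtype=str).fillna(UNKNOWN_PARENT)
    for col in ("id", "sire", "dam"):
        if col not in pedframe.columns:
            raise ParseError(f"pedigree CSV lacks column {col!r}")
    pedframe = _toposort_pedigree(pedframe)
    phframe = pd.read_csv(indir / "phenotypes.csv")
    phframe["tree"] = phframe["tree"].astype(str)

    founder = (pedframe["sire"] == UNKNOWN_PARENT) & (pedframe["dam"] == UNKNOWN_PARENT)
    pedframe["generation"] = np.where(founder, 0, 1)
    site_map = dict(zip(phframe["tree"], phframe["site"]))
    pedframe["site"] = [site_map.get(i, "") for i in pedframe["id"]]
    ped = Pedigree(pedframe)

    ped_ids = set(ped.ids)
    missing = [t for t in phframe["tree"] if t not in ped_ids]
    if missing:
        raise ParseError(
            f"{len(missing)} phenotyped trees absent from pedigree "
            f"(first: {missing[:3]})"
        )
    traits = tuple(
        c for c in phframe.columns if c not in PhenotypeTable.LAYOUT_COLUMNS
    )
    pheno = PhenotypeTable(phframe, traits)
    return geno, ped, pheno


def simulate_trial(
    cfg: SimConfig,
) -> tuple[Pedigree, GenotypeMatrix, PhenotypeTable, TrueValues]:
    """Convenience wrapper: pedigree → gene dropping → phenotypes."""
    ped = make_diallel_pedigree(cfg)
    geno = drop_genotypes(ped, cfg)
    pheno, truth = simulate_phenotypes(geno, ped, cfg)
    return ped, geno, pheno, truth
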