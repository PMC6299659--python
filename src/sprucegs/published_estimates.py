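"""Published estimates from the two-site Norway spruce progeny-trial study.

The pipeline emulates a genomic-selection study of 1370 control-pollinated
progeny from 128 full-sib families (55 parents, partial diallel) grown at
two northern Swedish sites.  The study's printed tables provide variance
components, heritabilities, type-B genetic correlations, and
cross-validation accuracies for four traits (tree height, Pilodyn
penetration, acoustic velocity, and indirect MOE).  Those printed numbers
are frozen here and used in two ways:

* as inputs to worked-example arithmetic (recomputing heritability and
  relative-efficiency values from their components), and
* as calibration targets for the synthetic-trial generator's trait presets.

Nothing here is produced by this package; these are the study's reported
estimates.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Variance components and heritabilities (study Table 1).
# Keys: (trait, scope, model) -> dict with additive & residual variance,
# printed heritability, and (joint scope only) printed type-B correlation.
# ---------------------------------------------------------------------------
VARIANCE_COMPONENTS: dict[tuple[str, str, str], dict[str, float]] = {
    ("height", "site1", "ablup"): {"additive": 690.8, "residual": 5260.5, "h2": 0.12},
    ("height", "site1", "gblup"): {"additive": 902.2, "residual": 5064.1, "h2": 0.15},
    ("height", "site2", "ablup"): {"additive": 2007.1, "residual": 8604.5, "h2": 0.19},
    ("height", "site2", "gblup"): {"additive": 2140.6, "residual": 8461.8, "h2": 0.20},
    ("height", "joint", "ablup"): {
        "additive": 1104.2, "residual": 7576.4, "h2": 0.13, "type_b": 0.48,
    },
    ("height", "joint", "gblup"): {
        "additive": 1351.8, "residual": 7393.5, "h2": 0.15, "type_b": 0.41,
    },
    ("pilodyn", "site1", "ablup"): {"additive": 2.3, "residual": 3.2, "h2": 0.42},
    ("pilodyn", "site1", "gblup"): {"additive": 1.7, "residual": 3.6, "h2": 0.31},
    ("pilodyn", "site2", "ablup"): {"additive": 2.3, "residual": 2.7, "h2": 0.46},
    ("pilodyn", "site2", "gblup"): {"additive": 1.9, "residual": 2.9, "h2": 0.39},
    ("pilodyn", "joint", "ablup"): {
        "additive": 2.2, "residual": 3.0, "h2": 0.41, "type_b": 0.88,
    },
    ("pilodyn", "joint", "gblup"): {
        "additive": 1.7, "residual": 3.3, "h2": 0.34, "type_b": 0.90,
    },
    ("velocity", "site1", "ablup"): {"additive": 0.039, "residual": 0.036, "h2": 0.52},
    ("velocity", "site1", "gblup"): {"additive": 0.036, "residual": 0.037, "h2": 0.49},
    ("velocity", "site2", "ablup"): {"additive": 0.034, "residual": 0.039, "h2": 0.47},
    ("velocity", "site2", "gblup"): {"additive": 0.026, "residual": 0.044, "h2": 0.37},
    ("velocity", "joint", "ablup"): {
        "additive": 0.033, "residual": 0.041, "h2": 0.45, "type_b": 0.88,
    },
    ("velocity", "joint", "gblup"): {
        "additive": 0.027, "residual": 0.045, "h2": 0.37, "type_b": 0.80,
    },
    ("moe", "site1", "ablup"): {"additive": 8.0, "residual": 8.5, "h2": 0.48},
    ("moe", "site1", "gblup"): {"additive": 6.2, "residual": 9.7, "h2": 0.39},
    ("moe", "site2", "ablup"): {"additive": 5.8, "residual": 6.4, "h2": 0.47},
    ("moe", "site2", "gblup"): {"additive": 4.7, "residual": 6.9, "h2": 0.40},
    ("moe", "joint", "ablup"): {
        "additive": 6.2, "residual": 7.7, "h2": 0.44, "type_b": 0.88,
    },
    ("moe", "joint", "gblup"): {
        "additive": 4.7, "residual": 8.5, "h2": 0.36, "type_b": 0.94,
    },
}

# Cells of Table 1 whose printed heritability equals additive/(additive+residual)
# rounded to 2 dp.  A few printed cells (e.g. Pilodyn site-1 GBLUP: 1.7/5.3 =
# 0.321 printed as 0.31) reflect unrounded internal components and are not
# self-consistent at the printed precision; worked-example arithmetic targets
# the self-consistent cells only.
SELF_CONSISTENT_H2_CELLS: tuple[tuple[str, str, str], ...] = (
    ("height", "site1", "ablup"),
    ("height", "site1", "gblup"),
    ("pilodyn", "site1", "ablup"),
    ("velocity", "site1", "ablup"),
    ("velocity", "site1", "gblup"),
    ("moe", "joint", "gblup"),
)

# ---------------------------------------------------------------------------
# Full-data cross-validation accuracies / predictive abilities (study Table 2):
# all markers, joint 10-fold CV, full-sib structure; five site scenarios.
# Values: (ablup_accuracy, gblup_accuracy, ablup_pa, gblup_pa, re, re_per_year)
# ---------------------------------------------------------------------------
SITE_SCENARIO_METRICS: dict[tuple[str, str], dict[str, float]] = {
    ("height", "site1"): {"ablup_acc": 0.82, "gblup_acc": 0.74, "ablup_pa": 0.15,
                          "gblup_pa": 0.16, "re": 0.91, "re_per_year": 1.81},
    ("height", "site2"): {"ablup_acc": 0.89, "gblup_acc": 0.77, "ablup_pa": 0.26,
                          "gblup_pa": 0.23, "re": 0.87, "re_per_year": 1.73},
    ("height", "cross_1to2"): {"ablup_acc": 0.48, "gblup_acc": 0.39, "ablup_pa": 0.10,
                               "gblup_pa": 0.11, "re": 0.81, "re_per_year": 1.63},
    ("height", "cross_2to1"): {"ablup_acc": 0.54, "gblup_acc": 0.48, "ablup_pa": 0.02,
                               "gblup_pa": 0.01, "re": 0.89, "re_per_year": 1.77},
    ("height", "joint"): {"ablup_acc": 0.91, "gblup_acc": 0.81, "ablup_pa": 0.20,
                          "gblup_pa": 0.20, "re": 0.89, "re_per_year": 1.78},
    ("pilodyn", "site1"): {"ablup_acc": 0.69, "gblup_acc": 0.60, "ablup_pa": 0.29,
                           "gblup_pa": 0.24, "re": 0.87, "re_per_year": 1.74},
    ("pilodyn", "site2"): {"ablup_acc": 0.72, "gblup_acc": 0.58, "ablup_pa": 0.33,
                           "gblup_pa": 0.29, "re": 0.80, "re_per_year": 1.60},
    ("pilodyn", "cross_1to2"): {"ablup_acc": 0.57, "gblup_acc": 0.52, "ablup_pa": 0.28,
                                "gblup_pa": 0.28, "re": 0.92, "re_per_year": 1.84},
    ("pilodyn", "cross_2to1"): {"ablup_acc": 0.58, "gblup_acc": 0.52, "ablup_pa": 0.24,
                                "gblup_pa": 0.23, "re": 0.90, "re_per_year": 1.80},
    ("pilodyn", "joint"): {"ablup_acc": 0.77, "gblup_acc": 0.66, "ablup_pa": 0.32,
                           "gblup_pa": 0.30, "re": 0.86, "re_per_year": 1.71},
    ("velocity", "site1"): {"ablup_acc": 0.75, "gblup_acc": 0.70, "ablup_pa": 0.42,
                            "gblup_pa": 0.44, "re": 0.93, "re_per_year": 1.87},
    ("velocity", "site2"): {"ablup_acc": 0.80, "gblup_acc": 0.69, "ablup_pa": 0.41,
                            "gblup_pa": 0.37, "re": 0.86, "re_per_year": 1.72},
    ("velocity", "cross_1to2"): {"ablup_acc": 0.72, "gblup_acc": 0.63, "ablup_pa": 0.40,
                                 "gblup_pa": 0.36, "re": 0.88, "re_per_year": 1.76},
    ("velocity", "cross_2to1"): {"ablup_acc": 0.69, "gblup_acc": 0.60, "ablup_pa": 0.37,
                                 "gblup_pa": 0.34, "re": 0.87, "re_per_year": 1.75},
    ("velocity", "joint"): {"ablup_acc": 0.83, "gblup_acc": 0.74, "ablup_pa": 0.43,
                            "gblup_pa": 0.41, "re": 0.89, "re_per_year": 1.78},
    ("moe", "site1"): {"ablup_acc": 0.70, "gblup_acc": 0.64, "ablup_pa": 0.34,
                       "gblup_pa": 0.35, "re": 0.91, "re_per_year": 1.83},
    ("moe", "site2"): {"ablup_acc": 0.76, "gblup_acc": 0.64, "ablup_pa": 0.38,
                       "gblup_pa": 0.35, "re": 0.84, "re_per_year": 1.69},
    ("moe", "cross_1to2"): {"ablup_acc": 0.66, "gblup_acc": 0.59, "ablup_pa": 0.34,
                            "gblup_pa": 0.32, "re": 0.89, "re_per_year": 1.78},
    ("moe", "cross_2to1"): {"ablup_acc": 0.61, "gblup_acc": 0.58, "ablup_pa": 0.29,
                            "gblup_pa": 0.31, "re": 0.95, "re_per_year": 1.89},
    ("moe", "joint"): {"ablup_acc": 0.79, "gblup_acc": 0.69, "ablup_pa": 0.38,
                       "gblup_pa": 0.36, "re": 0.87, "re_per_year": 1.75},
}

# ---------------------------------------------------------------------------
# Half-sib / unrelated structure joint-site metrics (study Table 3).
# gblup_hs = GBLUP with half-sib TS/VS structure; gblup_unrel = unrelated
# structure.  ABLUP accuracies under the unrelated structure are identically
# zero (no pedigree ties between TS and VS) and were not printed.
# ---------------------------------------------------------------------------
RELATEDNESS_METRICS: dict[str, dict[str, float]] = {
    "height": {"ablup_acc": 0.66, "gblup_hs_acc": 0.55, "gblup_unrel_acc": 0.24,
               "ablup_pa": 0.16, "gblup_hs_pa": 0.11, "gblup_unrel_pa": 0.06,
               "re": 0.83, "re_per_year": 1.67},
    "pilodyn": {"ablup_acc": 0.59, "gblup_hs_acc": 0.44, "gblup_unrel_acc": 0.21,
                "ablup_pa": 0.23, "gblup_hs_pa": 0.19, "gblup_unrel_pa": 0.12,
                "re": 0.75, "re_per_year": 1.49},
    "velocity": {"ablup_acc": 0.63, "gblup_hs_acc": 0.62, "gblup_unrel_acc": 0.09,
                 "ablup_pa": 0.29, "gblup_hs_pa": 0.32, "gblup_unrel_pa": 0.02,
                 "re": 0.98, "re_per_year": 1.97},
    "moe": {"ablup_acc": 0.59, "gblup_hs_acc": 0.50, "gblup_unrel_acc": 0.19,
            "ablup_pa": 0.28, "gblup_hs_pa": 0.26, "gblup_unrel_pa": 0.10,
            "re": 0.85, "re_per_year": 1.69},
}

# Breeding-cycle lengths (years): conventional progeny-test selection vs GS.
T_CONVENTIONAL_YEARS = 25.0
T_GENOMIC_YEARS = 12.5
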