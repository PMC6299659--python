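"""Synthetic-trial generator: pedigree structure, gene dropping, phenotypes, I/O."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sprucegs._errors import ConfigurationError, ParseError, PedigreeError
from sprucegs import simdata
from sprucegs.relationship import a_matrix
from sprucegs.simdata import (
    GenotypeMatrix,
    Pedigree,
    SimConfig,
    drop_genotypes,
    family_of,
    make_diallel_pedigree,
    read_trial,
    simulate_phenotypes,
    simulate_trial,
    write_trial,
)


class TestSimConfig:
    def test_rejects_more_qtl_than_markers(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_markers=10, n_qtl=11)

    def test_rejects_too_many_families(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_markers=10, n_qtl=5, n_parents=4, n_families=7)

    def test_rejects_type_b_with_zero_heritability(self):
        with pytest.raises(ConfigurationError):
            SimConfig(
                n_markers=10, n_qtl=5, trait_specs=(("t", 0.0, 0.5),)
            )

    @pytest.mark.parametrize("maf_range", [(0.0, 0.5), (0.1, 0.6), (0.4, 0.1)])
    def test_rejects_bad_maf_range(self, maf_range):
        with pytest.raises(ConfigurationError):
            SimConfig(n_markers=10, n_qtl=5, maf_range=maf_range)


class TestDiallelPedigree:
    def test_progeny_count_within_configured_range(self):
        cfg = SimConfig(n_markers=10, n_qtl=5, seed=7)  # default 55/128, 5-20, 2 sites
        ped = make_diallel_pedigree(cfg)
        n_prog = len(ped.progeny_ids)
        assert 128 * 5 * 2 <= n_prog <= 128 * 20 * 2
        assert len(ped.founder_ids) == 55

    def test_three_parents_exhaust_all_pairs(self):
        cfg = SimConfig(
            n_markers=10, n_qtl=5, n_parents=3, n_families=3,
            progeny_range=(1, 2),
        )
        ped = make_diallel_pedigree(cfg)
        fams = set(family_of(ped).unique())
        assert fams == {"P001xP002", "P001xP003", "P002xP003"}

    def test_same_seed_reproduces_pedigree(self):
        cfg = SimConfig(n_markers=10, n_qtl=5, n_parents=10, n_families=20, seed=3)
        p1 = make_diallel_pedigree(cfg)
        p2 = make_diallel_pedigree(cfg)
        pd.testing.assert_frame_equal(p1.frame, p2.frame)

    def test_single_known_parent_rejected(self):
        frame = pd.DataFrame(
            [("A", "0", "0", 0, ""), ("B", "A", "0", 1, "site1")],
            columns=["id", "sire", "dam", "generation", "site"],
        )
        with pytest.raises(PedigreeError, match="one known parent"):
            Pedigree(frame)

    def test_offspring_before_parent_rejected(self):
        frame = pd.DataFrame(
            [("B", "A", "C", 1, ""), ("A", "0", "0", 0, ""), ("C", "0", "0", 0, "")],
            columns=["id", "sire", "dam", "generation", "site"],
        )
        with pytest.raises(PedigreeError, match="precede"):
            Pedigree(frame)


@pytest.fixture(scope="module")
def dropped():
    cfg = SimConfig(
        n_markers=2500, n_qtl=100, n_parents=12, n_families=12,
        progeny_range=(6, 8), seed=5,
    )
    ped = make_diallel_pedigree(cfg)
    return cfg, ped, drop_genotypes(ped, cfg)


class TestGeneDropping:
    def test_mendelian_transmission_extremes(self, dropped):
        cfg, ped, geno = dropped
        pos = {s: i for i, s in enumerate(geno.samples)}
        prog = ped.frame[ped.frame["sire"] != "0"]
        for row in prog.head(20).itertuples(index=False):
            ds = geno.dosages[pos[row.sire]]
            dd = geno.dosages[pos[row.dam]]
            do = geno.dosages[pos[row.id]]
            both0 = (ds == 0) & (dd == 0)
            both2 = (ds == 2) & (dd == 2)
            assert np.all(do[both0] == 0)
            assert np.all(do[both2] == 2)

    def test_full_sib_realized_relationship_near_half(self, dropped):
        # oracle: the pedigree expectation for full sibs is exactly 0.5; the
        # realized relationship uses founder-frequency centering so it is not
        # deflated by the structure of the progeny sample
        cfg, ped, geno = dropped
        # true generative frequencies (first draw of the gene-drop stream):
        # centering on estimated frequencies from 12 founders would bias the
        # realized relationship down by O(1/n_founders)
        p = cfg.rng("genedrop").uniform(
            cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_markers
        )
        centered = geno.dosages - 2 * p
        denom = 2 * np.sum(p * (1 - p))
        G = centered @ centered.T / denom
        pos = {s: i for i, s in enumerate(geno.samples)}
        fam = family_of(ped)
        vals = []
        for f in fam.unique():
            members = fam.index[fam == f].to_numpy()
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    vals.append(G[pos[members[i]], pos[members[j]]])
        assert len(vals) > 100
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_founder_dosage_mean_is_binomial_around_2p(self):
        # founders draw 2n_f alleles i.i.d. Bernoulli(p) per marker
        cfg = SimConfig(
            n_markers=3000, n_qtl=10, n_parents=50, n_families=5,
            progeny_range=(1, 1), maf_range=(0.2, 0.4), seed=9,
        )
        ped = make_diallel_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        founder_set = set(ped.founder_ids)
        fmask = np.array([s in founder_set for s in geno.samples])
        mean_dos = geno.dosages[fmask].mean(axis=0)
        p_drawn = cfg.rng("genedrop").uniform(
            cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_markers
        )
        se = np.sqrt(2 * p_drawn * (1 - p_drawn) / fmask.sum())
        z = (mean_dos - 2 * p_drawn) / se
        # ~0.3% of standard normal draws fall outside |z| > 3
        assert np.mean(np.abs(z) > 3) < 0.02
        assert abs(np.mean(z)) < 0.1

    def test_determinism(self, dropped):
        cfg, ped, _ = dropped
        g1 = drop_genotypes(ped, cfg)
        g2 = drop_genotypes(ped, cfg)
        assert np.array_equal(g1.dosages, g2.dosages)


class TestPhenotypes:
    def test_type_b_one_gives_identical_site_effects(self):
        cfg = SimConfig(
            n_markers=300, n_qtl=100, n_parents=10, n_families=15,
            progeny_range=(3, 4), trait_specs=(("t", 0.4, 1.0),), seed=2,
        )
        ped, geno, pheno, truth = simulate_trial(cfg)
        eff = truth.marker_effects["t"]
        np.testing.assert_allclose(eff[:, 0], eff[:, 1], atol=1e-10)

    def test_near_unit_heritability_phenotype_tracks_tbv(self):
        cfg = SimConfig(
            n_markers=300, n_qtl=100, n_parents=10, n_families=15,
            progeny_range=(4, 6), trait_specs=(("t", 0.999, 0.9),),
            block_variance_fraction=0.0, seed=2,
        )
        ped, geno, pheno, truth = simulate_trial(cfg)
        pos = {s: i for i, s in enumerate(truth.ids)}
        for site in ("site1", "site2"):
            sub = pheno.frame[pheno.frame["site"] == site]
            scode = 0 if site == "site1" else 1
            tbv = np.array([truth.tbv["t"][pos[t], scode] for t in sub["tree"]])
            r = np.corrcoef(sub["t"], tbv)[0, 1]
            assert r > 0.99

    def test_effect_correlation_matches_type_b_target(self):
        target = 0.45
        rs = []
        for seed in range(4):
            cfg = SimConfig(
                n_markers=700, n_qtl=600, n_parents=10, n_families=15,
                progeny_range=(2, 3), trait_specs=(("t", 0.3, target),), seed=seed,
            )
            ped, geno, pheno, truth = simulate_trial(cfg)
            eff = truth.marker_effects["t"]
            qtl = truth.qtl_indices["t"]
            rs.append(np.corrcoef(eff[qtl, 0], eff[qtl, 1])[0, 1])
        assert abs(np.mean(rs) - target) < 0.05

    def test_zero_heritability_gives_zero_tbv(self):
        cfg = SimConfig(
            n_markers=100, n_qtl=50, n_parents=8, n_families=10,
            progeny_range=(2, 3), trait_specs=(("t", 0.0, 0.0),), seed=1,
        )
        _, _, _, truth = simulate_trial(cfg)
        assert np.all(truth.tbv["t"] == 0)


class TestTrialIO:
    def test_round_trip_preserves_everything(self, tmp_path, small_trial):
        ped, geno, pheno, _ = small_trial
        write_trial(geno, ped, pheno, tmp_path)
        geno2, ped2, pheno2 = read_trial(tmp_path)
        assert np.array_equal(geno.dosages, geno2.dosages)
        assert list(geno2.samples) == list(geno.samples)
        assert list(geno2.markers) == list(geno.markers)
        assert list(ped2.ids) == list(ped.ids)
        got = pheno2.frame.sort_values("tree").reset_index(drop=True)
        want = pheno.frame.sort_values("tree").reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want, check_like=True, atol=1e-9)

    def test_missing_genotype_round_trips_as_nan(self, tmp_path):
        geno = GenotypeMatrix(
            ["s1", "s2"], ["m1"], np.array([[np.nan], [1.0]])
        )
        simdata.write_vcf(geno, tmp_path / "genotypes.vcf")
        text = (tmp_path / "genotypes.vcf").read_text()
        assert "./." in text
        back = simdata.read_vcf(tmp_path / "genotypes.vcf")
        assert np.isnan(back.dosages[0, 0])
        assert back.dosages[1, 0] == 1.0

    def test_unordered_pedigree_csv_is_reordered(self, tmp_path, small_trial):
        ped, geno, pheno, _ = small_trial
        write_trial(geno, ped, pheno, tmp_path)
        frame = pd.read_csv(tmp_path / "pedigree.csv", dtype=str)
        frame.iloc[::-1].to_csv(tmp_path / "pedigree.csv", index=False)
        _, ped2, _ = read_trial(tmp_path)
        order = {iid: k for k, iid in enumerate(ped2.ids)}
        for row in ped2.frame.itertuples(index=False):
            for par in (row.sire, row.dam):
                if par != "0":
                    assert order[par] < order[row.id]

    def test_pedigree_cycle_detected(self, tmp_path, small_trial):
        ped, geno, pheno, _ = small_trial
        write_trial(geno, ped, pheno, tmp_path)
        frame = pd.read_csv(tmp_path / "pedigree.csv", dtype=str)
        # make the first founder a child of its own grandchild
        prog = frame[frame["sire"] != "0"].iloc[0]
        frame.loc[frame["id"] == prog["sire"], ["sire", "dam"]] = [
            prog["id"], prog["id"],
        ]
        frame.to_csv(tmp_path / "pedigree.csv", index=False)
        with pytest.raises(PedigreeError, match="cycle"):
            read_trial(tmp_path)

    def test_phenotyped_tree_missing_from_pedigree_fatal(self, tmp_path, small_trial):
        ped, geno, pheno, _ = small_trial
        write_trial(geno, ped, pheno, tmp_path)
        frame = pd.read_csv(tmp_path / "phenotypes.csv")
        frame.loc[0, "tree"] = "GHOST"
        frame.to_csv(tmp_path / "phenotypes.csv", index=False)
        with pytest.raises(ParseError, match="absent from pedigree"):
            read_trial(tmp_path)


def test_pedigree_relationships_exact(small_trial):
    """Parent-offspring and full-sib A entries are exactly 0.5, half sibs 0.25."""
    ped, _, _, _ = small_trial
    A = a_matrix(ped)
    pos = {s: i for i, s in enumerate(A.ids)}
    prog = ped.frame[ped.frame["sire"] != "0"]
    row = prog.iloc[0]
    assert A.values[pos[row["id"]], pos[row["sire"]]] == 0.5
    assert A.values[pos[row["id"]], pos[row["dam"]]] == 0.5
    fam = family_of(ped)
    f0 = fam.unique()[0]
    members = fam.index[fam == f0].to_numpy()
    assert A.values[pos[members[0]], pos[members[1]]] == 0.5
    # half sibs: two families sharing exactly one parent
    fams = [(f, set(f.split("x"))) for f in fam.unique()]
    for i in range(len(fams)):
        for j in range(i + 1, len(fams)):
            shared = fams[i][1] & fams[j][1]
            if len(shared) == 1:
                a = fam.index[fam == fams[i][0]][0]
                b = fam.index[fam == fams[j][0]][0]
                assert A.values[pos[a], pos[b]] == 0.25
                return
    pytest.skip("no half-sib family pair in this draw")
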