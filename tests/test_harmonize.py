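import numpy as np
import pytest

from conftest import make_table
from neuromr.harmonize import (COMPLEMENT, HarmonizedInstruments,
                               MvmrInfeasibleError, _align_one, harmonize,
                               harmonize_multi)
from neuromr.simulate import SimulationTruth, generate

BAND = (0.42, 0.58)


def pair_tables(exp_row: dict, out_row: dict):
    e = make_table([dict({"snp_id": "rs1"}, **exp_row)], "exp")
    o = make_table([dict({"snp_id": "rs1"}, **out_row)], "out", "binary")
    return e, o


class TestAlignmentRules:
    def test_swapped_alleles_flip_outcome_sign(self):
        e, o = pair_tables(
            {"effect_allele": "A", "other_allele": "G", "beta": 0.1, "eaf": 0.3},
            {"effect_allele": "G", "other_allele": "A", "beta": -0.05, "eaf": 0.7},
        )
        h = harmonize(e, o, ["rs1"])
        assert h.beta_y[0] == pytest.approx(0.05)
        assert h.eaf_y[0] == pytest.approx(0.3)
        assert list(h.log["action"]) == ["sign-flipped"]

    def test_palindromic_intermediate_frequency_dropped(self):
        e, o = pair_tables(
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.50},
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.50},
        )
        with pytest.raises(Exception):
            harmonize(e, o, ["rs1"])  # sole SNP dropped -> empty set
        e2 = make_table([{"snp_id": "rs1", "effect_allele": "A",
                          "other_allele": "T", "eaf": 0.5},
                         {"snp_id": "rs2"}], "exp")
        o2 = make_table([{"snp_id": "rs1", "effect_allele": "A",
                          "other_allele": "T", "eaf": 0.5},
                         {"snp_id": "rs2"}], "out", "binary")
        h = harmonize(e2, o2, ["rs1", "rs2"])
        assert list(h.snp_ids) == ["rs2"]
        row = h.log[h.log.snp_id == "rs1"].iloc[0]
        assert row["action"] == "dropped-palindromic"

    def test_complementary_strand_same_orientation(self):
        e, o = pair_tables(
            {"effect_allele": "A", "other_allele": "G", "beta": 0.1, "eaf": 0.3},
            {"effect_allele": "T", "other_allele": "C", "beta": 0.07, "eaf": 0.3},
        )
        h = harmonize(e, o, ["rs1"])
        assert h.beta_y[0] == pytest.approx(0.07)
        assert list(h.log["action"]) == ["strand-flipped"]

    def test_irreconcilable_alleles_never_silently_kept(self):
        e2 = make_table([{"snp_id": "rs1", "effect_allele": "A",
                          "other_allele": "G"}, {"snp_id": "rs2"}], "exp")
        o2 = make_table([{"snp_id": "rs1", "effect_allele": "A",
                          "other_allele": "C"}, {"snp_id": "rs2"}], "out", "binary")
        h = harmonize(e2, o2, ["rs1", "rs2"])
        assert list(h.snp_ids) == ["rs2"]
        assert h.log[h.log.snp_id == "rs1"]["action"].iloc[0] == "dropped-unmatched"

    def test_all_allele_pair_cases_against_truth_table(self):
        """Enumerate outcome representations of an exposure A/G SNP."""
        cases = {
            ("A", "G"): ("kept", 1.0),
            ("G", "A"): ("sign-flipped", -1.0),
            ("T", "C"): ("strand-flipped", 1.0),
            ("C", "T"): ("strand-flipped", -1.0),
            ("A", "C"): ("dropped-unmatched", None),
            ("C", "G"): ("dropped-unmatched", None),
            ("T", "G"): ("dropped-unmatched", None),
            ("A", "T"): ("dropped-unmatched", None),
        }
        for (ea_y, oa_y), (action, sign) in cases.items():
            got = _align_one("A", "G", 0.3, ea_y, oa_y, 0.3, BAND)
            assert got[0] == action, (ea_y, oa_y)
            assert got[1] == sign, (ea_y, oa_y)

    def test_palindrome_frequency_alignment(self):
        # same side of 0.5: keep orientation
        action, sign, eaf = _align_one("A", "T", 0.2, "A", "T", 0.25, BAND)
        assert (action, sign) == ("kept", 1.0)
        # opposite sides: the outcome is on the other strand
        action, sign, eaf = _align_one("A", "T", 0.2, "A", "T", 0.8, BAND)
        assert (action, sign) == ("strand-flipped", -1.0)
        assert eaf == pytest.approx(0.2)
        # missing frequency: drop
        action, sign, _ = _align_one("C", "G", np.nan, "C", "G", 0.2, BAND)
        assert action == "dropped-palindromic" and sign is None

    def test_band_zero_one_drops_all_palindromes(self):
        action, sign, _ = _align_one("A", "T", 0.05, "A", "T", 0.05, (0.0, 1.0))
        assert action == "dropped-palindromic" and sign is None


class TestHarmonizeProperties:
    def test_involution_on_harmonized_data(self):
        """Harmonizing already-aligned tables changes nothing."""
        ds = generate(SimulationTruth(theta=0.3, seed=21, palindrome_frac=0.1))
        h1 = harmonize(ds.exposure, ds.outcome, list(ds.exposure.df["snp_id"]))
        # rebuild an outcome table that is already aligned to the exposure
        aligned = ds.exposure.df.copy()
        keep = aligned["snp_id"].isin(h1.snp_ids)
        aligned = aligned[keep].reset_index(drop=True)
        aligned["beta"] = h1.beta_y
        aligned["se"] = h1.se_y
        aligned["eaf"] = h1.eaf_y
        from neuromr.sumstats import SummaryStatsTable
        out2 = SummaryStatsTable("outcome", "binary", aligned)
        h2 = harmonize(ds.exposure, out2, list(h1.snp_ids))
        assert np.array_equal(h1.snp_ids, h2.snp_ids)
        assert np.allclose(h1.beta_y, h2.beta_y)
        assert set(h2.log["action"]) == {"kept"}

    def test_wald_ratio_invariant_to_re_polarization(self):
        """Randomly flipping which allele a file reports leaves ratios fixed."""
        ds = generate(SimulationTruth(theta=0.3, seed=22, j_instruments=30))
        ids = list(ds.exposure.df["snp_id"])
        h1 = harmonize(ds.exposure, ds.outcome, ids)
        rng = np.random.default_rng(0)
        flipped = ds.exposure.df.copy()
        mask = rng.random(len(flipped)) < 0.5
        ea = flipped["effect_allele"].copy()
        flipped.loc[mask, "effect_allele"] = flipped.loc[mask, "other_allele"]
        flipped.loc[mask, "other_allele"] = ea[mask]
        flipped.loc[mask, "beta"] = -flipped.loc[mask, "beta"]
        flipped.loc[mask, "eaf"] = 1 - flipped.loc[mask, "eaf"]
        from neuromr.sumstats import SummaryStatsTable
        exp2 = SummaryStatsTable("exposure", "continuous", flipped)
        h2 = harmonize(exp2, ds.outcome, ids)
        assert np.array_equal(h1.snp_ids, h2.snp_ids)
        assert np.allclose(h1.beta_y / h1.beta_x, h2.beta_y / h2.beta_x)

    def test_palindrome_drop_count_matches_ambiguous_count(self):
        ds = generate(SimulationTruth(theta=0.3, seed=23, j_instruments=60,
                                      palindrome_frac=0.3))
        ids = list(ds.exposure.df["snp_id"])
        h = harmonize(ds.exposure, ds.outcome, ids)
        df = ds.exposure.df
        pal = df.apply(lambda r: COMPLEMENT[r["effect_allele"]] == r["other_allele"],
                       axis=1)
        ambiguous = pal & df["eaf"].between(0.42, 0.58, inclusive="neither")
        n_dropped = (h.log["action"] == "dropped-palindromic").sum()
        assert n_dropped == int(ambiguous.sum())


class TestHarmonizeMulti:
    def _tables(self, seed=31, j=40):
        rng = np.random.default_rng(seed)
        rows_x = []
        for i in range(j):
            rows_x.append({"snp_id": f"rs{i}", "beta": rng.normal(0.05, 0.01),
                           "eaf": float(rng.uniform(0.1, 0.4))})
        e1 = make_table(rows_x, "e1")
        e2 = make_table([dict(r, beta=r["beta"] * 0.5) for r in rows_x], "e2")
        e3 = make_table([dict(r, beta=r["beta"] * 0.2) for r in rows_x], "e3")
        out = make_table([dict(r, beta=r["beta"] * 0.3) for r in rows_x],
                         "out", "binary")
        return [e1, e2, e3], out

    def test_intersection_shape(self):
        exps, out = self._tables()
        h = harmonize_multi(exps, out, [f"rs{i}" for i in range(40)])
        assert h.beta_x.shape == (40, 3)
        assert h.n_exposures == 3

    def test_missing_snp_dropped(self):
        exps, out = self._tables()
        exps[1] = exps[1].subset([f"rs{i}" for i in range(39)])  # drop rs39
        h = harmonize_multi(exps, out, [f"rs{i}" for i in range(40)])
        assert h.beta_x.shape == (39, 3)
        assert "rs39" not in set(h.snp_ids)

    def test_flipping_one_exposure_file_leaves_matrix_unchanged(self):
        exps, out = self._tables()
        h1 = harmonize_multi(exps, out, [f"rs{i}" for i in range(40)])
        df = exps[1].df.copy()
        ea = df["effect_allele"].copy()
        df["effect_allele"] = df["other_allele"]
        df["other_allele"] = ea
        df["beta"] = -df["beta"]
        df["eaf"] = 1 - df["eaf"]
        from neuromr.sumstats import SummaryStatsTable
        exps[1] = SummaryStatsTable("e2", "continuous", df)
        h2 = harmonize_multi(exps, out, [f"rs{i}" for i in range(40)])
        assert np.allclose(h1.beta_x, h2.beta_x)

    def test_too_few_joint_snps_raises(self):
        exps, out = self._tables(j=3)
        exps = [e.subset(["rs0", "rs1", "rs2"]) for e in exps]
        with pytest.raises(MvmrInfeasibleError):
            harmonize_multi(exps, out, ["rs0", "rs1", "rs2"])


def test_se_positive_enforced():
    with pytest.raises(ValueError):
        HarmonizedInstruments(["x"], "y", np.array(["rs1"], dtype=object),
                              np.array([0.1]), np.array([0.01]),
                              np.array([0.05]), np.array([0.0]))
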