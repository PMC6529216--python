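"""CSC / ASC statistics, leave-one-out variant, concordance and covariates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import codonopt as co
from codonopt.optimality_stats import most_abundant_synonymous


@pytest.fixture(scope="module")
def comp3000():
    scn = co.SimScenario(n_genes=3000, seed=101)
    _, comp = co.simulate_transcriptome(scn)
    return comp


@pytest.fixture(scope="module")
def comp500():
    scn = co.SimScenario(n_genes=500, seed=55)
    _, comp = co.simulate_transcriptome(scn)
    return comp


class TestComputeCSC:
    def test_perfect_linear_dependence_gives_unit_csc(self, comp500):
        rng = np.random.default_rng(0)
        stab = pd.Series(
            5.0 * comp500.freq["AAA"] + rng.normal(0, 1e-9, len(comp500.freq)),
            index=comp500.freq.index,
        )
        csc = co.compute_csc(stab, comp500)
        assert csc.loc["AAA", "r"] == pytest.approx(1.0, abs=1e-3)

    def test_permuted_stability_kills_signal(self, comp3000):
        rng = np.random.default_rng(12)
        stab = pd.Series(
            rng.permutation(comp3000.freq["AAA"].to_numpy()), index=comp3000.freq.index
        )
        csc = co.compute_csc(stab, comp3000)
        assert csc["r"].abs().mean() < 0.05

    def test_affine_invariance_and_sign_flip(self, comp500, rng):
        stab = pd.Series(rng.normal(size=len(comp500.freq)), index=comp500.freq.index)
        base = co.compute_csc(stab, comp500)
        scaled = co.compute_csc(2.0 * stab + 7.0, comp500)
        np.testing.assert_allclose(base["r"], scaled["r"], atol=1e-12)
        negated = co.compute_csc(-stab, comp500)
        np.testing.assert_allclose(base["r"], -negated["r"], atol=1e-12)

    def test_effect_recovery_with_noise(self, comp3000):
        """Known per-codon effects are recovered through the correlation even
        with noise comparable to the signal (sd = 0.3 x signal sd)."""
        rng = np.random.default_rng(77)
        effects = pd.Series(
            rng.normal(0, 0.05, 61), index=list(co.SENSE_CODONS)
        )
        signal = (comp3000.freq * 100.0) @ effects
        stab = signal + rng.normal(0, 0.3 * signal.std(), len(signal))
        csc = co.compute_csc(stab, comp3000)
        rho = stats.spearmanr(effects, csc["r"])[0]
        assert rho >= 0.9

    def test_too_few_genes_errors(self, comp500):
        stab = pd.Series(1.0, index=comp500.freq.index[:5])
        with pytest.raises(ValueError, match="at least 10"):
            co.compute_csc(stab, comp500)

    def test_absent_codon_reported_na(self):
        # genes made only of AAA and AAG: every other codon has zero variance
        cds = [
            co.CodingSequence(f"g{i}", "AAA" * (i + 1) + "AAG" * (12 - i))
            for i in range(12)
        ]
        comp = co.build_composition(cds)
        stab = pd.Series(np.linspace(0, 1, 12), index=comp.freq.index)
        csc = co.compute_csc(stab, comp)
        assert np.isnan(csc.loc["TTT", "r"])
        assert not np.isnan(csc.loc["AAA", "r"])


class TestASC:
    def test_perfect_amino_acid_dependence(self, comp500):
        aa = co.amino_acid_composition(comp500)
        rng = np.random.default_rng(3)
        stab = pd.Series(
            3.0 * aa.freq["H"] + rng.normal(0, 1e-9, len(aa.freq)),
            index=aa.freq.index,
        )
        asc = co.compute_asc(stab, aa)
        assert asc.loc["H", "r"] == pytest.approx(1.0, abs=1e-3)

    def test_asc_equals_csc_of_pooled_frequency_column(self, comp500, rng):
        stab = pd.Series(rng.normal(size=len(comp500.freq)), index=comp500.freq.index)
        aa = co.amino_acid_composition(comp500)
        asc = co.compute_asc(stab, aa)
        for target_aa in ("L", "S", "G"):
            pooled = comp500.freq[list(co.AA_TO_CODONS[target_aa])].sum(axis=1)
            r_direct = stats.pearsonr(pooled, stab)[0]
            assert asc.loc[target_aa, "r"] == pytest.approx(r_direct, abs=1e-12)

    def test_permuted_stability_null(self, comp3000):
        rng = np.random.default_rng(9)
        stab = pd.Series(rng.normal(size=len(comp3000.freq)), index=comp3000.freq.index)
        asc = co.compute_asc(rng.permutation(stab.to_numpy()) + 0 * stab, co.amino_acid_composition(comp3000))
        assert asc["r"].abs().mean() < 0.05


class TestASCDropMostAbundant:
    def test_single_codon_amino_acids_are_na(self, comp500, rng):
        stab = pd.Series(rng.normal(size=len(comp500.freq)), index=comp500.freq.index)
        dropped = co.asc_drop_most_abundant(stab, comp500)
        assert np.isnan(dropped.loc["M", "r"])
        assert np.isnan(dropped.loc["W", "r"])

    def test_dominant_codon_flips_leucine_sign(self):
        """An amino acid whose dominant synonymous codon is stabilizing while
        the minor codons are destabilizing looks optimal overall but flips
        sign once the dominant codon is removed."""
        weights = {c: 1.0 for c in co.SENSE_CODONS}
        weights["CTG"] = 20.0  # ~80% of Leu counts
        scn = co.SimScenario(n_genes=1000, seed=17, base_weights=weights, noise_sd=0.1)
        _, comp = co.simulate_transcriptome(scn)
        leu = co.AA_TO_CODONS["L"]
        assert comp.raw["CTG"].sum() / comp.raw[list(leu)].sum().sum() > 0.7
        effects = pd.Series(0.0, index=list(co.SENSE_CODONS))
        effects["CTG"] = 0.1
        for c in leu:
            if c != "CTG":
                effects[c] = -0.1
        rates = co.assign_rates(comp, effects, scn)
        stab = -rates
        asc_all = co.compute_asc(stab, co.amino_acid_composition(comp))
        asc_drop = co.asc_drop_most_abundant(stab, comp)
        assert asc_drop.attrs["dropped"]["L"] == "CTG"
        assert asc_all.loc["L", "r"] > 0
        assert asc_drop.loc["L", "r"] < 0

    def test_equal_effects_across_synonymous_codons_agree(self, comp3000):
        """When all synonymous codons share the amino acid's effect, dropping
        the dominant codon leaves the sign and rough magnitude unchanged."""
        rng = np.random.default_rng(23)
        aa_effects = {a: rng.normal(0, 0.05) for a in co.AMINO_ACIDS}
        effects = pd.Series(
            {c: aa_effects[co.CODON_TO_AA[c]] for c in co.SENSE_CODONS}
        )
        scn = co.SimScenario(n_genes=3000, seed=101, noise_sd=0.1)
        rates = co.assign_rates(comp3000, effects, scn)
        stab = -rates
        asc_all = co.compute_asc(stab, co.amino_acid_composition(comp3000))
        asc_drop = co.asc_drop_most_abundant(stab, comp3000)
        both = pd.DataFrame({"all": asc_all["r"], "drop": asc_drop["r"]}).dropna()
        strong = both[both["all"].abs() > 0.1]
        assert (np.sign(strong["all"]) == np.sign(strong["drop"])).all()

    def test_most_abundant_identification(self, comp500):
        dominant = most_abundant_synonymous(comp500)
        totals = comp500.raw.sum(axis=0)
        for aa, codon in dominant.items():
            assert totals[codon] == max(totals[c] for c in co.AA_TO_CODONS[aa])


class TestConcordanceAndCovariates:
    def _csc(self, values):
        return pd.DataFrame(
            {"r": values, "p": 0.5, "n": 100}, index=list(co.SENSE_CODONS)
        )

    def test_identical_tables_rho_one(self, rng):
        t = self._csc(rng.normal(size=61))
        rho, p = co.correlate_csc_tables(t, t)
        assert rho == pytest.approx(1.0)

    def test_negated_table_rho_minus_one(self, rng):
        t = self._csc(rng.normal(size=61))
        rho, _ = co.correlate_csc_tables(t, self._csc(-t["r"].to_numpy()))
        assert rho == pytest.approx(-1.0)

    def test_independent_tables_near_null(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = self._csc(rng.normal(size=61))
            b = self._csc(rng.normal(size=61))
            rho, _ = co.correlate_csc_tables(a, b)
            hits += abs(rho) < 0.35
        assert hits >= 19

    def test_anticodon_reverse_complement(self):
        assert co.map_anticodon_to_codon("UUU") == "AAA"
        assert co.map_anticodon_to_codon("CAT") == "ATG"

    def test_covariate_equal_to_csc_rho_one(self, rng):
        t = self._csc(rng.normal(size=61))
        rho, _ = co.correlate_csc_with_covariate(t, t["r"])
        assert rho == pytest.approx(1.0)

    def test_monotone_transform_rank_invariance(self, rng):
        t = self._csc(rng.normal(size=61))
        rho, _ = co.correlate_csc_with_covariate(t, np.exp(3 * t["r"]))
        assert rho == pytest.approx(1.0)

    def test_anticodon_keyed_covariate(self, rng):
        t = self._csc(rng.normal(size=61))
        cov = t["r"].copy()
        cov.index = [co.map_anticodon_to_codon(c) for c in cov.index]  # involution
        rho, _ = co.correlate_csc_with_covariate(t, cov, key="anticodon")
        assert rho == pytest.approx(1.0)


class TestUsageCorrelation:
    def test_usage_equal_to_csc_rank_gives_one(self, comp500, rng):
        usage = comp500.raw.sum(axis=0) / comp500.raw.to_numpy().sum()
        csc = pd.DataFrame(
            {"r": stats.rankdata(usage), "p": 0.5, "n": 10}, index=usage.index
        )
        rho, _ = co.codon_usage_correlation(comp500, csc)
        assert rho == pytest.approx(1.0)

    def test_uniform_usage_undefined(self):
        cds = [co.CodingSequence(f"g{i}", "".join(co.SENSE_CODONS)) for i in range(12)]
        comp = co.build_composition(cds)
        csc = pd.DataFrame(
            {"r": np.linspace(-1, 1, 61), "p": 0.5, "n": 12},
            index=list(co.SENSE_CODONS),
        )
        rho, p = co.codon_usage_correlation(comp, csc)
        assert np.isnan(rho) and np.isnan(p)

    def test_effects_independent_of_usage_near_null(self, comp3000):
        rng = np.random.default_rng(19)
        effects = pd.Series(rng.normal(0, 0.05, 61), index=list(co.SENSE_CODONS))
        stab = (comp3000.freq * 100.0) @ effects
        csc = co.compute_csc(stab, comp3000)
        rho, _ = co.codon_usage_correlation(comp3000, csc)
        assert abs(rho) < 0.35


class TestStabilityConventions:
    def test_log2_halflife_excludes_nonpositive_rates(self):
        est = pd.DataFrame({"rate_k": [0.5, -0.1, 0.0]}, index=list("abc"))
        s = co.make_stability(est, convention="log2_halflife")
        assert list(s.index) == ["a"]
        assert s["a"] == pytest.approx(np.log2(np.log(2) / 0.5))

    def test_neg_rate_keeps_all_finite(self):
        est = pd.DataFrame({"rate_k": [0.5, -0.1, np.nan]}, index=list("abc"))
        s = co.make_stability(est)
        assert list(s.index) == ["a", "b"]
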