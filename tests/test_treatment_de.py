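import numpy as np
import pandas as pd
import pytest

from astrodiverge.io_formats import ExpressionTable, OrthologTable
from astrodiverge import treatment_de
from astrodiverge.treatment_de import DirectionalGeneSets
from astrodiverge.synthetic_data import TwoSpeciesSimConfig, gen_treatment_experiment


def _counts(values: dict, genes):
    df = pd.DataFrame(values, index=genes).astype(float)
    meta = pd.DataFrame({"species": "human", "condition": "x"}, index=df.columns)
    return ExpressionTable(df, meta)


class TestNbTwoGroupTest:
    def test_duplicated_columns_give_null_result(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        base = rng.poisson(50, size=(30, 2)).astype(float)
        expr = _counts({"c1": base[:, 0], "c2": base[:, 1],
                        "t1": base[:, 0], "t2": base[:, 1]}, genes)
        table = treatment_de.nb_two_group_test(expr, ["c1", "c2"], ["t1", "t2"])
        np.testing.assert_allclose(table["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["p"], 1.0)

    def test_all_zero_gene_excluded(self):
        expr = _counts({"c1": [10, 0], "c2": [12, 0], "t1": [9, 0], "t2": [11, 0]},
                       ["gA", "gZero"])
        table = treatment_de.nb_two_group_test(expr, ["c1", "c2"], ["t1", "t2"])
        assert "gZero" not in table.index and "gA" in table.index

    def test_too_few_samples_rejected(self):
        expr = _counts({"c1": [5], "t1": [5], "t2": [6]}, ["gA"])
        with pytest.raises(ValueError, match="2 samples"):
            treatment_de.nb_two_group_test(expr, ["c1"], ["t1", "t2"])

    def test_null_type_i_error_calibrated(self):
        """Type-I at p<0.05 near nominal on null NB data (pooled over seeds)."""
        rates = []
        for seed in range(10):
            cfg = TwoSpeciesSimConfig(n_genes=2000, n_samples_per_group=4,
                                      frac_responsive=0.0, response_log2fc=0.0,
                                      seed=7000 + seed)
            h, *_ = gen_treatment_experiment(cfg)
            tab = treatment_de.nb_two_group_test(
                h, h.samples_where(condition="control"),
                h.samples_where(condition="treated"))
            rates.append((tab["p"] < 0.05).mean())
        assert 0.03 <= np.mean(rates) <= 0.07


class TestDegFilter:
    def _table(self, **cols):
        n = len(next(iter(cols.values())))
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])

    def test_rpkm_disjunction_and_thresholds(self):
        table = self._table(
            log2fc=[np.log2(1.6), np.log2(1.6), -np.log2(1.6)],
            fdr=[0.04, 0.04, 0.04],
            mean_rpkm_control=[0.5, 0.5, 2.0],
            mean_rpkm_treated=[2.0, 0.5, 0.5],
        )
        sets = treatment_de.deg_filter(table)
        assert sets.up == {"g0"}       # passes via treated-group RPKM
        assert sets.down == {"g2"}     # symmetric filter, control-group RPKM
        # g1 fails the expression filter in both groups

    def test_infinite_fc_cut_empties_sets(self):
        table = self._table(log2fc=[5.0, -5.0], fdr=[0.001, 0.001],
                            mean_rpkm_control=[10.0, 10.0], mean_rpkm_treated=[10.0, 10.0])
        sets = treatment_de.deg_filter(table, fc_cut=np.inf)
        assert sets.up == set() and sets.down == set()

    def test_label_swap_exchanges_up_and_down(self):
        rng = np.random.default_rng(1)
        table = self._table(log2fc=rng.normal(0, 2, 50).tolist(),
                            fdr=rng.uniform(0, 0.1, 50).tolist(),
                            mean_rpkm_control=[5.0] * 50, mean_rpkm_treated=[5.0] * 50)
        swapped = table.copy()
        swapped["log2fc"] = -swapped["log2fc"]
        swapped[["mean_rpkm_control", "mean_rpkm_treated"]] = (
            table[["mean_rpkm_treated", "mean_rpkm_control"]].to_numpy())
        a = treatment_de.deg_filter(table)
        b = treatment_de.deg_filter(swapped)
        assert a.up == b.down and a.down == b.up


class TestCrossSpeciesOverlap:
    def _orth(self, genes):
        return OrthologTable(pd.DataFrame(
            {"human": list(genes), "mouse": [g.lower() for g in genes]}))

    def test_printed_hypoxia_percentage(self):
        """322 human-down genes, 11 shared with mouse -> 3.4% (1 d.p.)."""
        genes = [f"G{i}" for i in range(400)]
        orth = self._orth(genes)
        human = DirectionalGeneSets(up=set(genes[350:360]), down=set(genes[:322]))
        mouse = DirectionalGeneSets(up={g.lower() for g in genes[350:355]},
                                    down={g.lower() for g in genes[:11]})
        out = treatment_de.cross_species_deg_overlap(human, mouse, orth)
        assert out.loc["down", "n_overlap"] == 11
        assert round(out.loc["down", "pct_of_human"], 1) == 3.4

    def test_identity_and_disjoint_extremes(self):
        genes = [f"G{i}" for i in range(20)]
        orth = self._orth(genes)
        full = DirectionalGeneSets(up=set(genes[:10]), down=set(genes[10:]))
        same = DirectionalGeneSets(up={g.lower() for g in genes[:10]},
                                   down={g.lower() for g in genes[10:]})
        out = treatment_de.cross_species_deg_overlap(full, same, orth)
        assert (out["pct_of_human"] == 100.0).all()
        flipped = DirectionalGeneSets(up={g.lower() for g in genes[10:]},
                                      down={g.lower() for g in genes[:10]})
        out2 = treatment_de.cross_species_deg_overlap(full, flipped, orth)
        assert (out2["pct_of_human"] == 0.0).all()

    def test_empty_human_set_signaled(self):
        orth = self._orth(["A"])
        with pytest.raises(ValueError, match="empty human"):
            treatment_de.cross_species_deg_overlap(
                DirectionalGeneSets(up=set(), down={"A"}),
                DirectionalGeneSets(up={"a"}, down=set()), orth)

    def test_percentage_invariant_under_consistent_renaming(self):
        genes = [f"G{i}" for i in range(30)]
        orth = self._orth(genes)
        h = DirectionalGeneSets(up=set(genes[:12]), down=set(genes[12:20]))
        m = DirectionalGeneSets(up={g.lower() for g in genes[5:15]},
                                down={g.lower() for g in genes[15:25]})
        base = treatment_de.cross_species_deg_overlap(h, m, orth)
        renamed = OrthologTable(pd.DataFrame(
            {"human": [f"X{g}" for g in genes], "mouse": [g.lower() for g in genes]}))
        h2 = DirectionalGeneSets(up={f"X{g}" for g in h.up}, down={f"X{g}" for g in h.down})
        out = treatment_de.cross_species_deg_overlap(h2, m, renamed)
        np.testing.assert_allclose(out["pct_of_human"], base["pct_of_human"])


class TestEffectsizeAndConservedFraction:
    def test_identity_orthology_gives_r_one(self):
        genes = list("abcdef")
        table = pd.DataFrame({"log2fc": [0.5, -1.0, 2.0, 0.1, -0.4, 1.1]}, index=genes)
        orth = OrthologTable(pd.DataFrame({"human": genes, "mouse": genes}))
        r, p, n = treatment_de.effectsize_summary(table, table, orth)
        assert r == pytest.approx(1.0) and n == 6

    def test_independent_null_uncorrelated_and_planted_signal_detected(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(2000)]
        orth = OrthologTable(pd.DataFrame({"human": genes, "mouse": genes}))
        a = pd.DataFrame({"log2fc": rng.normal(size=2000)}, index=genes)
        b = pd.DataFrame({"log2fc": rng.normal(size=2000)}, index=genes)
        r_null, _, _ = treatment_de.effectsize_summary(a, b, orth)
        assert abs(r_null) < 0.1
        shared = rng.normal(size=2000)
        c = pd.DataFrame({"log2fc": shared + rng.normal(scale=1.0, size=2000)}, index=genes)
        d = pd.DataFrame({"log2fc": shared + rng.normal(scale=1.0, size=2000)}, index=genes)
        r_sig, p_sig, _ = treatment_de.effectsize_summary(c, d, orth)
        assert r_sig > 0 and p_sig < 0.01

    def test_conserved_fraction_recovered_from_overlap(self):
        """Union-based estimate lands within 0.1 of the planted fraction."""
        cfg = TwoSpeciesSimConfig(n_genes=2000, n_samples_per_group=4,
                                  frac_responsive=0.1, response_log2fc=2.0,
                                  conserved_fraction=0.5, seed=77)
        h, m, orth, lengths, truth = gen_treatment_experiment(cfg)
        sets = {}
        for sp, expr in (("human", h), ("mouse", m)):
            tab = treatment_de.nb_two_group_test(
                expr, expr.samples_where(condition="control"),
                expr.samples_where(condition="treated"), lengths=lengths)
            sets[sp] = treatment_de.deg_filter(tab)
        overlap = treatment_de.cross_species_deg_overlap(sets["human"], sets["mouse"], orth)
        est = treatment_de.estimate_conserved_fraction(overlap)
        assert abs(est - 0.5) <= 0.1
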