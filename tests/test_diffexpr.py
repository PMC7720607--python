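"""Exact conditional tests, dispersion estimation, BH-FDR and DE profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import regendiv as rd
from regendiv.diffexpr import _binomial_pvalues, _nb_conditional_pvalue


def _two_group_frame(y_a, y_b, reps=1):
    """Counts DataFrame with `reps` identical replicates per group (so the
    pooled totals are exactly reps * y)."""
    data = {}
    for r in range(reps):
        data[f"a{r}"] = y_a
        data[f"b{r}"] = y_b
    return pd.DataFrame(data, index=[f"g{i}" for i in range(len(y_a))])


class TestExactTest:
    def test_symmetric_null_gene(self):
        """Equal counts with equal offsets: p = 1 and log2FC = 0."""
        counts = _two_group_frame([50, 7], [50, 7])
        tab = rd.exact_test(counts, ["a0"], ["b0"], mode="binomial",
                            factors=pd.Series(1.0, index=counts.columns))
        assert np.allclose(tab["pvalue"], 1.0)
        assert np.allclose(tab["log2fc"], 0.0)

    def test_extreme_split_exact_probability(self):
        """y_A=0, y_B=10 at equal offsets: doubled lower tail = 2 * 2^-10."""
        counts = _two_group_frame([0, 100], [10, 100])
        tab = rd.exact_test(counts, ["a0"], ["b0"], mode="binomial",
                            factors=pd.Series(1.0, index=counts.columns))
        assert tab.loc["g0", "pvalue"] == pytest.approx(2 * 0.5**10, abs=1e-15)

    def test_zero_total_gene(self):
        counts = _two_group_frame([0, 50], [0, 50])
        tab = rd.exact_test(counts, ["a0"], ["b0"], mode="binomial",
                            factors=pd.Series(1.0, index=counts.columns))
        assert tab.loc["g0", "pvalue"] == 1.0
        assert tab.loc["g0", "log2fc"] == 0.0

    def test_nb_zero_dispersion_matches_binomial(self):
        """Poisson-limit oracle: with phi=0 and equal offsets the conditional
        NB p equals the tail-doubled binomial p on 50 random cases."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            t = int(rng.integers(1, 400))
            y = int(rng.integers(0, t + 1))
            p_nb = _nb_conditional_pvalue(y, t, 0.5, 0.0, max_enum=10_000)
            p_bin = float(_binomial_pvalues(np.array([y]), np.array([t]), 0.5)[0])
            assert p_nb == pytest.approx(p_bin, abs=1e-9)

    def test_windowed_enumeration_matches_full(self):
        """The large-total window is numerically identical to full
        enumeration (the truncated mass is below double precision)."""
        for y, t, phi in [(480, 1000, 0.05), (520, 1000, 0.0), (700, 1000, 0.2)]:
            full = _nb_conditional_pvalue(y, t, 0.5, phi, max_enum=10_000)
            windowed = _nb_conditional_pvalue(y, t, 0.5, phi, max_enum=10)
            assert windowed == pytest.approx(full, rel=1e-9)

    @pytest.mark.parametrize("mode", ["binomial", "nb"])
    def test_group_swap_antisymmetry_is_exact(self, small_dataset, mode):
        """Swapping A and B negates log2FC and reproduces p bit for bit."""
        _, cm, _ = small_dataset
        sub = cm.subset_genes(cm.genes[:300])
        ga = sub.samples_of("AO_untreated")
        gb = sub.samples_of("NM_untreated")
        kw = dict(mode=mode, dispersion=0.1 if mode == "nb" else None)
        ab = rd.exact_test(sub, ga, gb, **kw)
        ba = rd.exact_test(sub, gb, ga, **kw)
        assert (ab["pvalue"].to_numpy() == ba["pvalue"].to_numpy()).all()
        assert np.allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)

    def test_input_validation(self, small_dataset):
        _, cm, _ = small_dataset
        with pytest.raises(ValueError, match="overlap"):
            rd.exact_test(cm, ["EP_r1"], ["EP_r1"])
        with pytest.raises(ValueError, match="non-empty"):
            rd.exact_test(cm, [], ["EP_r1"])
        with pytest.raises(ValueError, match="dispersion"):
            rd.exact_test(cm, ["EP_r1"], ["EP_r2"], mode="nb", dispersion=-1)


class TestDispersionEstimation:
    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(100, size=(5000, 4)),
            columns=["a1", "a2", "b1", "b2"],
        )
        phi = rd.estimate_common_dispersion(counts, [["a1", "a2"], ["b1", "b2"]])
        assert 0 <= phi < 0.02

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        phi_true, mu = 0.2, 100.0
        r = 1 / phi_true
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(5000, 4)),
            columns=["a1", "a2", "b1", "b2"],
        )
        phi = rd.estimate_common_dispersion(counts, [["a1", "a2"], ["b1", "b2"]])
        assert 0.15 <= phi <= 0.25

    def test_constant_replicates_floor_at_zero(self):
        counts = pd.DataFrame({"a1": [10, 20], "a2": [10, 20]})
        phi = rd.estimate_common_dispersion(counts, [["a1", "a2"]])
        assert phi == 0.0

    def test_no_replicates_warns_and_returns_zero(self):
        counts = pd.DataFrame({"a1": [10, 20], "b1": [11, 19]})
        with pytest.warns(UserWarning, match="replicate"):
            phi = rd.estimate_common_dispersion(counts, [["a1"], ["b1"]])
        assert phi == 0.0


def bh_oracle(pvals):
    """Brute-force BH step-up: q_(i) = min(1, min_{j>=i} p_(j) * n / j)."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        q[i] = running
    return q


class TestBH:
    def test_all_equal_p_unchanged(self):
        assert np.allclose(rd.bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_hand_computed_step_up(self):
        got = rd.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 12)).tolist()
            assert np.allclose(rd.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        q = rd.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rd.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            rd.bh_adjust([-0.1])


class TestClassifyDE:
    @pytest.mark.parametrize(
        "lfc,fdr,expected",
        [
            (1.2, 0.005, "up"),
            (1.0, 0.001, "ns"),   # strict |log2FC| > 1
            (-3.0, 0.02, "ns"),   # FDR fails
            (-1.5, 0.009, "down"),
            (2.0, 0.01, "ns"),    # strict FDR < 0.01
        ],
    )
    def test_strict_threshold_rule(self, lfc, fdr, expected):
        tab = pd.DataFrame({"log2fc": [lfc], "fdr": [fdr]}, index=["g"])
        n_up, n_down, n_ns, labels = rd.classify_de(tab)
        assert labels["g"] == expected
        assert n_up + n_down + n_ns == 1


class TestFoldChangeProfiles:
    def test_null_gene_profile_near_zero(self, small_dataset):
        """A background gene's log2FC-to-EP profile hovers around zero."""
        _, cm, truth = small_dataset
        sub = cm.subset_genes(cm.genes[:400])
        profiles, tables = rd.fold_change_to_reference(sub, dispersion=0.1)
        assert list(profiles.columns) == list(rd.SENSORY_CONDITIONS)
        bg = truth.index[truth["gene_class"] == "background"][:400]
        bg = [g for g in bg if g in profiles.index]
        assert profiles.loc[bg].abs().to_numpy().mean() < 0.4

    def test_planted_ao_specific_recovered(self, small_dataset):
        _, cm, truth = small_dataset
        profiles, _ = rd.fold_change_to_reference(cm, dispersion=0.1)
        ao = truth.index[truth["gene_class"] == "ao_specific"]
        ao_cols = [c for c in profiles.columns if c.startswith("AO")]
        nm_cols = [c for c in profiles.columns if c.startswith("NM")]
        assert profiles.loc[ao, ao_cols].to_numpy().mean() == pytest.approx(3.0, abs=0.3)
        assert abs(profiles.loc[ao, nm_cols].to_numpy().mean()) < 0.3

    def test_relabeling_organs_swaps_profile_halves(self, small_dataset):
        """Swapping the AO and NM labels exchanges the two profile halves."""
        _, cm, _ = small_dataset
        sub = cm.subset_genes(cm.genes[:200])
        swapped_meta = sub.metadata.copy()
        swapped_meta["organ"] = swapped_meta["organ"].map(
            {"AO": "NM", "NM": "AO", "EP": "EP"}
        )
        swapped = rd.CountMatrix(sub.counts.copy(), swapped_meta)
        p1, _ = rd.fold_change_to_reference(sub, dispersion=0.1)
        p2, _ = rd.fold_change_to_reference(swapped, dispersion=0.1)
        for tp in ("12hpt", "24hpt", "untreated"):
            assert np.allclose(p1[f"AO_{tp}"], p2[f"NM_{tp}"], atol=1e-12)
            assert np.allclose(p1[f"NM_{tp}"], p2[f"AO_{tp}"], atol=1e-12)

    def test_missing_condition_reported(self, small_dataset):
        _, cm, _ = small_dataset
        keep = [s for s in cm.samples if not s.startswith("AO_12hpt")]
        partial = rd.CountMatrix(cm.counts[keep], cm.metadata.loc[keep])
        with pytest.raises(ValueError, match="AO_12hpt"):
            rd.fold_change_to_reference(partial)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
             min_size=1, max_size=30)
)
def test_bh_is_order_preserving_and_bounded(pvals):
    q = rd.bh_adjust(pvals)
    assert ((q >= 0) & (q <= 1)).all()
    order = np.argsort(pvals, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-12).all()
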