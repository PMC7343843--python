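"""Unit and property tests for the two-state local-ancestry HMM."""

import numpy as np
import pandas as pd
import pytest

import oracles
from asmqc.ancestry import (
    HmmParams,
    aim_select,
    baum_welch,
    biallelic_filter,
    forward_backward,
    laplace_freq,
    paint_and_summarize,
    viterbi,
)
from asmqc.synthetic import gen_ancestry_mosaic


def _aims_from_emissions(pC, pH, contig="c1", spacing=100):
    pC, pH = np.asarray(pC, dtype=float), np.asarray(pH, dtype=float)
    return pd.DataFrame(
        {"contig": contig, "pos": np.arange(len(pC)) * spacing, "p_C": pC, "p_H": pH}
    )


class TestBiallelicFilter:
    def _frame(self, **overrides):
        base = dict(ref_count_C=[15], depth_C=[30], ref_count_H=[25], depth_H=[30])
        base.update(overrides)
        return pd.DataFrame(base)

    def test_depth_exactly_twenty_dropped(self):
        assert not biallelic_filter(self._frame(depth_C=[20]))[0]

    def test_third_allele_dropped(self):
        assert not biallelic_filter(self._frame(other_count=[1]))[0]

    def test_boundary_depths_kept(self):
        assert biallelic_filter(self._frame(depth_C=[21], depth_H=[249]))[0]

    def test_monomorphic_site_dropped(self):
        # alternate allele never observed in either pool
        assert not biallelic_filter(self._frame(ref_count_C=[30], ref_count_H=[30]))[0]


class TestLaplace:
    @pytest.mark.parametrize("ref, depth, expected", [(0, 30, 1 / 32), (30, 30, 31 / 32)])
    def test_examples(self, ref, depth, expected):
        assert laplace_freq(ref, depth) == pytest.approx(expected)

    def test_output_strictly_inside_unit_interval(self):
        for depth in (1, 5, 100):
            for ref in (0, depth // 2, depth):
                f = laplace_freq(ref, depth)
                assert 0.0 < f < 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            laplace_freq(5, 4)


class TestAimSelect:
    def _frame(self, ref_C, ref_H, depth=30):
        return pd.DataFrame(
            {"contig": "c1", "pos": np.arange(len(ref_C)),
             "ref_count_C": ref_C, "depth_C": depth,
             "ref_count_H": ref_H, "depth_H": depth}
        )

    def test_strict_threshold(self):
        # Laplace freqs: (28+1)/32=0.90625, (18+1)/32=0.59375 -> diff 0.3125 kept
        # equal counts -> diff 0 dropped; crafted diff exactly 0.2 dropped
        df = self._frame([28, 15, 15], [18, 15, 15])
        df.loc[2, "ref_count_H"] = 15
        df.loc[2, "ref_count_C"] = 15
        out = aim_select(df, min_diff=0.2)
        assert list(out["pos"]) == [0]

    def test_exact_boundary_dropped(self):
        # depth 18: freqs (x+1)/20; counts 13 vs 9 give 0.70 - 0.50 = 0.20 exactly
        df = self._frame([13], [9], depth=18)
        assert len(aim_select(df, min_diff=0.2)) == 0


class TestForwardBackward:
    def test_single_aim_bayes(self):
        aims = _aims_from_emissions([0.9], [0.1])
        post, loglik, _ = forward_backward(aims, HmmParams(pi_C=0.5, tau=0.1))
        assert post[0] == pytest.approx(0.9)
        assert loglik == pytest.approx(np.log(0.5))

    def test_uninformative_emissions_return_prior(self):
        aims = _aims_from_emissions([0.4] * 50, [0.4] * 50)
        post, _, _ = forward_backward(aims, HmmParams(pi_C=0.5, tau=0.01))
        assert np.allclose(post, 0.5)

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(71)
        for L in (1, 2, 5, 10):
            e = rng.uniform(0.05, 0.95, size=(L, 2))
            aims = _aims_from_emissions(e[:, 0], e[:, 1])
            params = HmmParams(pi_C=0.6, tau=0.2)
            post, loglik, _ = forward_backward(aims, params)
            ref_post, ref_ll, ref_path = oracles.enumerate_hmm_posteriors(e, 0.6, 0.2)
            assert np.max(np.abs(post - ref_post)) < 1e-10
            assert loglik == pytest.approx(ref_ll, abs=1e-10)
            assert np.array_equal(viterbi(aims, params), ref_path)

    def test_agrees_with_independent_logspace_forward(self):
        rng = np.random.default_rng(73)
        L = 2000
        e = rng.uniform(0.05, 0.95, size=(L, 2))
        aims = _aims_from_emissions(e[:, 0], e[:, 1])
        _, loglik, _ = forward_backward(aims, HmmParams(pi_C=0.3, tau=0.01))
        # independent log-space forward recursion
        la = np.log([0.3 * e[0, 0], 0.7 * e[0, 1]])
        lT = np.log([[0.99, 0.01], [0.01, 0.99]])
        for t in range(1, L):
            la = np.logaddexp(la[0] + lT[0], la[1] + lT[1]) + np.log(e[t])
        ref = np.logaddexp(la[0], la[1])
        assert loglik == pytest.approx(ref, rel=1e-10)

    def test_posterior_normalization_and_range(self, standard_mosaic):
        aims, _ = standard_mosaic
        sel = aim_select(aims.assign(other_count=0), min_diff=0.2)
        post, _, _ = forward_backward(sel, HmmParams(pi_C=0.5, tau=1e-3))
        assert np.all((post >= 0) & (post <= 1))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            forward_backward(_aims_from_emissions([], []), HmmParams())


class TestBaumWelch:
    def test_recovers_switch_rate(self, standard_mosaic):
        aims, truth = standard_mosaic
        sel = aim_select(aims, min_diff=0.2)
        params, trace = baum_welch(sel, init=HmmParams(pi_C=0.5, tau=0.01))
        assert 1e-3 / 1.5 <= params.tau <= 1e-3 * 1.5
        assert np.all(np.diff(trace) >= -1e-6)

    def test_switchless_data_drives_tau_to_clamp(self):
        rng = np.random.default_rng(79)
        L = 500
        pC = rng.uniform(0.8, 0.95, L)
        pH = 1.0 - pC
        aims = _aims_from_emissions(pC, pH)
        with pytest.warns(RuntimeWarning):
            params, _ = baum_welch(aims, init=HmmParams(pi_C=0.5, tau=1e-3), tol=0.0,
                                   max_iter=100)
        assert params.tau <= 1e-7


class TestPainting:
    def test_pure_ancestry_gives_alpha_one_single_segment(self):
        rng = np.random.default_rng(83)
        pC = rng.uniform(0.85, 0.95, 200)
        aims = _aims_from_emissions(pC, 1.0 - pC)
        res = paint_and_summarize(aims, HmmParams(pi_C=0.5, tau=1e-3))
        assert res.alpha_per_contig["c1"] > 0.99
        assert len(res.segments) == 1 and res.segments["state"].iloc[0] == "C"

    def test_alpha_and_viterbi_recover_simulated_mosaic(self, standard_mosaic):
        aims, truth = standard_mosaic
        sel = aim_select(aims, min_diff=0.2)
        params, _ = baum_welch(sel, init=HmmParams(pi_C=0.5, tau=0.01))
        res = paint_and_summarize(sel, params)
        truth_path = np.array([1 if s == "C" else 0 for s in truth.ancestry_path])
        kept_idx = sel.index  # aim_select preserved row order; map via positions
        pos_to_idx = {p: i for i, p in enumerate(aims["pos"])}
        truth_kept = truth_path[[pos_to_idx[p] for p in sel["pos"]]]
        alpha_hat = res.alpha_per_contig["contig_1"]
        assert abs(alpha_hat - np.mean(truth_kept)) <= 0.02
        accuracy = np.mean(res.viterbi_paths["contig_1"] == truth_kept)
        assert accuracy >= 0.95

    def test_swapping_source_pools_flips_alpha_and_segments(self):
        rng = np.random.default_rng(89)
        pC = rng.uniform(0.05, 0.95, 300)
        pH = np.clip(pC + rng.choice([-0.4, 0.4], 300), 0.02, 0.98)
        aims = _aims_from_emissions(pC, pH)
        swapped = aims.rename(columns={"p_C": "p_H", "p_H": "p_C"})
        params = HmmParams(pi_C=0.5, tau=5e-3)
        res = paint_and_summarize(aims, params)
        res_sw = paint_and_summarize(swapped, params)
        assert res.alpha_per_contig["c1"] + res_sw.alpha_per_contig["c1"] == pytest.approx(1.0)
        states = res.segments["state"].tolist()
        states_sw = res_sw.segments["state"].tolist()
        assert states_sw == ["H" if s == "C" else "C" for s in states]
        assert res.segments[["start", "end"]].equals(res_sw.segments[["start", "end"]])

    def test_confidence_improves_with_depth_and_divergence(self):
        def mean_confidence(divergence, depth, seed=97):
            aims, _ = gen_ancestry_mosaic(
                n_aims=3000, switch_prob=1e-3, alpha_target=0.6,
                freq_divergence=divergence, depth=depth, seed=seed,
            )
            sel = aim_select(aims, min_diff=0.2)
            post, _, _ = forward_backward(sel, HmmParams(pi_C=0.5, tau=1e-3))
            return np.mean(np.maximum(post, 1 - post))

        low = mean_confidence(0.3, 20)
        high = mean_confidence(0.6, 80)
        assert high > low
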