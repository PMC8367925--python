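import numpy as np
import pytest
from dataclasses import replace

from predlex import iam_simulator as iam
from predlex.lexicon import PhonemeInventory

from conftest import make_lexicon


FAST = iam.IAMParameters(n_cycles=60)


class TestParameters:
    def test_defaults_valid(self):
        iam.IAMParameters()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"excite_phoneme_word": -0.1},
            {"decay_word": 1.5},
            {"rest_phoneme": 0.1},
            {"rest_word": -0.5},
            {"slices_per_phoneme": 0},
            {"n_cycles": 0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            iam.IAMParameters(**kwargs)


class TestBuildNetwork:
    def test_unit_count_single_word(self):
        # word "ab" with spread 0: extent 2s slices, one unit per alignment
        s = 4
        params = replace(FAST, slices_per_phoneme=s, input_spread=0)
        lex = make_lexicon({"ab": 1.0})
        net = iam.build_network(lex, params, n_slices=4 * s)
        assert net.n_word_units == 4 * s - 2 * s + 1

    def test_unit_count_scales_linearly_with_lexicon(self):
        params = replace(FAST, input_spread=0, slices_per_phoneme=3)
        lex1 = make_lexicon({"ab": 1.0})
        lex3 = make_lexicon({"ab": 1.0, "cd": 1.0, "ad": 1.0})
        n1 = iam.build_network(lex1, params, 30).n_word_units
        n3 = iam.build_network(lex3, params, 30).n_word_units
        assert n3 == 3 * n1

    def test_constituency_agrees_with_recomputation(self):
        params = FAST
        lex = make_lexicon({"abc": 1.0, "ba": 2.0})
        net = iam.build_network(lex, params, 40)
        spp, spread = params.slices_per_phoneme, params.input_spread
        C = net.constituency.tocoo()
        cells = {}
        for u, flat in zip(C.row, C.col):
            cells.setdefault(u, set()).add((flat // net.n_slices, flat % net.n_slices))
        for u in range(net.n_word_units):
            form = net.forms[net.word_index[u]]
            a = int(net.starts[u])
            expected = {
                (net.inventory.index(p), a + i * spp + spread)
                for i, p in enumerate(form)
            }
            assert cells[u] == expected
            assert net.n_constituents[u] == len(form)

    def test_word_unit_lookup(self):
        lex = make_lexicon({"ab": 1.0})
        net = iam.build_network(lex, FAST, 30)
        u = net.word_unit(tuple("ab"), 2)
        assert net.starts[u] == 2
        with pytest.raises(KeyError):
            net.word_unit(tuple("ab"), 999)


class TestEncodeInput:
    def test_single_phoneme_spread_zero(self):
        inv = PhonemeInventory(("a", "b"))
        params = replace(FAST, input_spread=0, slices_per_phoneme=3)
        inp = iam.encode_input(("a",), params, inv, 10)
        assert inp.drive[0, 0] == 1.0
        assert inp.drive.sum() == 1.0

    def test_shared_prefix_identical_drive_over_prefix_slices(self):
        inv = PhonemeInventory(tuple("abcdef"))
        params = FAST
        a = iam.encode_input(tuple("abcde"), params, inv, 60)
        b = iam.encode_input(tuple("abcdf"), params, inv, 60)
        # drive identical up to the onset slice of position 5
        onset = 4 * params.slices_per_phoneme
        assert np.array_equal(a.drive[:, :onset], b.drive[:, :onset])

    def test_equal_drive_mass_per_phoneme(self):
        inv = PhonemeInventory(tuple("abcd"))
        inp = iam.encode_input(tuple("abcd"), FAST, inv, 60)
        masses = inp.drive.sum(axis=1)
        assert np.allclose(masses, masses[0])

    def test_drive_unfolds_one_slice_per_cycle(self):
        inv = PhonemeInventory(tuple("ab"))
        inp = iam.encode_input(tuple("ab"), FAST, inv, 30)
        assert inp.drive_at(0).sum() <= inp.drive_at(10).sum()
        assert np.array_equal(inp.drive_at(10**6), inp.drive)

    def test_too_few_slices_rejected(self):
        inv = PhonemeInventory(tuple("ab"))
        with pytest.raises(ValueError, match="n_slices"):
            iam.encode_input(tuple("ab"), FAST, inv, 5)


class TestStep:
    def test_rest_state_is_fixed_point_under_zero_drive(self):
        lex = make_lexicon({"ab": 1.0, "cd": 1.0})
        net = iam.build_network(lex, FAST, 30)
        state = iam.NetworkState(
            np.full((net.n_phonemes, net.n_slices), FAST.rest_phoneme),
            np.full(net.n_word_units, FAST.rest_word),
        )
        new, fb = iam.step(state, np.zeros_like(state.phoneme_act), net, FAST)
        assert np.array_equal(new.phoneme_act, state.phoneme_act)
        assert np.array_equal(new.word_act, state.word_act)
        assert fb == 0.0

    def test_two_unit_step_matches_hand_computation(self):
        # one word "a" over a 1-symbol inventory, spread 0, one slice:
        # exactly one phoneme unit and one word unit
        params = iam.IAMParameters(
            slices_per_phoneme=1, input_spread=0, n_cycles=5
        )
        lex = make_lexicon({"a": 1.0})
        net = iam.build_network(lex, params, n_slices=1)
        assert net.n_word_units == 1 and net.n_phonemes == 1
        p0, w0 = 0.2, 0.1
        state = iam.NetworkState(np.array([[p0]]), np.array([w0]))
        drive = np.ones((1, 1))
        new, fb = iam.step(state, drive, net, params)
        # phoneme: net = eip*1 + fwp*w0 (no other units to inhibit)
        net_p = params.excite_input_phoneme + params.feedback_word_phoneme * w0
        dp = net_p * (params.act_max - p0) - params.decay_phoneme * (
            p0 - params.rest_phoneme
        )
        # word: net = epw*p0, no competitors
        net_w = params.excite_phoneme_word * p0
        dw = net_w * (params.act_max - w0) - params.decay_word * (
            w0 - params.rest_word
        )
        assert new.phoneme_act[0, 0] == pytest.approx(p0 + dp)
        assert new.word_act[0] == pytest.approx(w0 + dw)
        assert fb == pytest.approx(params.feedback_word_phoneme * w0)

    def test_only_positive_activations_transmit(self):
        # a negative word activation must contribute no feedback
        params = iam.IAMParameters(slices_per_phoneme=1, input_spread=0)
        lex = make_lexicon({"a": 1.0})
        net = iam.build_network(lex, params, n_slices=1)
        state = iam.NetworkState(np.array([[0.5]]), np.array([-0.2]))
        _, fb = iam.step(state, np.zeros((1, 1)), net, params)
        assert fb == 0.0


class TestRun:
    def test_deterministic(self, tiny_lexicon):
        a = iam.run(tuple("mud"), tiny_lexicon, FAST)
        b = iam.run(tuple("mud"), tiny_lexicon, FAST)
        assert np.array_equal(a.phoneme_act, b.phoneme_act)
        assert np.array_equal(a.word_act, b.word_act)
        assert np.array_equal(a.total_feedback, b.total_feedback)

    def test_totals_are_exact_sums_of_recorded_activations(self, tiny_lexicon):
        tr = iam.run(tuple("mud"), tiny_lexicon, FAST)
        assert np.allclose(tr.total_word_act, tr.word_act.sum(axis=1))
        assert np.allclose(tr.total_phoneme_act, tr.phoneme_act.sum(axis=(1, 2)))

    def test_activations_stay_in_bounds(self, tiny_lexicon):
        tr = iam.run(tuple("mushroom"), tiny_lexicon, FAST)
        assert tr.phoneme_act.min() >= FAST.act_min - 1e-12
        assert tr.phoneme_act.max() <= FAST.act_max + 1e-12
        assert tr.word_act.min() >= FAST.act_min - 1e-12
        assert tr.word_act.max() <= FAST.act_max + 1e-12

    def test_total_feedback_nonnegative_and_zero_when_ablated(self, tiny_lexicon):
        tr = iam.run(tuple("mud"), tiny_lexicon, FAST)
        assert (tr.total_feedback >= 0).all()
        ablated = replace(FAST, feedback_word_phoneme=0.0)
        tr0 = iam.run(tuple("mud"), tiny_lexicon, ablated)
        assert np.array_equal(tr0.total_feedback, np.zeros(ablated.n_cycles))

    def test_matching_word_rises_then_plateaus(self):
        lex = make_lexicon({"abab": 1.0}, symbols="ab")
        params = iam.IAMParameters(n_cycles=100)
        net = iam.build_network(lex, params, iam.default_n_slices(4, lex, params))
        tr = iam.simulate(net, tuple("abab"), params)
        u = net.word_unit(tuple("abab"), 0)
        tc = tr.word_act[:, u]
        assert tc[-1] > params.rest_word
        rise = tc[10:40]
        assert np.all(np.diff(rise) > -1e-6)  # monotone rise during input
        assert abs(tc[-1] - tc[-10]) < 0.01  # plateau at the end

    def test_frequency_scaling_leaves_dynamics_unchanged(self, tiny_lexicon):
        scaled = make_lexicon(
            {"".join(e.form): e.frequency * 10 for e in tiny_lexicon}
        )
        a = iam.run(tuple("mud"), tiny_lexicon, FAST)
        b = iam.run(tuple("mud"), scaled, FAST)
        assert np.array_equal(a.word_act, b.word_act)


class TestPhonemeTimecourse:
    def test_returns_n_cycles_vector_and_rises_for_presented_phoneme(
        self, tiny_lexicon
    ):
        tr = iam.run(tuple("mud"), tiny_lexicon, FAST)
        tc = iam.phoneme_timecourse(tr, "u", 2, tuple("mud"), FAST)
        assert tc.shape == (FAST.n_cycles,)
        assert tc.max() > FAST.rest_phoneme

    def test_position_out_of_range_rejected(self, tiny_lexicon):
        tr = iam.run(tuple("mud"), tiny_lexicon, FAST)
        with pytest.raises(ValueError):
            iam.phoneme_timecourse(tr, "m", 9, tuple("mud"), FAST)

    def test_unknown_symbol_rejected(self, tiny_lexicon):
        tr = iam.run(tuple("mud"), tiny_lexicon, FAST)
        with pytest.raises(KeyError):
            iam.phoneme_timecourse(tr, "Q", 1, tuple("mud"), FAST)


class TestAnticipation:
    def test_no_anticipation_without_feedback(self, default_lexicon, default_triples):
        t = default_triples[0]
        params = replace(iam.IAMParameters(), feedback_word_phoneme=0.0)
        tr = iam.run(t.source, default_lexicon, params)
        onset = iam.input_onset_cycle(t.dp + 1, params)
        tc = iam.phoneme_timecourse(tr, t.source[t.dp], t.dp + 1, t.source, params)
        assert np.allclose(tc[:onset], params.rest_phoneme)

    def test_predicted_phoneme_exceeds_replacements_before_dp(
        self, default_lexicon, default_triples
    ):
        params = iam.IAMParameters()
        # mean over items: lexically supported post-DP phoneme is
        # anticipated, replacements are not
        diffs = []
        for t in default_triples:
            onset = iam.input_onset_cycle(t.dp + 1, params)
            win = slice(max(0, onset - 15), onset)
            tr = iam.run(t.source, default_lexicon, params)
            src = iam.phoneme_timecourse(tr, t.source[t.dp], t.dp + 1, t.source, params)
            nov = iam.phoneme_timecourse(tr, t.novel[t.dp], t.dp + 1, t.source, params)
            bas = iam.phoneme_timecourse(
                tr, t.baseline[t.dp], t.dp + 1, t.source, params
            )
            diffs.append(src[win].mean() - 0.5 * (nov[win].mean() + bas[win].mean()))
        assert np.mean(diffs) > 0
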