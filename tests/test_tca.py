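"""PSTH construction, non-negative CP decomposition and trial TC scores."""

import numpy as np
import pandas as pd
import pytest

from gonogo import tca


def _spike_row(neuron, trial, condition, times, mouse="m0", session=0, zone="6+"):
    return {
        "neuron": neuron,
        "mouse": mouse,
        "session": session,
        "zone": zone,
        "trial": trial,
        "condition": condition,
        "spike_times": np.asarray(times, dtype=float),
    }


def test_psth_single_spike_rate():
    """One spike at 0.10 s in one trial: its 50-ms bin reads 20 Hz."""
    spikes = pd.DataFrame([_spike_row("n0", 0, "HIT", [0.10])])
    t = tca.build_psth(spikes)
    assert t.values.shape == (1, 50, 4)
    k = t.conditions.index("HIT")
    b = np.searchsorted(t.bin_edges, 0.10, side="right") - 1
    assert t.values[0, b, k] == pytest.approx(20.0)
    other = np.delete(t.values[0, :, k], b)
    assert np.all(other == 0.0)
    assert t.empty_mask[0, t.conditions.index("FA")]


def test_psth_stationary_poisson_is_near_zero(rng):
    """Homogeneous Poisson spikes: baseline subtraction cancels the rate."""
    rows = []
    for trial in range(200):
        times = rng.uniform(-2, 2, rng.poisson(4 * 5.0))
        rows.append(_spike_row("n0", trial, "HIT", np.sort(times)))
    t = tca.build_psth(pd.DataFrame(rows))
    k = t.conditions.index("HIT")
    assert np.abs(t.values[0, :, k]).max() < 2.5  # sampling error only, ~5 Hz base
    assert abs(t.values[0, :, k].mean()) < 0.3


def test_psth_rejects_empty():
    with pytest.raises(ValueError):
        tca.build_psth(pd.DataFrame(columns=["neuron", "condition", "spike_times"]))


def _random_cp(rng, shape=(30, 50, 4), rank=1):
    factors = [np.abs(rng.random((s, rank))) + 0.05 for s in shape]
    x = np.einsum("nr,tr,kr->ntk", *factors)
    return x, factors


def test_ntf_rank1_exact_recovery(rng):
    x, _ = _random_cp(rng, rank=1)
    f = tca.ntf_decompose(x, rank=1, n_restarts=3, seed=1)
    assert f.fit >= 0.99
    xhat = f.reconstruct()
    assert np.linalg.norm(x - xhat) / np.linalg.norm(x) < 0.01


def test_ntf_constraints(rng):
    x, _ = _random_cp(rng, rank=3)
    x += 0.01 * rng.random(x.shape)
    f = tca.ntf_decompose(x, rank=3, n_restarts=3, seed=2)
    for mat in (f.neuron, f.time, f.condition):
        assert np.all(mat >= 0)
        np.testing.assert_allclose(np.linalg.norm(mat, axis=0), 1.0, atol=1e-8)
    assert np.all(np.diff(f.lam) <= 1e-9)  # sorted descending


def test_ntf_fit_nondecreasing_in_rank(rng):
    x, _ = _random_cp(rng, rank=3)
    x += 0.05 * rng.random(x.shape)
    fits = [tca.ntf_decompose(x, rank=r, n_restarts=3, seed=3).fit for r in (1, 2, 3, 4)]
    assert all(b >= a - 1e-6 for a, b in zip(fits[:-1], fits[1:]))


def test_ntf_clips_negative_entries(rng):
    x, _ = _random_cp(rng, rank=2)
    x[0, 0, 0] = -1.0
    with pytest.warns(UserWarning, match="clipping"):
        tca.ntf_decompose(x, rank=2, n_restarts=2, seed=0)


def test_ntf_rejects_zero_tensor():
    with pytest.raises(ValueError):
        tca.ntf_decompose(np.zeros((5, 5, 4)), rank=2)


def _toy_factors():
    edges = np.arange(-0.5, 2.0 + 0.025, 0.05)
    time = np.zeros((50, 2))
    time[12, 0] = 0.5  # bin containing t = 0.10..0.15
    time[:, 0] /= np.linalg.norm(time[:, 0])
    time[5, 1] = 1.0
    neuron = np.array([[2.0, 0.1], [1.0, 0.3]])
    cond = np.array([[0.3, 0.5], [0.1, 0.2], [0.0, 0.1], [0.0, 0.0]])
    return tca.TCAFactors(
        lam=np.ones(2), neuron=neuron, time=time, condition=cond,
        neurons=np.array(["n0", "n1"]), bin_edges=edges,
    )


def test_trial_activity_direct_evaluation():
    f = _toy_factors()
    # one spike in the bin where b = 1 (pre-normalization 0.5 -> after unit
    # norm it's exactly 1.0 because it's the only entry), w=2, a=0.3
    y = tca.trial_tc_activity(np.array([0.12]), f, neuron_index=0, condition="HIT", component=0)
    assert y == pytest.approx(2.0 * 0.3 * 1.0)
    assert tca.trial_tc_activity(np.array([]), f, 0, "HIT", 0) == 0.0
    # doubling w doubles y; spike order irrelevant
    y2 = tca.trial_tc_activity(np.array([0.14, 0.12]), f, 0, "HIT", 0)
    y2_perm = tca.trial_tc_activity(np.array([0.12, 0.14]), f, 0, "HIT", 0)
    assert y2 == pytest.approx(2 * y) and y2_perm == y2
    # spikes outside [-0.5, 2] are ignored
    assert tca.trial_tc_activity(np.array([2.5, -1.0]), f, 0, "HIT", 0) == 0.0
    with pytest.raises(IndexError):
        tca.trial_tc_activity(np.array([0.12]), f, 0, "HIT", 5)


def test_session_scores_are_neuron_means():
    f = _toy_factors()
    spikes = pd.DataFrame(
        [
            _spike_row("n0", 0, "HIT", [0.12]),
            _spike_row("n1", 0, "HIT", []),
        ]
    )
    scores = tca.session_tc_scores(spikes, f)
    # neuron means: (0.6 + 0) / 2
    assert scores.loc[0, "tc1"] == pytest.approx(0.3)
    single = tca.session_tc_scores(spikes.iloc[:1], f)
    assert single.loc[0, "tc1"] == pytest.approx(0.6)


def test_planted_component_separates_conditions(small_spikes):
    """With a HIT-selective planted component, HIT-trial scores exceed
    CR-trial scores (trial-resolved analogue of the condition loadings)."""
    spikes, factors, _, _ = small_spikes
    scores = tca.session_tc_scores(spikes, factors)
    hit = scores[scores["condition"] == "HIT"]["tc1"].mean()
    cr = scores[scores["condition"] == "CR"]["tc1"].mean()
    assert hit > cr


def test_scoring_invariant_to_neuron_relabeling(small_spikes):
    spikes, factors, _, _ = small_spikes
    scores = tca.session_tc_scores(spikes, factors)
    relabeled = spikes.copy()
    mapping = {n: f"z{hash(n) % 10**6}_{n}" for n in spikes["neuron"].unique()}
    relabeled["neuron"] = relabeled["neuron"].map(mapping)
    f2 = tca.TCAFactors(
        lam=factors.lam, neuron=factors.neuron, time=factors.time,
        condition=factors.condition, bin_edges=factors.bin_edges,
        neurons=np.array([mapping[n] for n in factors.neurons]),
    )
    # scores must be identical: only the labels changed
    s2 = tca.session_tc_scores(relabeled, f2)
    np.testing.assert_allclose(scores[["tc1", "tc2", "tc3", "tc4"]],
                               s2[["tc1", "tc2", "tc3", "tc4"]])


def test_synchronized_spikes_identical_trains_survive():
    times = np.array([0.1, 0.5, 1.0])
    spikes = pd.DataFrame(
        [_spike_row("a", 0, "HIT", times), _spike_row("b", 0, "HIT", times)]
    )
    out = tca.synchronized_spikes(spikes)
    for t in out["spike_times"]:
        np.testing.assert_array_equal(t, times)


def test_synchronized_spikes_threshold_unsatisfiable():
    spikes = pd.DataFrame(
        [_spike_row("a", 0, "HIT", [0.1]), _spike_row("b", 0, "HIT", [0.9])]
    )
    out = tca.synchronized_spikes(spikes, min_coactive=3)
    assert all(len(t) == 0 for t in out["spike_times"])


def test_synchronized_spikes_poisson_coincidence_rate(rng):
    """Independent 1-Hz Poisson pairs: retained fraction ~ the coincidence
    probability per 30-ms bin, 1 - exp(-rate * bin) ~ 0.0296."""
    rate, dur, bin_w, n_pairs = 1.0, 100.0, 0.03, 60
    rows, kept, total = [], 0, 0
    for i in range(n_pairs):
        a = np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
        b = np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
        df = pd.DataFrame([
            _spike_row("a", 0, "HIT", a, session=i),
            _spike_row("b", 0, "HIT", b, session=i),
        ])
        out = tca.synchronized_spikes(df, bin_width=bin_w)
        kept += sum(len(t) for t in out["spike_times"])
        total += len(a) + len(b)
    frac = kept / total
    expected = 1.0 - np.exp(-rate * bin_w)
    assert frac == pytest.approx(expected, rel=0.35)
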