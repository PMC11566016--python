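"""Synthetic-subject generator: latent structure, planted effects, BOLD
rendering, hypnograms."""

import numpy as np
import pytest
from scipy import stats

from conftest import subject_scores
from remdiff import design as dm
from remdiff import sleepmet, synthgen
from remdiff.synthgen import DEFAULT_EFFECTS, EffectConfig


def _noise_free(group="Wake", **kw):
    return EffectConfig(group, noise_sd=1e-9, **kw)


def test_latent_blocks_exactly_orthogonal(rem_subject):
    lat = rem_subject.ground_truth.latents["ca23dg"]
    for i in range(len(lat.shared)):
        assert abs(lat.shared[i] @ lat.a_unique[i]) < 1e-8
        assert abs(lat.shared[i] @ lat.b_unique[i]) < 1e-8
        assert abs(lat.shared[i] @ lat.novel[i]) < 1e-8
        assert abs(lat.a_unique[i] @ lat.b_unique[i]) < 1e-8
        assert abs(lat.b_unique[i] @ lat.novel[i]) < 1e-8


def test_no_planted_effect_gives_zero_diff_score(small_design):
    sub = synthgen.simulate_subject(small_design, _noise_free(), n_vox=120, seed=4)
    diff = subject_scores(sub)["diff"]
    assert abs(diff.diff_score) < 1e-6


def test_full_differentiation_separates_conditions(small_design):
    """delta_diff = 1: every violation pair's z falls below every nonviolation z."""
    eff = _noise_free("REM", delta_diff=1.0, pred_sd=0.0)
    sub = synthgen.simulate_subject(small_design, eff, n_vox=120, seed=5)
    records = subject_scores(sub)["records"]
    viol = [r.z for r in records if r.condition == "violation"]
    nonv = [r.z for r in records if r.condition == "nonviolation"]
    assert max(viol) < min(nonv)


def test_diff_score_strictly_monotone_in_delta_diff(small_design):
    scores = []
    for dd in (0.0, 0.3, 0.6, 0.9):
        eff = _noise_free("REM", delta_diff=dd, pred_sd=0.0)
        sub = synthgen.simulate_subject(small_design, eff, n_vox=120, seed=6)
        scores.append(subject_scores(sub)["diff"].diff_score)
    assert all(b < a for a, b in zip(scores, scores[1:]))


def test_ground_truth_records_pi_and_d(rem_subject):
    gt = rem_subject.ground_truth
    eff = gt.effect
    assert set(gt.pi) == {p.pair_id for p in rem_subject.design.pairs if p.condition == "violation"}
    for pid, pi in gt.pi.items():
        assert 0.0 <= pi <= 1.0
        expected = np.clip(eff.delta_diff + eff.kappa * (pi - eff.pred_mean), 0.0, 1.0)
        assert gt.d[pid] == pytest.approx(float(expected))


def test_one_pattern_per_event(rem_subject):
    assert rem_subject.patterns["ca23dg"].shape == (
        len(rem_subject.design.events),
        rem_subject.n_vox,
    )


def test_subject_determinism(small_design):
    a = synthgen.simulate_subject(small_design, DEFAULT_EFFECTS["REM"], n_vox=90, seed=42)
    b = synthgen.simulate_subject(small_design, DEFAULT_EFFECTS["REM"], n_vox=90, seed=42)
    assert np.array_equal(a.patterns["ca23dg"], b.patterns["ca23dg"])
    assert a.ground_truth.pi == b.ground_truth.pi


def test_effect_config_validation():
    with pytest.raises(ValueError):
        EffectConfig("Wake", noise_sd=0.0)
    with pytest.raises(ValueError):
        EffectConfig("Wake", delta_diff=float("nan"))


def test_cohort_counts_labels_and_errors():
    subs = synthgen.simulate_cohort(
        2, seed=1, n_vox=70, n_runs=1, pairs_per_run=4
    )
    assert len(subs) == 6
    assert [s.group for s in subs] == ["Wake"] * 2 + ["NREM"] * 2 + ["REM"] * 2
    assert len({s.seed for s in subs}) == 6
    with pytest.raises(ValueError, match="duplicate"):
        synthgen.simulate_cohort(2, effects=[EffectConfig("A"), EffectConfig("A")], seed=1)
    with pytest.raises(ValueError):
        synthgen.simulate_cohort(0, seed=1)


# ---------------------------------------------------------------------------
# BOLD rendering


def test_render_isolated_trial_recovers_pattern(small_design):
    """Zero noise, wide spacing: raw extraction at onset+4.5 s is the pattern
    scaled by the HRF value, so correlation with ground truth is ~1."""
    from remdiff.snapshots import extract_pattern

    des = dm.respace_run(small_design, 3, 60.0)  # post-B run, temporally isolated
    sub = synthgen.simulate_subject(des, _noise_free(), n_vox=80, seed=9)
    bold, ev = synthgen.render_bold(sub, "ca23dg", run=3)
    mask = np.ones(bold.shape[:-1], bool)
    rows = [i for i, e in enumerate(sub.design.events) if e.run == 3]
    for (_, row), i in zip(ev.iterrows(), rows):
        pv = extract_pattern(bold, mask, row.onset, 1.5, time_offset=0.0)
        r = np.corrcoef(pv.values, sub.patterns["ca23dg"][i])[0, 1]
        assert r > 0.99


def test_render_overlap_matches_direct_convolution(small_design):
    """Two trials 3 s apart: the sampled volume is exactly the HRF-weighted
    sum of both patterns (closed-form overlap oracle)."""
    sub = synthgen.simulate_subject(small_design, _noise_free(), n_vox=70, seed=10)
    run = 1
    bold, ev = synthgen.render_bold(sub, "ca23dg", run=run)
    rows = [i for i, e in enumerate(sub.design.events) if e.run == run]
    pats = sub.patterns["ca23dg"][rows]
    onsets = ev["onset"].to_numpy()
    tr = 1.5
    target = onsets[0] + 4.5
    vol = int(round(target / tr))
    lags = vol * tr - onsets
    expected = synthgen.double_gamma_hrf(lags) @ pats
    np.testing.assert_allclose(bold[:, 0, 0, vol], expected, atol=1e-7)


def test_render_zero_patterns_yield_zero_volumes(small_design):
    sub = synthgen.simulate_subject(small_design, _noise_free(), n_vox=70, seed=13)
    sub.patterns["ca23dg"][:] = 0.0
    bold, _ = synthgen.render_bold(sub, "ca23dg", run=1)
    assert np.abs(bold).max() < 1e-12


def test_render_includes_lead_in_and_tail(small_design):
    sub = synthgen.simulate_subject(small_design, _noise_free(), n_vox=70, seed=14)
    bold, ev = synthgen.render_bold(sub, "ca23dg", run=1, lead_in=9, tail=5)
    assert ev["onset"].min() == pytest.approx(9 * 1.5)
    # lead-in volumes precede any stimulus: all zero at zero noise
    assert np.abs(bold[..., :9]).max() < 1e-12


def test_hrf_shape():
    t = np.linspace(0, 30, 601)
    h = synthgen.double_gamma_hrf(t)
    assert h.max() == pytest.approx(1.0, abs=1e-3)
    assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.5)  # gamma(6) peaks at 5 s
    assert h[t > 12].min() < 0  # undershoot
    assert synthgen.double_gamma_hrf(np.array([-1.0]))[0] == 0.0


# ---------------------------------------------------------------------------
# hypnograms


def test_hypnogram_targets_reproduced_exactly():
    targets = {"N1": 6.0, "N2": 22.0, "N3": 20.0, "REM": 0.0, "WASO": 8.0}
    h, _ = synthgen.simulate_hypnogram("NREM", targets, seed=3, tib_min=65.0)
    arch = sleepmet.score_architecture(h)
    assert arch.tib_min == 65.0
    assert arch.tst_min == 48.0
    assert arch.waso_min == 8.0
    assert arch.minutes == {"N1": 6.0, "N2": 22.0, "N3": 20.0, "REM": 0.0, "NREM": 48.0}


def test_nrem_group_cannot_request_rem():
    with pytest.raises(ValueError, match="REM"):
        synthgen.simulate_hypnogram("NREM", {"N1": 2, "N2": 10, "N3": 5, "REM": 1}, seed=0)
    h, _ = synthgen.simulate_hypnogram("NREM", seed=0)
    assert "REM" not in h.epoch_stages


def test_rem_group_classified_rem():
    h, _ = synthgen.simulate_hypnogram("REM", seed=5)
    assert sleepmet.classify_nap(h).label == "REM"
    assert sleepmet.score_architecture(h).minutes["REM"] == pytest.approx(16.5)


def test_spindle_rate_recovery():
    """4.3/min in 42 min of N2 -> ~181 events, within Poisson error."""
    h, events = synthgen.simulate_hypnogram(
        "REM", {"N1": 0, "N2": 42, "N3": 0, "REM": 1}, seed=21
    )
    n2 = [e for e in events if e.stage == "N2"]
    expected = 4.3 * 42
    assert abs(len(n2) - expected) < 4.5 * np.sqrt(expected)
    dens = sleepmet.spindle_density(events, h, "N2")
    assert dens == pytest.approx(len(n2) / 42.0)


def test_spindles_lie_within_their_stage_epochs():
    h, events = synthgen.simulate_hypnogram("REM", seed=2)
    for e in events:
        epoch = int(e.start // 30)
        assert h.epoch_stages[epoch] == e.stage
        assert e.start + e.duration <= (epoch + 1) * 30.0


def test_invalid_targets_rejected():
    with pytest.raises(ValueError, match="multiple"):
        synthgen.simulate_hypnogram("REM", {"N1": 0.3, "N2": 10, "N3": 0, "REM": 1}, seed=0)
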