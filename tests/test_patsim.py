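"""Pattern-similarity statistics against hand computations and brute-force
oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import (
    oracle_coupling,
    oracle_diff_score,
    oracle_prediction,
    random_instance,
    subject_scores,
)
from remdiff import patsim, synthgen
from remdiff.design import Item, Pair
from remdiff.patsim import SimilarityRecord
from remdiff.snapshots import SnapshotMatrix


# ---------------------------------------------------------------------------
# Fisher z


def test_fisher_z_values_and_inverse():
    assert patsim.fisher_z(0.0) == 0.0
    assert patsim.fisher_z(0.5) == pytest.approx(0.5 * math.log(1.5 / 0.5), abs=1e-12)
    assert patsim.fisher_z(-0.3) == -patsim.fisher_z(0.3)
    for r in (-0.9, -0.2, 0.0, 0.4, 0.99):
        assert patsim.inverse_fisher_z(patsim.fisher_z(r)) == pytest.approx(r, abs=1e-12)
    with pytest.raises(patsim.PatsimError):
        patsim.fisher_z(1.0)
    with pytest.raises(patsim.PatsimError):
        patsim.fisher_z(-1.5)


# ---------------------------------------------------------------------------
# pair similarity


def _two_pair_setup():
    pairs = [
        Pair("p0", Item("a0", "scene", "indoor"), Item("b0", "scene", "outdoor"),
             "nonviolation", 1),
        Pair("p1", Item("a1", "scene", "indoor"), Item("b1", "scene", "outdoor"),
             "nonviolation", 1),
    ]
    return pairs


def test_pair_similarity_toys():
    pairs = _two_pair_setup()
    pre = SnapshotMatrix("roi", "pre", ["a0", "a1"], [[1.0, 2.0, 3.0], [1.0, 0.0, 1.0]])
    post = SnapshotMatrix("roi", "post", ["b0", "b1"], [[3.0, 2.0, 1.0], [1.0, 2.0, 3.0]])
    recs = patsim.pair_similarity(pre, post, pairs)
    assert recs[0].r == pytest.approx(-1.0)  # (1,2,3) vs (3,2,1), hand computation
    assert np.isfinite(recs[0].z)  # clamp policy keeps degenerate toys runnable
    assert recs[1].r == pytest.approx(0.0, abs=1e-12)  # mean-centered orthogonal


def test_pair_similarity_identical_pattern_clamped():
    pairs = _two_pair_setup()[:1]
    pre = SnapshotMatrix("roi", "pre", ["a0"], [[1.0, 2.0, 3.0]])
    post = SnapshotMatrix("roi", "post", ["b0"], [[1.0, 2.0, 3.0]])
    recs = patsim.pair_similarity(pre, post, pairs)
    assert recs[0].r == pytest.approx(1.0)
    assert np.isfinite(recs[0].z) and recs[0].z > 13
    # exact |r| = 1 goes through the documented clamp
    with pytest.warns(RuntimeWarning, match="clamped"):
        z = patsim._safe_z(1.0)
    assert np.isfinite(z) and z > 13  # atanh(1 - 1e-12)


def test_pair_similarity_zero_variance_names_items():
    pairs = _two_pair_setup()[:1]
    pre = SnapshotMatrix("roi", "pre", ["a0"], [[2.0, 2.0, 2.0]])
    post = SnapshotMatrix("roi", "post", ["b0"], [[1.0, 2.0, 3.0]])
    with pytest.raises(patsim.PatsimError, match="a0"):
        patsim.pair_similarity(pre, post, pairs)


def test_similarity_affine_invariance():
    """Pearson similarity is unchanged by a*pattern + b on either side."""
    pairs, pre, post, _ = random_instance(3)
    base = patsim.pair_similarity(pre, post, pairs)
    scaled = SnapshotMatrix("roi", "post", post.item_ids, 3.7 * post.data - 11.0)
    again = patsim.pair_similarity(pre, scaled, pairs)
    for r1, r2 in zip(base, again):
        assert r1.r == pytest.approx(r2.r, abs=1e-12)


# ---------------------------------------------------------------------------
# differentiation score


def test_differentiation_score_hand_example():
    recs = [
        SimilarityRecord("p1", "violation", 0.0, 0.1),
        SimilarityRecord("p2", "violation", 0.0, 0.3),
        SimilarityRecord("p3", "nonviolation", 0.0, 0.4),
        SimilarityRecord("p4", "nonviolation", 0.0, 0.6),
    ]
    res = patsim.differentiation_score(recs)
    assert res.diff_score == pytest.approx(-0.3)
    assert patsim.differentiation_score(recs[::-1]).diff_score == pytest.approx(-0.3)


def test_differentiation_score_requires_both_conditions():
    recs = [SimilarityRecord("p1", "violation", 0.0, 0.1)]
    with pytest.raises(patsim.PatsimError, match="nonviolation"):
        patsim.differentiation_score(recs)


@pytest.mark.parametrize("seed", range(5))
def test_oracle_equivalence_small_instances(seed):
    """Pipeline scores equal one-line brute-force recomputation to 1e-12."""
    pairs, pre, post, evoked = random_instance(seed, n_pairs=6, n_vox=10)
    records = patsim.pair_similarity(pre, post, pairs)
    diff = patsim.differentiation_score(records)
    assert diff.diff_score == pytest.approx(oracle_diff_score(pre, post, pairs), abs=1e-12)

    pred = patsim.b_prediction_scores(pre, evoked, pairs)
    oracle_pred = oracle_prediction(pre, evoked, pairs)
    for s in pred:
        assert s.z_pred == pytest.approx(oracle_pred[s.pair_id], abs=1e-12)

    coup = patsim.coupling_correlation(pred, records, "violation")
    assert coup.r_within == pytest.approx(
        oracle_coupling(oracle_pred, pre, post, pairs), abs=1e-12
    )


# ---------------------------------------------------------------------------
# item specificity


def test_item_specificity_degenerate_null_raises():
    pairs, pre, post, _ = random_instance(0, n_pairs=4)
    post_same = SnapshotMatrix(
        "roi", "post", post.item_ids, np.tile(post.data[0], (len(post.item_ids), 1))
    )
    with pytest.raises(patsim.PatsimError):
        patsim.item_specificity_z(pre, post_same, pairs, n_shuffles=50, seed=0)


def test_item_specificity_needs_two_pairs_per_condition():
    pairs, pre, post, _ = random_instance(0, n_pairs=2)
    only_viol = [p for p in pairs if p.condition == "violation"]
    with pytest.raises(patsim.PatsimError):
        patsim.item_specificity_z(pre, post, only_viol, n_shuffles=10, seed=0)


def test_item_specificity_deterministic_per_seed():
    pairs, pre, post, _ = random_instance(1, n_pairs=6)
    a = patsim.item_specificity_z(pre, post, pairs, n_shuffles=200, seed=5)
    b = patsim.item_specificity_z(pre, post, pairs, n_shuffles=200, seed=5)
    assert a == b


def test_item_specificity_null_centered_under_exchangeability():
    """With exchangeable B patterns (no pairmate structure), z ~ 0 on average."""
    zs = []
    for seed in range(40):
        pairs, pre, post, _ = random_instance(100 + seed, n_pairs=12, n_vox=30)
        res = patsim.item_specificity_z(pre, post, pairs, n_shuffles=300, seed=seed)
        zs.append(res.z)
    assert abs(np.mean(zs)) < 0.45  # se ~ 1/sqrt(40)


def test_item_specificity_detects_planted_structure(rem_subject):
    res = subject_scores(rem_subject, n_shuffles=500, seed=3)["randomization"]
    assert res.z < 0
    assert res.null_sd > 0


# ---------------------------------------------------------------------------
# prediction & coupling


def test_prediction_rank_order_matches_reactivation(small_design):
    """Noise-free generator: z_pred orders pairs exactly by planted pi."""
    eff = synthgen.EffectConfig("REM", noise_sd=1e-9, pred_mean=0.5, pred_sd=0.25)
    sub = synthgen.simulate_subject(small_design, eff, n_vox=120, seed=17)
    scores = subject_scores(sub)
    gt_pi = sub.ground_truth.pi
    z = np.array([s.z_pred for s in scores["prediction"]])
    pi = np.array([gt_pi[s.pair_id] for s in scores["prediction"]])
    rho = stats.spearmanr(z, pi).statistic
    assert rho == pytest.approx(1.0)


def test_prediction_missing_evoked_raises():
    pairs, pre, _, evoked = random_instance(2)
    trimmed = SnapshotMatrix(
        "roi", "violation_evoked", evoked.item_ids[:-1], evoked.data[:-1]
    )
    with pytest.raises(patsim.PatsimError, match="missing evoked"):
        patsim.b_prediction_scores(pre, trimmed, pairs)


def test_coupling_error_modes():
    pairs, pre, post, evoked = random_instance(4)
    records = patsim.pair_similarity(pre, post, pairs)
    const = {p.pair_id: 1.0 for p in pairs if p.condition == "violation"}
    with pytest.raises(patsim.PatsimError, match="zero-variance"):
        patsim.coupling_correlation(const, records, "violation")
    with pytest.raises(patsim.PatsimError, match=">=3"):
        patsim.coupling_correlation({"p0": 1.0}, records, "violation")


def test_coupling_perfect_when_score_equals_similarity():
    pairs, pre, post, _ = random_instance(5)
    records = patsim.pair_similarity(pre, post, pairs)
    scores = {r.pair_id: r.z for r in records if r.condition == "violation"}
    res = patsim.coupling_correlation(scores, records, "violation")
    assert res.r_within == pytest.approx(1.0)
    assert np.isfinite(res.z_within)


def test_bxy_integration_orthogonal_and_identical():
    pairs, _, post, _ = random_instance(6)
    viol = [p for p in pairs if p.condition == "violation"]
    rng = np.random.default_rng(0)
    n_vox = 2000  # large so random patterns are nearly orthogonal
    b_ids = [p.b_item.item_id for p in viol]
    f_ids = [i.item_id for p in viol for i in (p.x_item, p.y_item)]
    post_b = SnapshotMatrix("roi", "post", b_ids, rng.standard_normal((len(b_ids), n_vox)))
    post_f = SnapshotMatrix("roi", "post", f_ids, rng.standard_normal((len(f_ids), n_vox)))
    scores = patsim.bxy_integration_scores(post_b, post_f, viol)
    assert max(abs(s.z_pred) for s in scores) < 0.1
    # identical post patterns -> maximal (clamped) score
    same = SnapshotMatrix("roi", "post", f_ids, np.tile(post_b.data[0], (len(f_ids), 1)))
    post_b1 = SnapshotMatrix("roi", "post", b_ids[:1], post_b.data[:1])
    s = patsim.bxy_integration_scores(post_b1, same, viol[:1])
    assert s[0].z_pred > 13
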