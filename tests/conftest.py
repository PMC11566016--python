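"""Shared fixtures and independent brute-force oracles.

The oracle functions recompute every pattern-similarity statistic from raw
pattern arrays with nothing but numpy one-liners, deliberately bypassing
the package's code paths, so tests can demand agreement to 1e-12.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from remdiff import design as design_mod
from remdiff import synthgen
from remdiff.snapshots import SnapshotMatrix


@pytest.fixture(scope="session")
def full_design():
    des = design_mod.generate_design(seed=1)
    return design_mod.generate_post_session(des, seed=2)


@pytest.fixture(scope="session")
def small_design():
    des = design_mod.generate_design(seed=7, n_runs=2, pairs_per_run=8)
    return design_mod.generate_post_session(des, seed=8)


@pytest.fixture(scope="session")
def rem_subject(small_design):
    return synthgen.simulate_subject(
        small_design, synthgen.DEFAULT_EFFECTS["REM"], n_vox=150, seed=11
    )


@pytest.fixture(scope="session")
def null_subject(small_design):
    return synthgen.simulate_subject(
        small_design, synthgen.EffectConfig("Wake"), n_vox=150, seed=12
    )


# ---------------------------------------------------------------------------
# oracles


def oracle_pearson(x, y):
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float(x @ y / math.sqrt((x @ x) * (y @ y)))


def oracle_diff_score(pre_a, post_b, pairs):
    """Differentiation score recomputed from raw patterns in one pass."""
    zs = {"violation": [], "nonviolation": []}
    for p in pairs:
        r = oracle_pearson(pre_a.get(p.a_item.item_id), post_b.get(p.b_item.item_id))
        zs[p.condition].append(math.atanh(r))
    return float(np.mean(zs["violation"]) - np.mean(zs["nonviolation"]))


def oracle_prediction(pre_b, evoked, pairs):
    out = {}
    for p in pairs:
        if p.condition != "violation":
            continue
        b = pre_b.get(p.b_item.item_id)
        out[p.pair_id] = 0.5 * (
            math.atanh(oracle_pearson(b, evoked.get(p.x_item.item_id)))
            + math.atanh(oracle_pearson(b, evoked.get(p.y_item.item_id)))
        )
    return out


def oracle_coupling(scores: dict, pre_a, post_b, pairs):
    xs, ys = [], []
    for p in pairs:
        if p.pair_id not in scores:
            continue
        xs.append(scores[p.pair_id])
        r = oracle_pearson(pre_a.get(p.a_item.item_id), post_b.get(p.b_item.item_id))
        ys.append(math.atanh(r))
    return oracle_pearson(xs, ys)


def random_instance(seed, n_pairs=6, n_vox=10):
    """A tiny random subject-like instance for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    pairs = []
    pre_a_rows, post_b_rows, pre_b_rows, ev_rows = [], [], [], []
    pre_ids, post_ids, ev_ids = [], [], []
    for i in range(n_pairs):
        cond = "violation" if i % 2 == 0 else "nonviolation"
        a = design_mod.Item(f"a{i}", "scene", "indoor")
        b = design_mod.Item(f"b{i}", "scene", "outdoor")
        x = design_mod.Item(f"x{i}", "face", "male") if cond == "violation" else None
        y = design_mod.Item(f"y{i}", "face", "female") if cond == "violation" else None
        pairs.append(design_mod.Pair(f"p{i}", a, b, cond, run=1, x_item=x, y_item=y))
        pre_ids += [a.item_id, b.item_id]
        pre_a_rows.append(rng.standard_normal(n_vox))
        pre_b_rows.append(rng.standard_normal(n_vox))
        post_ids.append(b.item_id)
        post_b_rows.append(rng.standard_normal(n_vox))
        if cond == "violation":
            ev_ids += [x.item_id, y.item_id]
            ev_rows += [rng.standard_normal(n_vox), rng.standard_normal(n_vox)]
    pre = SnapshotMatrix(
        "roi", "pre", pre_ids, np.array([v for ab in zip(pre_a_rows, pre_b_rows) for v in ab])
    )
    post = SnapshotMatrix("roi", "post", post_ids, np.array(post_b_rows))
    evoked = SnapshotMatrix("roi", "violation_evoked", ev_ids, np.array(ev_rows))
    return pairs, pre, post, evoked


def subject_scores(sub, roi="ca23dg", n_shuffles=0, seed=0):
    """Run the similarity stage on an in-memory subject; returns a dict."""
    from remdiff import patsim

    pre = sub.snapshot_matrix(roi, "pre")
    post = sub.snapshot_matrix(roi, "post")
    evoked = sub.snapshot_matrix(roi, "violation_evoked")
    records = patsim.pair_similarity(pre, post, sub.design.pairs)
    out = {
        "records": records,
        "diff": patsim.differentiation_score(records),
        "prediction": patsim.b_prediction_scores(pre, evoked, sub.design.pairs),
    }
    out["coupling"] = patsim.coupling_correlation(out["prediction"], records, "violation")
    if n_shuffles:
        out["randomization"] = patsim.item_specificity_z(
            pre, post, sub.design.pairs, n_shuffles=n_shuffles, seed=seed
        )
    return out
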