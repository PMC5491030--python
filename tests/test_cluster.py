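import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import adjusted_rand_score

import milieu
from milieu import (
    TwoStageClusterer,
    build_cluster_matrix,
    cohens_d,
    engagement_ordering,
    salience_profile,
    two_stage_cluster,
)
from milieu.cluster import ClusterSolution, render_salience_table
from milieu.network import WaveResult

from conftest import make_blocks

finite = st.floats(-1e6, 1e6, allow_nan=False)
vectors = st.lists(finite, min_size=2, max_size=12)


def test_cohens_d_hand_example():
    # means 2 vs 1, pooled SD sqrt(2)
    d = cohens_d([1.0, 3.0], [0.0, 2.0])
    assert abs(d - 1.0 / np.sqrt(2.0)) < 1e-12


@given(vectors, vectors)
def test_cohens_d_antisymmetric(a, b):
    da, db = cohens_d(a, b), cohens_d(b, a)
    if np.isfinite(da):
        assert da == pytest.approx(-db, abs=1e-9)
    else:
        assert da == -db


@given(vectors, vectors, st.floats(0.1, 100.0))
def test_cohens_d_scale_invariant(a, b, c):
    d1 = cohens_d(a, b)
    d2 = cohens_d([c * x for x in a], [c * x for x in b])
    if np.isfinite(d1):
        assert d2 == pytest.approx(d1, abs=1e-9, rel=1e-9)


def test_cohens_d_degenerate_spreads():
    assert cohens_d([1.0, 1.0], [1.0, 1.0]) == 0.0
    assert cohens_d([2.0, 2.0], [1.0, 1.0]) == np.inf
    assert cohens_d([0.0, 0.0], [1.0, 1.0]) == -np.inf
    with pytest.raises(ValueError):
        cohens_d([1.0], [0.0, 2.0])


def test_salience_threshold_boundary():
    # |d| = 0.50 is salient, 0.49 is not
    d = pd.DataFrame({"g": [0.50, -0.50, 0.49, -0.49]}, index=list("abcd"))
    mask = d.abs() >= milieu.cluster.SALIENCE_THRESHOLD
    assert mask["g"].tolist() == [True, True, False, False]


def blobs(rng, n_per=(50, 50, 50), sep=10.0, d=8):
    centers = rng.standard_normal((len(n_per), d)) * 0
    for i in range(len(n_per)):
        centers[i, i % d] = sep * i
    X, labels = [], []
    for i, n in enumerate(n_per):
        X.append(centers[i] + rng.standard_normal((n, d)))
        labels += [i] * n
    return np.vstack(X), np.asarray(labels)


def test_three_separated_blobs_recovered_exactly(rng):
    X, truth = blobs(rng, (50, 50, 50), sep=10.0)
    sol = two_stage_cluster(X, random_state=0)
    assert sol.k == 3
    assert adjusted_rand_score(truth, sol.assignments) == 1.0


def test_duplicated_rows_leave_solution_unchanged(rng):
    X, truth = blobs(rng, (30, 30), sep=12.0, d=5)
    sol = two_stage_cluster(X, random_state=0)
    dup = np.vstack([X, X])
    sol2 = two_stage_cluster(dup, random_state=0)
    assert sol2.k == sol.k
    assert adjusted_rand_score(sol.assignments, sol2.assignments[: len(X)]) == 1.0
    assert np.array_equal(sol2.assignments[: len(X)], sol2.assignments[len(X):])


def test_identical_rows_collapse_to_one_cluster():
    X = np.ones((20, 4))
    with pytest.warns(UserWarning, match="identical"):
        sol = two_stage_cluster(X)
    assert sol.k == 1


def test_k_override_validation(rng):
    X, _ = blobs(rng, (20, 20), d=4)
    sol = two_stage_cluster(X, k_override=3, random_state=0)
    assert sol.k == 3
    with pytest.raises(ValueError, match="k_override"):
        two_stage_cluster(X, k_override=12)


def test_cluster_matrix_modes(study, rng, fast_net):
    blocks = study["blocks"]
    only = build_cluster_matrix(blocks, feature_mode="predictors_only")
    assert only.shape[1] == 145
    model = fast_net.__class__(restarts=1, max_epochs=150).fit(blocks.saturated(), study["y"])
    wave = WaveResult("saturated", model.predict(blocks.saturated()), 0.9, model)
    full = build_cluster_matrix(blocks, wave)
    assert full.shape[1] == 146
    assert np.allclose(full.mean(), 0, atol=1e-9)
    assert np.allclose(full.std(ddof=1), 1, atol=1e-9)
    hid = build_cluster_matrix(blocks, wave, feature_mode="hidden_activations")
    assert hid.shape == (211, model.hidden_units)
    with pytest.raises(ValueError, match="saturated"):
        build_cluster_matrix(blocks, None)
    with pytest.raises(ValueError, match="feature_mode"):
        build_cluster_matrix(blocks, wave, feature_mode="pca")


def test_assignments_invariant_to_column_order(rng):
    X, _ = blobs(rng, (40, 40), sep=8.0, d=6)
    frame = pd.DataFrame(X, columns=[f"c{j}" for j in range(6)])
    a = TwoStageClusterer(random_state=1).fit(frame).labels_
    b = TwoStageClusterer(random_state=1).fit(frame[[f"c{j}" for j in (3, 1, 5, 0, 2, 4)]]).labels_
    assert np.array_equal(a, b)


def test_engagement_ordering_two_groups():
    y = np.concatenate([np.full(30, 1.0), np.full(30, -1.0)]) + np.linspace(0, 0.01, 60)
    sol = ClusterSolution(np.repeat([0, 1], 30), 2, (30, 30), np.zeros((2, 1)))
    out = engagement_ordering(sol, y)
    assert out.label_of(0) == "high" and out.label_of(1) == "low"
    assert out.engagement_d[0] > 0 > out.engagement_d[1]


def test_engagement_ordering_single_group():
    sol = ClusterSolution(np.zeros(10, dtype=int), 1, (10,), np.zeros((1, 1)))
    out = engagement_ordering(sol, np.arange(10.0))
    assert out.label_of(0) == "all"
    assert out.engagement_d == {}


def test_salience_requires_partition(study):
    sol = ClusterSolution(np.zeros(211, dtype=int), 1, (211,), np.zeros((1, 1)))
    with pytest.raises(ValueError, match="two groups"):
        salience_profile(sol, study["std"], study["blocks"])


def test_singleton_group_yields_missing_d(study):
    labels = np.zeros(211, dtype=int)
    labels[0] = 1
    labels[1:106] = 2
    sizes = tuple(int(x) for x in np.bincount(labels))
    sol = ClusterSolution(labels, 3, sizes, np.zeros((3, 1)))
    with pytest.warns(UserWarning, match="fewer than 2"):
        prof = salience_profile(sol, study["std"], study["blocks"])
    singleton_label = [c for c, n in prof.group_sizes.items() if n == 1][0]
    assert prof.d[singleton_label].isna().all()


def test_groupwise_mean_decomposition(study):
    """Size-weighted group means reproduce the overall mean per variable."""
    truth = study["truth"].group_labels
    variables = study["blocks"].saturated()
    for var in list(variables.columns)[:10]:
        v = variables[var].to_numpy()
        weighted = sum((truth == g).sum() * v[truth == g].mean() for g in range(4)) / len(v)
        assert abs(weighted - v.mean()) < 1e-9


def test_salience_render_blanks_subthreshold(study):
    truth = study["truth"].group_labels
    sizes = tuple(int(x) for x in np.bincount(truth))
    sol = engagement_ordering(
        ClusterSolution(truth, 4, sizes, np.zeros((4, 1))), study["std"].health_index
    )
    prof = salience_profile(sol, study["std"], study["blocks"])
    text = render_salience_table(prof)
    full = render_salience_table(prof, full=True)
    rows = {line.split("\t")[0]: line.split("\t")[1:] for line in text.strip().split("\n")[1:]}
    full_rows = {line.split("\t")[0]: line.split("\t")[1:] for line in full.strip().split("\n")[1:]}
    checked = 0
    for var in prof.d.index:
        for j, col in enumerate(prof.d.columns):
            v = prof.d.loc[var, col]
            if abs(v) < prof.threshold:
                assert rows[var][j] == ""
                assert full_rows[var][j] == f"{v:.2f}"
                checked += 1
    assert checked > 0
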