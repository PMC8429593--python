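"""Core UDC algorithm: folds, voting, success counts, triage, cleansing, rounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from udclean import (
    LabeledDataset,
    ModelSpec,
    NoiseSpec,
    SuccessCounts,
    UDCConfig,
    VoteMatrix,
    assign_folds,
    cleanse,
    inject_label_noise,
    register_backend,
    run_udc,
    screen_hyperparameters,
    success_counts,
    train_vote,
    triage,
)
from udclean.udc_core import default_model_specs

from conftest import make_separable


# ---------------------------------------------------------------------------
# fold assignment


def test_fold_sizes_k5_n100():
    ds = make_separable(n_per_class=50, seed=1)  # N=100
    folds = assign_folds(ds, k=5, seed=1)
    assert np.array_equal(np.bincount(folds.fold_of_item), [20] * 5)


def test_fold_sizes_forced_k2_n4():
    ds = LabeledDataset(
        item_ids=["a", "b", "c", "d"],
        labels=[0, 0, 1, 1],
        features=np.arange(8).reshape(4, 2),
    )
    folds = assign_folds(ds, k=2, seed=0)
    assert np.array_equal(np.bincount(folds.fold_of_item), [2, 2])


def test_stratified_folds_preserve_class_balance():
    """50/50 classes, k=5: every fold holds exactly 10 items of each class."""
    ds = make_separable(n_per_class=50, seed=2)
    folds = assign_folds(ds, k=5, seed=3, stratified=True)
    for f in range(5):
        in_fold = folds.fold_of_item == f
        counts = np.bincount(ds.labels[in_fold], minlength=2)
        assert np.array_equal(counts, [10, 10])


def test_fold_errors_and_determinism(blobs2):
    with pytest.raises(ValueError):
        assign_folds(blobs2, k=blobs2.n_items + 1, seed=0)
    skew = LabeledDataset(
        item_ids=[f"i{j}" for j in range(10)],
        labels=[0] * 8 + [1] * 2,
        features=np.random.default_rng(0).normal(size=(10, 2)),
        class_names=("a", "b"),
    )
    with pytest.raises(ValueError, match="'b'"):
        assign_folds(skew, k=5, seed=0, stratified=True)
    f1 = assign_folds(blobs2, k=5, seed=9)
    f2 = assign_folds(blobs2, k=5, seed=9)
    assert np.array_equal(f1.fold_of_item, f2.fold_of_item)


# ---------------------------------------------------------------------------
# voting


def test_vote_matrix_shape_n3_k5(blobs2, small_config):
    votes = train_vote(blobs2, small_config)
    assert votes.votes.shape == (15, blobs2.n_items)
    assert len(votes.model_index) == 15


def test_memorizing_backend_all_items_votes_all_true():
    """On clean widely separated data a memorizing ensemble votes every item
    correct: the memorization limit of all-items voting."""
    ds = make_separable(n_per_class=50, separation=12.0, seed=4)
    cfg = UDCConfig(
        model_specs=(ModelSpec("mem", "memorize", {}, seed=0),), k=3, seed=1
    )
    votes = train_vote(ds, cfg)
    assert votes.votes.all()


def test_fixed_wrong_backend_votes_all_false(blobs2):
    """A backend predicting a constant wrong class yields all-false rows."""

    class _Wrong:
        def predict(self, X):
            return np.full(len(X), 99)

    register_backend("always_wrong", lambda hp, seed, X, y: (_Wrong(), [0.0]))
    cfg = UDCConfig(
        model_specs=(ModelSpec("w", "always_wrong", {}, seed=0),), k=2, seed=1
    )
    votes = train_vote(blobs2, cfg)
    assert not votes.votes.any()


def test_out_of_fold_scope_gives_n_votes_per_item(blobs2):
    cfg = UDCConfig(voting_scope="out_of_fold", seed=2)
    votes = train_vote(blobs2, cfg)
    assert np.array_equal(votes.votes_per_item(), np.full(blobs2.n_items, 3))


# ---------------------------------------------------------------------------
# success counts and triage


def test_success_counts_are_column_sums():
    col = np.array([[True], [False], [True], [True], [False], [False]])
    vm = VoteMatrix(votes=col, model_index=tuple(("m", f) for f in range(6)),
                    valid=np.ones_like(col))
    assert success_counts(vm).s[0] == 3
    allv = np.ones((15, 4), dtype=bool)
    vm2 = VoteMatrix(votes=allv, model_index=tuple(("m", f) for f in range(15)),
                     valid=np.ones_like(allv))
    assert np.array_equal(success_counts(vm2).s, [15] * 4)
    vm3 = VoteMatrix(votes=~allv, model_index=vm2.model_index, valid=np.ones_like(allv))
    assert np.array_equal(success_counts(vm3).s, [0] * 4)


def test_triage_thresholds_nk15():
    counts = SuccessCounts(s=[14, 2, 8], max_votes=[15, 15, 15])
    cfg = UDCConfig(tau_low=0.3, tau_high=0.7, seed=0)
    cats = triage(counts, cfg).category_of_item
    assert list(cats) == ["correct", "incorrect", "noisy"]


def test_triage_boundary_semantics():
    cfg = UDCConfig(tau_low=0.0, tau_high=1.0, seed=0)
    counts = SuccessCounts(s=[15, 0, 14, 1], max_votes=[15] * 4)
    cats = triage(counts, cfg).category_of_item
    assert list(cats) == ["correct", "incorrect", "noisy", "noisy"]
    # s = n*k is correct for any tau_high <= 1
    for th in (0.5, 0.9, 1.0):
        cfg2 = UDCConfig(tau_low=0.1, tau_high=th, seed=0)
        assert triage(SuccessCounts(s=[15], max_votes=[15]), cfg2).category_of_item[0] == "correct"


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    s=st.lists(st.integers(min_value=0, max_value=15), min_size=1, max_size=40),
    taus=st.tuples(
        st.floats(min_value=0, max_value=0.98), st.floats(min_value=0.01, max_value=1.0)
    ).filter(lambda t: t[0] < t[1]),
)
def test_triage_partitions_items(s, taus):
    """Invariant: correct/incorrect/noisy partition the item set for any
    success counts and any admissible thresholds."""
    cfg = UDCConfig(tau_low=taus[0], tau_high=taus[1], seed=0)
    counts = SuccessCounts(s=s, max_votes=[15] * len(s))
    cats = triage(counts, cfg).category_of_item
    tallies = {c: int(np.sum(cats == c)) for c in ("correct", "incorrect", "noisy")}
    assert sum(tallies.values()) == len(s)


# ---------------------------------------------------------------------------
# cleansing


def _hand_triage(categories, ids):
    return triage(
        SuccessCounts(
            s=[15 if c == "correct" else 0 if c == "incorrect" else 8 for c in categories],
            max_votes=[15] * len(categories),
        ),
        UDCConfig(seed=0),
        item_ids=np.asarray(ids),
    )


def test_cleanse_policies():
    ds = LabeledDataset(
        item_ids=["a", "b", "c"], labels=[0, 1, 0],
        features=np.arange(6).reshape(3, 2), class_names=("x", "y"),
    )
    tri = _hand_triage(["correct", "incorrect", "noisy"], ds.item_ids)
    with pytest.warns(UserWarning):  # class 'y' is emptied by this policy
        cleansed, removed = cleanse(ds, tri, "incorrect_and_noisy")
    assert set(removed) == {"b", "c"} and list(cleansed.item_ids) == ["a"]
    _, removed2 = cleanse(ds, tri, "noisy_only")
    assert set(removed2) == {"c"}
    tri_ok = _hand_triage(["correct"] * 3, ds.item_ids)
    same, removed3 = cleanse(ds, tri_ok, "incorrect_and_noisy")
    assert len(removed3) == 0 and np.array_equal(same.item_ids, ds.item_ids)
    assert np.array_equal(same.labels, ds.labels)


def test_cleanse_warns_when_class_emptied():
    ds = LabeledDataset(
        item_ids=["a", "b", "c", "d"], labels=[0, 0, 1, 1],
        features=np.arange(8).reshape(4, 2), class_names=("x", "y"),
    )
    tri = _hand_triage(["correct", "correct", "incorrect", "incorrect"], ds.item_ids)
    with pytest.warns(UserWarning, match="no longer trainable"):
        cleansed, _ = cleanse(ds, tri, "incorrect_only")
    assert cleansed.meta.get("untrainable") is True


# ---------------------------------------------------------------------------
# multi-round runs


def test_single_round_run(noisy_blobs2, small_config):
    noisy, _ = noisy_blobs2
    rounds = run_udc(noisy, small_config)
    assert len(rounds) == 1
    assert rounds[0].triage.round_index == 0


def test_clean_data_stops_after_empty_round():
    """A round that removes nothing is a fixed point: later rounds are absent."""
    ds = make_separable(n_per_class=50, separation=12.0, seed=5)
    cfg = UDCConfig(
        model_specs=(ModelSpec("mem", "memorize", {}, seed=0),), rounds=3, seed=4
    )
    rounds = run_udc(ds, cfg)
    assert len(rounds) == 1 and len(rounds[0].removed_ids) == 0


def test_second_round_operates_on_survivors(noisy_blobs2):
    """Round 2 removals come from round-1 survivors and target residual
    flips/noise; the cleansed set shrinks monotonically."""
    noisy, record = noisy_blobs2
    cfg = UDCConfig(rounds=2, seed=8)
    rounds = run_udc(noisy, cfg)
    survivors_r1 = set(rounds[0].dataset_after.item_ids)
    for rnd in rounds[1:]:
        assert set(rnd.removed_ids) <= survivors_r1
        assert rnd.dataset_after.n_items <= rounds[0].dataset_after.n_items
    # overall: nearly all injected flips are gone from the final survivors
    final = set(rounds[-1].dataset_after.item_ids)
    residual = final & set(record.flipped_item_ids)
    assert len(residual) <= 0.1 * len(record)


def test_run_udc_is_deterministic(noisy_blobs2, small_config):
    noisy, _ = noisy_blobs2
    r1 = run_udc(noisy, small_config)
    r2 = run_udc(noisy, small_config)
    assert np.array_equal(r1[0].triage.category_of_item, r2[0].triage.category_of_item)
    assert np.array_equal(r1[0].triage.counts.s, r2[0].triage.counts.s)


def test_asymmetric_flip_recovery():
    """(35%, 5%) flips: at least 90% of injected flips are triaged incorrect."""
    ds = make_separable(n_per_class=300, dim=8, seed=31)
    noisy, record = inject_label_noise(ds, NoiseSpec((0.35, 0.05)), seed=32)
    rounds = run_udc(noisy, UDCConfig(seed=33))
    incorrect = set(rounds[0].triage.ids_in_category("incorrect"))
    recall = len(incorrect & set(record.flipped_item_ids)) / len(record)
    assert recall >= 0.9


def test_symmetric_fifty_fifty_failure_mode():
    """(50%, 50%) flips destroy the label signal: either screening declares
    the dataset untrainable, or the ensemble rejects one class wholesale."""
    ds = make_separable(n_per_class=150, dim=8, seed=51)
    noisy, _ = inject_label_noise(ds, NoiseSpec((0.5, 0.5)), seed=52)
    cfg = UDCConfig(seed=53)
    report = screen_hyperparameters(noisy, list(cfg.model_specs), k=5, seed=53)
    if not report.dataset_trainable:
        return
    tri = run_udc(noisy, cfg)[0].triage
    one_class_rejected = any(
        np.mean(tri.category_of_item[noisy.labels == c] == "incorrect") >= 0.9
        for c in range(2)
    )
    assert one_class_rejected


def test_multiclass_eighty_percent_uncleansable():
    """4 classes with 80% uniform flips leave fewer correct than incorrect
    labels per class: screening fails, or cleansing cannot beat the
    uncleansed baseline on a clean blind test set."""
    from udclean import split_blind_test
    from udclean.cli_io import retrain_and_evaluate

    ds = make_separable(n_per_class=220, C=4, dim=8, seed=61)
    train, test = split_blind_test(ds, 0.33, seed=61)
    noisy, _ = inject_label_noise(train, NoiseSpec.uniform(4, 0.8), seed=62)
    cfg = UDCConfig(model_specs=default_model_specs(4), seed=63)
    report = screen_hyperparameters(noisy, list(cfg.model_specs), k=5, seed=63)
    if not report.dataset_trainable:
        return
    before = retrain_and_evaluate(noisy, test, cfg.model_specs, seed=63)
    cleansed = run_udc(noisy, cfg)[0].dataset_after
    if cleansed.meta.get("untrainable") or len(np.unique(cleansed.labels)) < 2:
        return
    after = retrain_and_evaluate(cleansed, test, cfg.model_specs, seed=63)
    assert after <= before
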