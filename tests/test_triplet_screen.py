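import itertools
import math

import numpy as np
import pytest

from multisol.elm_classifier import ELMConfig
from multisol.feature_ranking import rank_features, top_k
from multisol.splits_metrics import PerformanceMetrics, SplitSpec
from multisol.triplet_screen import (
    Best10,
    TripletRecord,
    best10,
    enumerate_triplets,
    screen_triplets,
    single_feature_accuracy,
)

ELM = ELMConfig(n_hidden=150, seed=11)
SPLIT = SplitSpec(train_fraction=0.8, seed=5)


@pytest.fixture(scope="module")
def easy_rf(easy_dataset):
    return rank_features(easy_dataset)


@pytest.fixture(scope="module")
def small_report(easy_dataset, easy_rf):
    return screen_triplets(easy_dataset, easy_rf, k=12,
                           cutoffs={"accuracy": 0.9, "precision": 0.9,
                                    "recall": 0.9},
                           elm_config=ELM, split_spec=SPLIT)


@pytest.mark.parametrize("k,expected", [(3, 1), (10, 120), (50, 19600)])
def test_enumeration_counts(easy_rf, k, expected):
    assert len(enumerate_triplets(top_k(easy_rf, k))) == expected
    assert expected == math.comb(k, 3)


def test_enumeration_needs_three(easy_rf):
    with pytest.raises(ValueError, match=">= 3"):
        enumerate_triplets(top_k(easy_rf, 2))


def test_enumeration_lexicographic_and_exhaustive(easy_rf):
    # independent brute-force oracle at k = 6
    triplets = enumerate_triplets(top_k(easy_rf, 6))
    brute = set()
    for x in range(1, 7):
        for y in range(x + 1, 7):
            for z in range(y + 1, 7):
                brute.add((x, y, z))
    assert set(triplets) == brute
    assert triplets == sorted(triplets)
    assert len(set(triplets)) == len(triplets)


def test_rank_ordering_invariant(small_report):
    for r in small_report.records:
        x, y, z = r.ranks
        assert 1 <= x < y < z <= small_report.k
        assert len(set(r.feature_ids)) == 3
        assert r.mean_rank == pytest.approx((x + y + z) / 3)


def test_record_count(small_report):
    assert len(small_report.records) == math.comb(12, 3)


def test_census_ge_inequality(small_report):
    accs = [r.metrics.accuracy for r in small_report.records]
    assert small_report.census["accuracy"] == sum(a >= 0.9 for a in accs)


def test_census_monotone_in_cutoff(easy_dataset, easy_rf):
    accs = [r.metrics.accuracy
            for r in screen_triplets(easy_dataset, easy_rf, k=8,
                                     elm_config=ELM,
                                     split_spec=SPLIT).records]
    counts = [sum(a >= c for a in accs) for c in (0.5, 0.8, 0.9, 1.0)]
    assert counts == sorted(counts, reverse=True)


def test_impossible_cutoff_census_zero(easy_dataset, easy_rf):
    rep = screen_triplets(easy_dataset, easy_rf, k=6,
                          cutoffs={m: 1.01 for m in
                                   ("accuracy", "precision", "recall")},
                          elm_config=ELM, split_spec=SPLIT)
    assert rep.census == {"accuracy": 0, "precision": 0, "recall": 0}


def test_determinism(easy_dataset, easy_rf):
    kw = dict(k=8, elm_config=ELM, split_spec=SPLIT)
    r1 = screen_triplets(easy_dataset, easy_rf, **kw)
    r2 = screen_triplets(easy_dataset, easy_rf, **kw)
    assert r1.records == r2.records


def test_per_triplet_split_mode(easy_dataset, easy_rf):
    rep = screen_triplets(easy_dataset, easy_rf, k=6, elm_config=ELM,
                          split_spec=SPLIT, per_triplet_split=True)
    assert len(rep.records) == 20


def test_multiplicity_with_redundant_blocks(easy_dataset, easy_rf):
    # >= 10 triplets at accuracy >= 0.9, with >= 2 sharing no features
    rep = screen_triplets(easy_dataset, easy_rf, k=20,
                          cutoffs={"accuracy": 0.9}, elm_config=ELM,
                          split_spec=SPLIT)
    good = [r for r in rep.records if r.metrics.accuracy >= 0.9]
    assert len(good) >= 10
    disjoint = any(
        not set(a.feature_ids) & set(b.feature_ids)
        for a, b in itertools.combinations(good, 2))
    assert disjoint


# -- best10 -----------------------------------------------------------------

def _toy_record(ranks, acc):
    ids = tuple(f"f{r}" for r in ranks)
    tp = round(acc * 10)
    return TripletRecord(ids, ranks, PerformanceMetrics(TP=tp, FP=10 - tp,
                                                        FN=0, TN=0))


def _toy_report(records):
    from multisol.triplet_screen import TripletScreenReport
    return TripletScreenReport(records=records, k=50,
                               cutoffs={"accuracy": 0.8, "precision": 0.8,
                                        "recall": 0.8},
                               census={}, n_undefined={}, split_seed=0,
                               elm_base_seed=0)


def test_best10_hand_built_oracle():
    # 12 records; brute-force sort oracle for the (min, max) mean_ranks
    rng = np.random.default_rng(13)
    records = []
    for i in range(12):
        ranks = tuple(sorted(rng.choice(np.arange(1, 51), 3,
                                        replace=False).tolist()))
        records.append(_toy_record(ranks, acc=round(0.5 + 0.05 * (i % 9), 2)))
    rep = _toy_report(records)
    b = best10(rep, "accuracy")
    assert len(b.records) == 10

    oracle = sorted(records,
                    key=lambda r: (-r.metrics.accuracy, r.mean_rank, r.ranks))
    expected = oracle[:10]
    assert list(b.records) == expected
    assert b.min_mean_rank == min(r.mean_rank for r in expected)
    assert b.max_mean_rank == max(r.mean_rank for r in expected)


def test_best10_identity_when_exactly_ten():
    records = [_toy_record((i + 1, i + 2, i + 3), 0.9) for i in range(10)]
    b = best10(_toy_report(records), "accuracy")
    assert set(b.records) == set(records)
    assert b.complete


def test_best10_fewer_than_ten_flagged():
    records = [_toy_record((1, 2, 3), 0.9), _toy_record((2, 3, 4), 0.8)]
    b = best10(_toy_report(records), "accuracy")
    assert len(b.records) == 2
    assert not b.complete


def test_best10_tie_determinism(small_report):
    b1 = best10(small_report, "accuracy")
    b2 = best10(small_report, "accuracy")
    assert b1 == b2


def test_best10_min_mean_rank_bound(small_report):
    b = best10(small_report, "accuracy")
    assert b.min_mean_rank >= (1 + 2 + 3) / 3


def test_best10_unknown_metric(small_report):
    with pytest.raises(ValueError):
        best10(small_report, "f1")


# -- single features --------------------------------------------------------

def test_single_feature_unknown_id(easy_dataset):
    with pytest.raises(KeyError):
        single_feature_accuracy(easy_dataset, "no_such_feature")


def test_triplet_distinctness_enforced():
    with pytest.raises(ValueError, match="distinct"):
        TripletRecord(("a", "a", "b"), (1, 1, 2),
                      PerformanceMetrics(1, 1, 1, 1))
    with pytest.raises(ValueError, match="x <= y <= z"):
        TripletRecord(("a", "b", "c"), (3, 2, 1),
                      PerformanceMetrics(1, 1, 1, 1))


def test_uninformative_single_feature_near_chance():
    from multisol.synthetic_data import SyntheticSpec, generate
    accs = []
    for seed in range(20):
        ds = generate(SyntheticSpec(n_features=10,
                                    n_samples_per_class=(20, 20),
                                    n_informative=0, effect_size=0.0,
                                    seed=seed))
        accs.append(single_feature_accuracy(
            ds, ds.feature_ids[0], ELMConfig(n_hidden=30, seed=seed),
            SplitSpec(0.8, True, seed)).accuracy)
    # 8 test samples per run; mean over 20 runs concentrates near 0.5
    assert 0.3 < float(np.mean(accs)) < 0.7


def test_complementarity_on_redundant_blocks(easy_dataset, easy_rf):
    # some triplet beats each of its members alone by >= 0.05
    rep = screen_triplets(easy_dataset, easy_rf, k=15, elm_config=ELM,
                          split_spec=SPLIT)
    singles = {}
    for fid in top_k(easy_rf, 15).feature_ids:
        singles[fid] = single_feature_accuracy(easy_dataset, fid, ELM,
                                               SPLIT).accuracy
    assert any(
        all(r.metrics.accuracy >= singles[f] + 0.05 for f in r.feature_ids)
        for r in rep.records)


def test_report_serialization(tmp_path, small_report):
    from multisol import data_io
    path = data_io.write_report_table(small_report, tmp_path / "t.tsv")
    back = data_io.read_report_table(path)
    assert int(back["n_triplets"]) == len(small_report.records)
    assert int(back["census_accuracy"]) == small_report.census["accuracy"]
    frame_path = small_report.to_tsv(tmp_path / "records.tsv")
    assert frame_path.read_text().count("\n") == len(small_report.records) + 1
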