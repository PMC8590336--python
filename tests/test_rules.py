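import math

import numpy as np
import pytest
from scipy import stats

from mmpaq.mmp import MatchedPair
from mmpaq.rules import (
    TransformationRule,
    aggregate,
    cluster_contexts,
    compare_rulesets,
    compile_rules,
    rules_to_frame,
    sd_sem_by_cluster_count,
)
from mmpaq.rules import test_binary as binomial_direction_test
from mmpaq.rules import test_continuous as wilcoxon_delta_test


def _pair(delta, context="c1ccc([*:1])cc1", va="C[*:1]", vb="Cl[*:1]", i=[0]):
    i[0] += 1
    return MatchedPair(
        id_a=f"a{i[0]}", id_b=f"b{i[0]}", context_key=context,
        variable_a=va, variable_b=vb, delta=delta, n_cuts=1,
    )


# ---------------------------------------------------------------------------
# aggregation


def test_aggregate_constant_deltas():
    pairs = [_pair(1.0) for _ in range(12)]
    (rule,) = aggregate(pairs)
    assert rule.n_pairs == 12
    assert rule.mean_delta == 1.0
    assert rule.sd_delta == 0.0
    assert rule.sem_delta == 0.0


def test_aggregate_sample_sd():
    pairs = [_pair(d) for d in (1.0, 1.0, -1.0, -1.0)]
    (rule,) = aggregate(pairs)
    assert rule.mean_delta == 0.0
    assert rule.sd_delta == pytest.approx(np.std([1, 1, -1, -1], ddof=1))
    assert rule.sem_delta == pytest.approx(rule.sd_delta / 2)


def test_aggregate_classification_extreme():
    pairs = [_pair(-1.0) for _ in range(22)]
    (rule,) = aggregate(pairs, task="classification")
    assert rule.n_decrease == 22 and rule.n_increase == 0
    assert rule.toxicity_change == -1.0


def test_aggregate_conserves_pair_count(noisy_pairs):
    rules = aggregate(noisy_pairs)
    assert sum(r.n_pairs for r in rules) == len(noisy_pairs)


def test_reversal_antisymmetry():
    pairs = [_pair(d) for d in (0.5, 1.0, 0.7, 1.2, 0.9, 0.6, 1.1, 0.8, 1.3, 0.4, 0.95, 1.05)]
    (rule,) = aggregate(pairs)
    wilcoxon_delta_test(rule)
    rev = rule.reversed()
    assert rev.mean_delta == -rule.mean_delta
    assert rev.sd_delta == rule.sd_delta
    assert rev.p_value == rule.p_value
    assert (rev.variable_from, rev.variable_to) == (rule.variable_to, rule.variable_from)


# ---------------------------------------------------------------------------
# continuous test


def test_wilcoxon_twenty_positive_deltas_exact():
    """All-positive deltas hit the maximal signed-rank statistic: the exact
    two-sided p is twice the one-sided point mass, 2 * 2^-20."""
    deltas = [0.1 * (i + 1) for i in range(20)]
    (rule,) = aggregate([_pair(d) for d in deltas])
    wilcoxon_delta_test(rule)
    assert rule.p_value == pytest.approx(2 * 2**-20, rel=1e-9)
    assert rule.is_rule


def test_more_than_ten_is_strict():
    deltas = [0.1 * (i + 1) for i in range(10)]
    (rule,) = aggregate([_pair(d) for d in deltas])
    wilcoxon_delta_test(rule, min_pairs=10)
    assert rule.p_value < 0.05
    assert not rule.is_rule  # 10 pairs is not "more than 10"


def test_all_zero_deltas_sentinel():
    (rule,) = aggregate([_pair(0.0) for _ in range(12)])
    wilcoxon_delta_test(rule)
    assert rule.p_value == 1.0
    assert not rule.is_rule


def test_wilcoxon_type1_error_rate():
    """Symmetric zero-centered deltas: rejection rate ~ alpha."""
    rng = np.random.default_rng(123)
    rejections = 0
    n_sim = 1000
    for _ in range(n_sim):
        deltas = rng.normal(0, 1, 20)
        (rule,) = aggregate([_pair(float(d)) for d in deltas])
        wilcoxon_delta_test(rule, min_pairs=10)
        if rule.p_value < 0.05:
            rejections += 1
    assert abs(rejections / n_sim - 0.05) <= 0.02


# ---------------------------------------------------------------------------
# binary test


def _binomial_two_sided(k, n, p=0.5):
    """Oracle: sum of all outcome probabilities not exceeding P(X=k)."""
    pk = stats.binom.pmf(k, n, p)
    return float(
        sum(
            stats.binom.pmf(i, n, p)
            for i in range(n + 1)
            if stats.binom.pmf(i, n, p) <= pk * (1 + 1e-12)
        )
    )


def test_binomial_ten_decreases():
    pairs = [_pair(-1.0) for _ in range(10)]
    (rule,) = aggregate(pairs, task="classification")
    binomial_direction_test(rule, require_direction=False)
    assert rule.p_value == pytest.approx(2 * 0.5**10, rel=1e-12)
    assert rule.is_rule


def test_binomial_balanced_split_fails():
    pairs = [_pair(-1.0) for _ in range(5)] + [_pair(1.0) for _ in range(5)]
    (rule,) = aggregate(pairs, task="classification")
    binomial_direction_test(rule, require_direction=False)
    assert rule.p_value == 1.0
    assert not rule.is_rule


def test_binomial_matches_exact_tail_sums():
    for n in range(1, 31):
        for k in range(n + 1):
            pairs = [_pair(-1.0) for _ in range(k)] + [_pair(1.0) for _ in range(n - k)]
            (rule,) = aggregate(pairs, task="classification")
            binomial_direction_test(rule, min_pairs=0, require_direction=False)
            assert rule.p_value == pytest.approx(
                _binomial_two_sided(k, n), abs=1e-12
            ), (n, k)


def test_direction_requirement_blocks_toxicity_increase():
    pairs = [_pair(1.0) for _ in range(20)]
    (rule,) = aggregate(pairs, task="classification")
    binomial_direction_test(rule, require_direction=True)
    assert rule.p_value < 0.05
    assert not rule.is_rule
    binomial_direction_test(rule, require_direction=False)
    assert rule.is_rule


def test_nochange_pairs_count_toward_npairs_not_binomial_n():
    pairs = [_pair(-1.0) for _ in range(8)] + [_pair(0.0) for _ in range(4)]
    (rule,) = aggregate(pairs, task="classification")
    binomial_direction_test(rule, require_direction=True)
    assert rule.n_pairs == 12 and rule.n_nochange == 4
    assert rule.p_value == pytest.approx(2 * 0.5**8, rel=1e-12)


# ---------------------------------------------------------------------------
# context clustering


def test_single_context_single_cluster():
    pairs = [_pair(1.0) for _ in range(5)]
    (rule,) = aggregate(pairs)
    cluster_contexts(rule)
    assert rule.n_clusters == 1
    assert rule.is_general is False


def test_two_distant_context_families_two_clusters():
    # long alkyl chains are near-identical under circular fingerprints;
    # cross-family Tanimoto is ~0.25, far under the 0.7 cutoff
    fam_a = [f"{'C' * i}CCCCCCCCC[*:1]" for i in range(1, 4)]
    fam_b = ["O=C(O)c1ccc(CCCC[*:1])cc1", "O=C(O)c1ccc(CCCCC[*:1])cc1"]
    pairs = [_pair(1.0, context=c) for c in fam_a + fam_b]
    (rule,) = aggregate(pairs)
    cluster_contexts(rule, tanimoto_cutoff=0.7)
    assert rule.n_clusters == 2


def test_clustering_does_not_change_effect_statistics(noisy_rules):
    for rule in noisy_rules[:5]:
        before = (rule.mean_delta, rule.sd_delta, rule.sem_delta)
        cluster_contexts(rule)
        assert (rule.mean_delta, rule.sd_delta, rule.sem_delta) == before


def test_generality_threshold_is_five(noisy_rules):
    for rule in noisy_rules:
        assert rule.is_general == (rule.n_clusters >= 5)


# ---------------------------------------------------------------------------
# ruleset comparison


def test_compare_identical_rulesets(noisy_rules):
    cmp = compare_rulesets(noisy_rules, noisy_rules)
    assert cmp.r_squared == pytest.approx(1.0)
    assert cmp.sign_agreement == 1.0
    assert cmp.n_only_a == cmp.n_only_b == 0


def test_compare_noise_limit(noisy_rules):
    rng = np.random.default_rng(5)
    import copy

    noisy_b = copy.deepcopy(noisy_rules)
    for r in noisy_b:
        r.mean_delta += float(rng.normal(0, 1e-6))
    cmp = compare_rulesets(noisy_rules, noisy_b)
    assert cmp.r_squared > 0.999999


def test_compare_disjoint_sets_sentinel():
    a = [TransformationRule("A[*:1]", "B[*:1]", "regression", 5, mean_delta=1.0, is_rule=True)]
    b = [TransformationRule("C[*:1]", "D[*:1]", "regression", 5, mean_delta=1.0, is_rule=True)]
    cmp = compare_rulesets(a, b)
    assert cmp.n_shared == 0
    assert cmp.r_squared is None


# ---------------------------------------------------------------------------
# frame output and diagnostics


def test_rules_frame_and_sd_sem_report(noisy_rules):
    frame = rules_to_frame(noisy_rules)
    assert len(frame) == len(noisy_rules)
    assert {"from", "to", "n_pairs", "p_value", "is_rule"} <= set(frame.columns)
    report = sd_sem_by_cluster_count(noisy_rules)
    assert not report.empty


def test_bh_correction_only_reduces_rules(noisy_pairs):
    plain = compile_rules(noisy_pairs, cluster=False)
    corrected = compile_rules(noisy_pairs, cluster=False, bh_correction=True)
    assert sum(r.is_rule for r in corrected) <= sum(r.is_rule for r in plain)
    for p, c in zip(plain, corrected):
        assert c.p_value >= p.p_value - 1e-15
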