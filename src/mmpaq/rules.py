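"""Compile matched pairs into statistically tested transformation rules.

Pairs sharing a directed fragment change (variable_from -> variable_to) are
aggregated; a transformation is promoted to a *rule* when it has enough pairs
and its property change passes the significance test — a two-sided Wilcoxon
signed-rank test for continuous endpoints, or an exact binomial test
(success probability 0.5) on the direction of label changes for binary
endpoints.  Contexts are clustered on Morgan fingerprints (Butina, Tanimoto
cutoff 0.7) to gauge chemotype generality; at least five clusters are
conventionally expected for a transferable rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.ML.Cluster import Butina
from scipy import stats

from mmpaq.mmp import MatchedPair

GENERALITY_MIN_CLUSTERS = 5


@dataclass
class TransformationRule:
    variable_from: str
    variable_to: str
    task: str
    n_pairs: int
    deltas: list[float] = field(default_factory=list, repr=False)
    context_keys: list[str] = field(default_factory=list, repr=False)
    mean_delta: float | None = None
    sd_delta: float | None = None
    sem_delta: float | None = None
    n_increase: int = 0
    n_decrease: int = 0
    n_nochange: int = 0
    toxicity_change: float | None = None
    p_value: float | None = None
    is_rule: bool = False
    n_clusters: int | None = None
    is_general: bool | None = None
    n_experimental: int = 0
    n_predicted: int = 0
    n_mixed: int = 0

    def reversed(self) -> "TransformationRule":
        """The same transformation read in the opposite direction."""
        rev = TransformationRule(
            variable_from=self.variable_to,
            variable_to=self.variable_from,
            task=self.task,
            n_pairs=self.n_pairs,
            deltas=[-d for d in self.deltas],
            context_keys=list(self.context_keys),
            n_increase=self.n_decrease,
            n_decrease=self.n_increase,
            n_nochange=self.n_nochange,
            p_value=self.p_value,
            is_rule=self.is_rule,
            n_clusters=self.n_clusters,
            is_general=self.is_general,
            n_experimental=self.n_experimental,
            n_predicted=self.n_predicted,
            n_mixed=self.n_mixed,
        )
        if self.mean_delta is not None:
            rev.mean_delta = -self.mean_delta
            rev.sd_delta = self.sd_delta
            rev.sem_delta = self.sem_delta
        if self.toxicity_change is not None:
            rev.toxicity_change = -self.toxicity_change
        return rev


def aggregate(pairs: list[MatchedPair], task: str = "regression") -> list[TransformationRule]:
    """Group pairs by directed transformation and compute summary statistics.

    Pairs arrive in canonical orientation (variable_a <= variable_b under the
    joint attachment renumbering), so each unordered molecule pair contributes
    one observation to exactly one directed transformation; the reverse
    direction is derivable via :meth:`TransformationRule.reversed`.
    """
    groups: dict[tuple[str, str], list[MatchedPair]] = {}
    for pair in pairs:
        groups.setdefault((pair.variable_a, pair.variable_b), []).append(pair)
    rules = []
    for (v_from, v_to) in sorted(groups):
        members = groups[(v_from, v_to)]
        deltas = [p.delta for p in members]
        rule = TransformationRule(
            variable_from=v_from,
            variable_to=v_to,
            task=task,
            n_pairs=len(members),
            deltas=deltas,
            context_keys=[p.context_key for p in members],
        )
        for p in members:
            srcs = {p.source_a, p.source_b}
            if srcs == {"experimental"}:
                rule.n_experimental += 1
            elif srcs == {"predicted"}:
                rule.n_predicted += 1
            else:
                rule.n_mixed += 1
        if task == "regression":
            arr = np.asarray(deltas, dtype=float)
            rule.mean_delta = float(arr.mean())
            rule.sd_delta = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            rule.sem_delta = rule.sd_delta / math.sqrt(arr.size)
        else:
            rule.n_increase = sum(1 for d in deltas if d > 0)
            rule.n_decrease = sum(1 for d in deltas if d < 0)
            rule.n_nochange = sum(1 for d in deltas if d == 0)
            rule.toxicity_change = (rule.n_increase - rule.n_decrease) / len(deltas)
        rules.append(rule)
    return rules


def test_continuous(
    rule: TransformationRule,
    alpha: float = 0.05,
    min_pairs: int = 10,
    alternative: str = "two-sided",
) -> TransformationRule:
    """Wilcoxon signed-rank test on the deltas of one transformation.

    Zero deltas are dropped (standard convention); the exact null
    distribution is used for n <= 25 without ties, the normal approximation
    with continuity correction otherwise.  ``is_rule`` requires strictly more
    than ``min_pairs`` pairs and p < alpha.
    """
    deltas = np.asarray([d for d in rule.deltas if d != 0.0], dtype=float)
    if deltas.size == 0:
        rule.p_value = 1.0
        rule.is_rule = False
        return rule
    exact = deltas.size <= 25 and len(set(np.abs(deltas))) == deltas.size
    res = stats.wilcoxon(
        deltas,
        alternative=alternative,
        method="exact" if exact else "approx",
        correction=True,
    )
    rule.p_value = float(res.pvalue)
    rule.is_rule = rule.n_pairs > min_pairs and rule.p_value < alpha
    return rule


def test_binary(
    rule: TransformationRule,
    alpha: float = 0.05,
    min_pairs: int = 6,
    p_success: float = 0.5,
    require_direction: bool = True,
) -> TransformationRule:
    """Exact binomial test on the direction of label changes.

    n counts only label-changing pairs; same-label pairs contribute to
    n_pairs and n_nochange but not to the test.  With ``require_direction``
    only toxicity-decreasing transformations can become rules.
    """
    n_changes = rule.n_increase + rule.n_decrease
    if n_changes == 0:
        rule.p_value = 1.0
        rule.is_rule = False
        return rule
    res = stats.binomtest(rule.n_decrease, n_changes, p=p_success,
                          alternative="two-sided")
    rule.p_value = float(res.pvalue)
    ok = rule.n_pairs > min_pairs and rule.p_value < alpha
    if require_direction:
        ok = ok and rule.toxicity_change < 0
    rule.is_rule = ok
    return rule


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _context_fingerprint(context_key: str):
    mol = Chem.MolFromSmiles(context_key, sanitize=False)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    Chem.SanitizeMol(mol)
    return _MORGAN.GetFingerprint(mol)


def cluster_contexts(
    rule: TransformationRule, tanimoto_cutoff: float = 0.7
) -> TransformationRule:
    """Butina clustering of the rule's pair contexts on Morgan fingerprints.

    Sets ``n_clusters`` (chemotype diversity of the contexts) and the
    generality flag (``n_clusters >= 5``).  Clustering is diagnostic only and
    never alters the rule's effect statistics.
    """
    contexts = sorted(set(rule.context_keys))
    if len(contexts) == 1:
        rule.n_clusters = 1
    else:
        fps = [_context_fingerprint(c) for c in contexts]
        dists = []
        for i in range(1, len(fps)):
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
            dists.extend(1.0 - s for s in sims)
        clusters = Butina.ClusterData(
            dists, len(fps), 1.0 - tanimoto_cutoff, isDistData=True
        )
        rule.n_clusters = len(clusters)
    rule.is_general = rule.n_clusters >= GENERALITY_MIN_CLUSTERS
    return rule


def compile_rules(
    pairs: list[MatchedPair],
    task: str = "regression",
    alpha: float = 0.05,
    min_pairs: int | None = None,
    require_direction: bool = False,
    tanimoto_cutoff: float = 0.7,
    cluster: bool = True,
    bh_correction: bool = False,
) -> list[TransformationRule]:
    """Aggregate, test, and (optionally) cluster: the full rule table.

    ``min_pairs`` defaults to 10 for regression ("more than 10 pairs") and 6
    for classification ("exceeds six") — both strict inequalities.  No
    multiple-testing correction is applied by default; ``bh_correction``
    switches on Benjamini-Hochberg across the transformation set.
    """
    if min_pairs is None:
        min_pairs = 10 if task == "regression" else 6
    rules = aggregate(pairs, task)
    for rule in rules:
        if task == "regression":
            test_continuous(rule, alpha=alpha, min_pairs=min_pairs)
        else:
            test_binary(
                rule, alpha=alpha, min_pairs=min_pairs,
                require_direction=require_direction,
            )
    if bh_correction and rules:
        pvals = np.array([r.p_value for r in rules])
        order = np.argsort(pvals)
        m = len(pvals)
        adjusted = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            running = min(running, pvals[idx] * m / rank)
            adjusted[idx] = running
        for rule, p_adj in zip(rules, adjusted):
            rule.p_value = float(p_adj)
            if rule.is_rule and p_adj >= alpha:
                rule.is_rule = False
    if cluster:
        for rule in rules:
            cluster_contexts(rule, tanimoto_cutoff)
    return rules


def rules_to_frame(rules: list[TransformationRule]) -> pd.DataFrame:
    rows = []
    for r in rules:
        rows.append(
            {
                "from": r.variable_from,
                "to": r.variable_to,
                "n_pairs": r.n_pairs,
                "n_clusters": r.n_clusters,
                "mean_delta": r.mean_delta,
                "sd_delta": r.sd_delta,
                "sem_delta": r.sem_delta,
                "n_increase": r.n_increase,
                "n_decrease": r.n_decrease,
                "n_nochange": r.n_nochange,
                "toxicity_change": r.toxicity_change,
                "p_value": r.p_value,
                "is_rule": r.is_rule,
                "is_general": r.is_general,
                "n_experimental": r.n_experimental,
                "n_predicted": r.n_predicted,
                "n_mixed": r.n_mixed,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RulesetComparison:
    n_shared: int
    r_squared: float | None
    sign_agreement: float | None
    n_only_a: int
    n_only_b: int
    n_converted_to_rules: int  # non-rules in A that became rules in B
    mean_pair_growth: float | None


def compare_rulesets(
    rules_a: list[TransformationRule],
    rules_b: list[TransformationRule],
    rules_only: bool = True,
) -> RulesetComparison:
    """Agreement between two rule sets (e.g. experimental vs expanded).

    Joins on the directed transformation key; reports the squared Pearson
    correlation of mean deltas over the intersection, the fraction of shared
    transformations whose mean deltas agree in sign, and amplification
    statistics (non-rules converted to rules, pair-count growth).
    """
    key = lambda r: (r.variable_from, r.variable_to)
    a_map = {key(r): r for r in rules_a}
    b_map = {key(r): r for r in rules_b}
    if rules_only:
        shared = [k for k in a_map if k in b_map and a_map[k].is_rule]
    else:
        shared = [k for k in a_map if k in b_map]
    n_converted = sum(
        1 for k in a_map if k in b_map and not a_map[k].is_rule and b_map[k].is_rule
    )
    if not shared:
        return RulesetComparison(
            n_shared=0,
            r_squared=None,
            sign_agreement=None,
            n_only_a=len(a_map) - len(set(a_map) & set(b_map)),
            n_only_b=len(b_map) - len(set(a_map) & set(b_map)),
            n_converted_to_rules=n_converted,
            mean_pair_growth=None,
        )
    da = np.array([a_map[k].mean_delta for k in shared], dtype=float)
    db = np.array([b_map[k].mean_delta for k in shared], dtype=float)
    if len(shared) >= 2 and np.std(da) > 0 and np.std(db) > 0:
        r2 = float(np.corrcoef(da, db)[0, 1] ** 2)
    else:
        r2 = None
    signs = float(np.mean(np.sign(da) == np.sign(db)))
    growth = float(
        np.mean([b_map[k].n_pairs / a_map[k].n_pairs for k in shared])
    )
    return RulesetComparison(
        n_shared=len(shared),
        r_squared=r2,
        sign_agreement=signs,
        n_only_a=len(a_map) - len(set(a_map) & set(b_map)),
        n_only_b=len(b_map) - len(set(a_map) & set(b_map)),
        n_converted_to_rules=n_converted,
        mean_pair_growth=growth,
    )


def sd_sem_by_cluster_count(rules: list[TransformationRule]) -> pd.DataFrame:
    """Diagnostic summary: SD and SEM of rule mean deltas by cluster count.

    Mirrors the generality analysis — rules backed by more chemotype clusters
    tend to have stable SD and shrinking SEM.  Purely a report; no filtering.
    """
    rows = [
        {
            "n_clusters": r.n_clusters,
            "sd_delta": r.sd_delta,
            "sem_delta": r.sem_delta,
        }
        for r in rules
        if r.n_clusters is not None and r.sd_delta is not None
    ]
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    return frame.groupby("n_clusters").agg(["mean", "count"])
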