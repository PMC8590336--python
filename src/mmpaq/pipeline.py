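"""End-to-end orchestration: plain MMPA and MMPA-by-QSAR.

Plain MMPA: curate -> fragment -> pair -> compile rules.  MMPA-by-QSAR, for
small labeled datasets with a pool of unlabeled molecules: train the consensus
QSAR model, score the pool, keep only predictions inside the applicability
domain under a stringent policy, merge them (source="predicted") with the
experimental records, rerun MMPA on the expanded set, and report how the
expanded rules agree with and amplify the experimental ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mmpaq.adfilter import ExpansionPolicy, ad_curve, filter_for_expansion, score_predictions
from mmpaq.mmp import mine_pairs
from mmpaq.molprep import MoleculeRecord, deduplicate
from mmpaq.qsar import ConsensusModel, scaffold_split
from mmpaq.rules import (
    RulesetComparison,
    TransformationRule,
    compare_rulesets,
    compile_rules,
    rules_to_frame,
    sd_sem_by_cluster_count,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    task: str = "regression"
    seed: int = 0
    # fragmentation
    max_cuts: int = 3
    max_heavy_variable: int = 13
    min_ratio_context_to_variable: float = 1.0
    hydrogen_mode: bool = True
    # rule compilation
    alpha: float = 0.05
    min_pairs: int | None = None  # task default: 10 regression / 6 classification
    require_direction: bool = False
    tanimoto_cutoff: float = 0.7
    cluster: bool = True
    # QSAR / AD (MMPA-by-QSAR mode)
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    algorithms: tuple[str, ...] = ("rf", "gb", "svm", "xgboost")
    descriptor_sets: tuple[str, ...] = ("maccs", "open2d")
    grid: dict | None = None
    policy: ExpansionPolicy = field(default_factory=ExpansionPolicy)

    def validate(self) -> None:
        if self.task not in {"regression", "classification"}:
            raise ValueError(f"unknown task: {self.task!r}")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")
        if not 1 <= self.max_cuts <= 3:
            raise ValueError("max_cuts must be in [1, 3]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


@dataclass
class MMPAResult:
    rules: list[TransformationRule]
    n_pairs: int
    n_transformations: int
    n_rules: int
    report: dict


@dataclass
class MMPAByQSARResult:
    experimental: MMPAResult
    expanded: MMPAResult
    comparison: RulesetComparison | None
    n_accepted: int
    model: ConsensusModel | None
    curve: object | None
    config: RunConfig | None = None
    warnings: list[str] = field(default_factory=list)


def run_mmpa(records: list[MoleculeRecord], config: RunConfig) -> MMPAResult:
    """Plain MMPA on a labeled dataset."""
    config.validate()
    if not records:
        raise ValueError("prep: empty input dataset")
    if any(r.property is None for r in records):
        raise ValueError("prep: every record needs a property value or label")
    pairs = mine_pairs(
        records,
        max_cuts=config.max_cuts,
        max_heavy_variable=config.max_heavy_variable,
        min_ratio_context_to_variable=config.min_ratio_context_to_variable,
        hydrogen_mode=config.hydrogen_mode,
    )
    rules = compile_rules(
        pairs,
        task=config.task,
        alpha=config.alpha,
        min_pairs=config.min_pairs,
        require_direction=config.require_direction,
        tanimoto_cutoff=config.tanimoto_cutoff,
        cluster=config.cluster,
    )
    report = {
        "n_molecules": len(records),
        "n_pairs": len(pairs),
        "n_transformations": len(rules),
        "n_rules": sum(r.is_rule for r in rules),
    }
    if config.task == "regression" and config.cluster:
        report["sd_sem_by_cluster"] = sd_sem_by_cluster_count(rules)
    return MMPAResult(
        rules=rules,
        n_pairs=len(pairs),
        n_transformations=len(rules),
        n_rules=report["n_rules"],
        report=report,
    )


def run_mmpa_by_qsar(
    labeled: list[MoleculeRecord],
    unlabeled: list[MoleculeRecord],
    config: RunConfig,
) -> MMPAByQSARResult:
    """Train -> AD-filter -> expand -> mine -> compare.

    The consensus model is trained on a scaffold split of the labeled data
    (grid search on the validation part).  AD diagnostics are computed on the
    held-out test part; the stringent expansion policy is then applied to the
    unlabeled pool.  If nothing is accepted, the run degrades to plain MMPA
    with a warning.
    """
    config.validate()
    experimental_result = run_mmpa(labeled, config)
    if not unlabeled:
        message = "no unlabeled pool provided; result equals plain MMPA"
        logger.warning(message)
        return MMPAByQSARResult(
            experimental=experimental_result,
            expanded=experimental_result,
            comparison=None,
            n_accepted=0,
            model=None,
            curve=None,
            config=config,
            warnings=[message],
        )

    train, val, test = scaffold_split(labeled, config.split_ratios, seed=config.seed)
    model = ConsensusModel(
        task=config.task,
        algorithms=config.algorithms,
        descriptor_sets=config.descriptor_sets,
        grid=config.grid,
        seed=config.seed,
    )
    model.fit(
        [r.smiles_canonical for r in train],
        [r.property for r in train],
        X_val=[r.smiles_canonical for r in val],
        y_val=[r.property for r in val],
    )

    curve = None
    if test:
        singles_test = model.predict_singles([r.smiles_canonical for r in test])
        test_ads = score_predictions(
            [r.id for r in test],
            [r.smiles_canonical for r in test],
            singles_test,
            config.task,
            truth=np.array([r.property for r in test]),
        )
        curve = ad_curve(test_ads, config.task)

    singles = model.predict_singles([r.smiles_canonical for r in unlabeled])
    pool_ads = score_predictions(
        [r.id for r in unlabeled],
        [r.smiles_canonical for r in unlabeled],
        singles,
        config.task,
    )
    accepted = filter_for_expansion(
        pool_ads, config.task, config.policy, experimental=labeled
    )
    if not accepted:
        message = "AD filter accepted zero molecules; falling back to plain MMPA"
        logger.warning(message)
        return MMPAByQSARResult(
            experimental=experimental_result,
            expanded=experimental_result,
            comparison=None,
            n_accepted=0,
            model=model,
            curve=curve,
            config=config,
            warnings=[message],
        )
    merged, _ = deduplicate(labeled + accepted, conflict_policy="mean")
    expanded_result = run_mmpa(merged, config)
    comparison = compare_rulesets(experimental_result.rules, expanded_result.rules)
    return MMPAByQSARResult(
        experimental=experimental_result,
        expanded=expanded_result,
        comparison=comparison,
        n_accepted=len(accepted),
        model=model,
        curve=curve,
        config=config,
    )


def write_outputs(result: MMPAResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rules_to_frame(result.rules).to_csv(out / "rules.csv", index=False)
    summary = {k: v for k, v in result.report.items() if not hasattr(v, "to_csv")}
    (out / "report.json").write_text(json.dumps(summary, indent=2))
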