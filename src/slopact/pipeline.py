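"""End-to-end experiment orchestration.

An experiment takes a cohort (generated synthetically or loaded from the
records CSV), optionally deduplicates it, extracts and normalises activity
epochs, computes one or more entropy features per epoch, and evaluates
every configured class pair: ROC-derived threshold, Se/Sp/Acc/MCC,
rank-sum p-value, and optionally the bootstrap leave-one-out accuracy.
Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .errors import ClassEmptyError, ParameterError, RecordRejectionError
from .evaluation import ScoredSample, evaluate_pair, loo_bootstrap
from .entropy import compute_entropy, normalize_entropies
from .preprocessing import Epoch, PreprocessConfig, preprocess_record
from .records import ActigraphyRecord, MoodState, STATE_ORDER, read_records_csv
from .synthetic import CohortSpec, GeneratorConfig, generate_cohort

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "deduplicate_cohort",
    "run_experiment",
    "length_sweep_experiment",
    "DEFAULT_PAIRS",
]

log = logging.getLogger("slopact")

DEFAULT_PAIRS: tuple[tuple[MoodState, MoodState], ...] = (
    (MoodState.DEP, MoodState.MAN),
    (MoodState.DEP, MoodState.REM),
    (MoodState.MAN, MoodState.REM),
)

DEDUP_POLICIES = ("none", "one_episode_per_subject_state", "require_multi_state")


def deduplicate_cohort(records: Sequence[ActigraphyRecord], policy: str,
                       exempt_state: MoodState = MoodState.MAN,
                       ) -> list[ActigraphyRecord]:
    """Confound-control filters over a cohort.

    ``one_episode_per_subject_state`` keeps at most one record per
    (subject, state), the first by input order.  ``require_multi_state``
    drops subjects observed in a single state only, except that records of
    ``exempt_state`` are always retained (that class is typically too
    small to thin further).
    """
    if policy not in DEDUP_POLICIES:
        raise ParameterError(f"unknown dedup policy {policy!r}")
    records = list(records)
    if policy == "none":
        return records
    if policy == "one_episode_per_subject_state":
        seen: set[tuple[str, MoodState]] = set()
        kept = []
        for rec in records:
            key = (rec.subject_id, rec.state)
            if key not in seen:
                seen.add(key)
                kept.append(rec)
        return kept
    # require_multi_state
    states_by_subject: dict[str, set[MoodState]] = {}
    for rec in records:
        states_by_subject.setdefault(rec.subject_id, set()).add(rec.state)
    return [rec for rec in records
            if rec.state == exempt_state
            or len(states_by_subject[rec.subject_id]) > 1]


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    cohort: CohortSpec | str | Path = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    methods: list[dict] = field(default_factory=lambda: [
        {"method": "slopen", "m": 6, "gamma": 0.94, "delta": 1e-3}])
    pairs: tuple[tuple[MoodState, MoodState], ...] = DEFAULT_PAIRS
    n_realisations: int = 1000
    alpha: float = 0.05
    run_loo: bool = False
    dedup_policy: str = "none"
    dedup_exempt_state: MoodState = MoodState.MAN
    seed: int = 0
    output_dir: str | Path | None = None

    def validate(self) -> None:
        if not self.methods:
            raise ParameterError("at least one entropy method is required")
        if not self.pairs:
            raise ParameterError("at least one class pair is required")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must lie in (0, 1)")
        if self.dedup_policy not in DEDUP_POLICIES:
            raise ParameterError(f"unknown dedup policy {self.dedup_policy!r}")
        self.preprocess.validate()
        if isinstance(self.cohort, CohortSpec):
            self.cohort.validate()

    # -- round-trip through the YAML config file ---------------------------
    def to_dict(self) -> dict:
        if isinstance(self.cohort, CohortSpec):
            cohort = {
                "counts": {s.value: int(self.cohort.counts.get(s, 0))
                           for s in STATE_ORDER},
                "episodes_per_subject": (
                    {s.value: self.cohort.episodes_for(s) for s in STATE_ORDER}
                    if isinstance(self.cohort.episodes_per_subject, dict)
                    else int(self.cohort.episodes_per_subject)),
                "configs": {s.value: vars(c).copy()
                            for s, c in self.cohort.configs.items()},
            }
        else:
            cohort = str(self.cohort)
        return {
            "cohort": cohort,
            "preprocess": vars(self.preprocess).copy(),
            "methods": [dict(m) for m in self.methods],
            "pairs": [[a.value, b.value] for a, b in self.pairs],
            "evaluation": {"n_realisations": int(self.n_realisations),
                           "alpha": float(self.alpha),
                           "run_loo": bool(self.run_loo)},
            "dedup_policy": self.dedup_policy,
            "dedup_exempt_state": self.dedup_exempt_state.value,
            "seed": int(self.seed),
            "output_dir": None if self.output_dir is None else str(self.output_dir),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        cohort = data.get("cohort", {})
        if isinstance(cohort, dict):
            eps = cohort.get("episodes_per_subject", 1)
            if isinstance(eps, dict):
                eps = {MoodState(k): int(v) for k, v in eps.items()}
            spec = CohortSpec(
                counts={MoodState(k): int(v)
                        for k, v in cohort.get("counts", {}).items()},
                configs={MoodState(k): GeneratorConfig(**v)
                         for k, v in cohort.get("configs", {}).items()},
                episodes_per_subject=eps,
            )
            if not spec.counts:
                spec = CohortSpec(configs=spec.configs, episodes_per_subject=eps)
        else:
            spec = cohort
        evaluation = data.get("evaluation", {})
        return cls(
            cohort=spec,
            preprocess=PreprocessConfig(**data.get("preprocess", {})),
            methods=[dict(m) for m in data.get("methods",
                     [{"method": "slopen", "m": 6, "gamma": 0.94, "delta": 1e-3}])],
            pairs=tuple((MoodState(a), MoodState(b))
                        for a, b in data.get("pairs",
                                             [[a.value, b.value] for a, b in DEFAULT_PAIRS])),
            n_realisations=int(evaluation.get("n_realisations", 1000)),
            alpha=float(evaluation.get("alpha", 0.05)),
            run_loo=bool(evaluation.get("run_loo", False)),
            dedup_policy=data.get("dedup_policy", "none"),
            dedup_exempt_state=MoodState(data.get("dedup_exempt_state", "man")),
            seed=int(data.get("seed", 0)),
            output_dir=data.get("output_dir"),
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ExperimentReport:
    """Results tables plus provenance of one experiment run."""

    results: pd.DataFrame
    class_summary: pd.DataFrame
    rejections: list[str]
    stage_counts: dict
    provenance: dict

    def write(self, output_dir) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "results.csv", index=False)
        self.class_summary.to_csv(out / "class_summary.csv", index=False)
        with open(out / "report.txt", "w") as fh:
            fh.write(self.render())

    def render(self) -> str:
        lines = ["slopact experiment report", "=" * 26, ""]
        lines.append("Provenance: " + ", ".join(
            f"{k}={v}" for k, v in sorted(self.provenance.items())))
        lines.append("Stage counts: " + ", ".join(
            f"{k}={v}" for k, v in self.stage_counts.items()))
        if self.rejections:
            lines.append(f"Rejections ({len(self.rejections)}):")
            lines += [f"  - {r}" for r in self.rejections]
        lines += ["", "Per-class entropy summaries (dataset-max normalised):",
                  self.class_summary.to_string(index=False), "",
                  "Classification results:", self.results.to_string(index=False), ""]
        return "\n".join(lines)


def _load_cohort(config: ExperimentConfig) -> list[ActigraphyRecord]:
    if isinstance(config.cohort, CohortSpec):
        return generate_cohort(config.cohort, seed=config.seed)
    return read_records_csv(config.cohort)


def _epochs_for(records: Sequence[ActigraphyRecord], pre: PreprocessConfig,
                rejections: list[str]) -> list[Epoch]:
    epochs: list[Epoch] = []
    for rec in records:
        try:
            epochs.extend(preprocess_record(rec, pre))
        except RecordRejectionError as err:
            rejections.append(str(err))
    return epochs


def _method_label(method_cfg: dict) -> str:
    params = {k: v for k, v in method_cfg.items() if k != "method"}
    inner = ",".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"{method_cfg['method']}({inner})"


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full pipeline for one configuration.

    Record-level rejections are collected and reported; the run only fails
    if a configured class ends up empty.
    """
    config.validate()
    records = _load_cohort(config)
    log.info("cohort: %d records", len(records))
    deduped = deduplicate_cohort(records, config.dedup_policy,
                                 config.dedup_exempt_state)
    log.info("after dedup (%s): %d records", config.dedup_policy, len(deduped))
    rejections: list[str] = []
    epochs = _epochs_for(deduped, config.preprocess, rejections)
    log.info("epochs extracted: %d (%d records rejected)", len(epochs), len(rejections))

    needed = {s for pair in config.pairs for s in pair}
    for state in needed:
        if not any(e.state == state for e in epochs):
            raise ClassEmptyError(f"class {state.value!r} has no usable epochs")

    result_rows, summary_rows = [], []
    for method_cfg in config.methods:
        method_cfg = dict(method_cfg)
        name = method_cfg.pop("method")
        label = _method_label({"method": name, **method_cfg})
        scored = [ScoredSample(e.source_id, e.state,
                               compute_entropy(e.values, name, **method_cfg).value)
                  for e in epochs]
        values = np.array([s.score for s in scored])
        norm = normalize_entropies(values)
        for state in STATE_ORDER:
            sel = np.array([s.state == state for s in scored])
            if sel.any():
                summary_rows.append({
                    "method": label, "state": state.value, "n": int(sel.sum()),
                    "mean_norm": float(norm[sel].mean()),
                    "sd_norm": float(norm[sel].std()),
                    "mean_raw": float(values[sel].mean()),
                    "sd_raw": float(values[sel].std()),
                })
        for pair in config.pairs:
            res = evaluate_pair(scored, pair)
            row = {
                "pair": f"{pair[0].value}-{pair[1].value}", "method": label,
                "se": res.se, "sp": res.sp, "acc": res.acc, "mcc": res.mcc,
                "p_value": res.p_value,
                "significant": bool(res.p_value < config.alpha),
                "threshold": res.threshold, "orientation": res.orientation,
                "n_a": res.n_per_class[0], "n_b": res.n_per_class[1],
            }
            if config.run_loo:
                mean_acc, sd_acc = loo_bootstrap(
                    scored, pair, n_realisations=config.n_realisations,
                    seed=config.seed)
                row["loo_mean_acc"] = mean_acc
                row["loo_sd_acc"] = sd_acc
            result_rows.append(row)
            log.info("%s %s: acc=%.3f p=%.4f", label, row["pair"], res.acc,
                     res.p_value)

    report = ExperimentReport(
        results=pd.DataFrame(result_rows),
        class_summary=pd.DataFrame(summary_rows),
        rejections=rejections,
        stage_counts={"records_in": len(records), "records_dedup": len(deduped),
                      "records_rejected": len(rejections), "epochs": len(epochs)},
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "version": __version__},
    )
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report


def length_sweep_experiment(config: ExperimentConfig,
                            lengths: Sequence[int]) -> ExperimentReport:
    """Re-run the experiment once per minimum epoch length.

    Each block uses the ``all_ge_min`` strategy with ``min_epoch_len`` set
    to the block's N, so the number of epochs processed shrinks as N
    grows and records without a long enough activity run drop out.
    """
    lengths = [int(n) for n in lengths]
    if not lengths or any(n <= 0 for n in lengths):
        raise ParameterError("lengths must be positive integers")
    if sorted(lengths) != lengths:
        raise ParameterError("lengths must be ascending")
    blocks_res, blocks_sum, rejections = [], [], []
    counts: dict = {}
    for n in lengths:
        block_cfg = replace(config,
                            preprocess=replace(config.preprocess,
                                               epoch_strategy="all_ge_min",
                                               min_epoch_len=n),
                            output_dir=None)
        try:
            rep = run_experiment(block_cfg)
        except ClassEmptyError as err:
            log.warning("length %d: %s; block skipped", n, err)
            counts[f"N={n}"] = 0
            continue
        rep.results.insert(0, "N", n)
        rep.class_summary.insert(0, "N", n)
        blocks_res.append(rep.results)
        blocks_sum.append(rep.class_summary)
        rejections += [f"N={n}: {r}" for r in rep.rejections]
        counts[f"N={n}"] = rep.stage_counts["epochs"]
    report = ExperimentReport(
        results=pd.concat(blocks_res, ignore_index=True) if blocks_res else pd.DataFrame(),
        class_summary=pd.concat(blocks_sum, ignore_index=True) if blocks_sum else pd.DataFrame(),
        rejections=rejections,
        stage_counts=counts,
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "version": __version__, "sweep": ",".join(map(str, lengths))},
    )
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report
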