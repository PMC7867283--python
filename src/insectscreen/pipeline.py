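"""End-to-end orchestration of the consensus screen.

Two entry points mirror the two halves of the workflow:

* :func:`run_qsar` — curate a labelled library, train the random-forest
  activity model on a stratified 80/20 partition, evaluate it on the test
  set and by pooled cross-validation, and fit the applicability domain.
* :func:`run_screen` — normalize docking tables into activity
  probabilities, fuse them with QSAR probabilities into the combined
  consensus probability, apply the strict > 0.5 selection, intersect
  selections across the required enzymes, and drop candidates with any
  predicted toxicity risk.

Every report embeds a hash of the configuration and a fingerprint of the
input data so that runs are auditable; identical config and inputs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import consensus as cons
from . import curation, docking, qsar, toxicity

ESP_MODES = ("test", "cross", "mean")


class PipelineError(ValueError):
    """Invalid pipeline configuration or missing inputs."""


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and thresholds for a full screening run."""

    library_csv: str | None = None
    descriptors_csv: str | None = None
    docking_csv: str | None = None
    toxicity_csv: str | None = None
    consensus_csv: str | None = None  # reported Prob_Comb values, used as-is
    required_enzymes: tuple[str, ...] = ()
    plc50_threshold: float = curation.DEFAULT_PLC50_THRESHOLD
    prob_comb_threshold: float = cons.PROB_COMB_THRESHOLD
    apd_z: float = qsar.DEFAULT_Z
    rf_trees: int = qsar.DEFAULT_N_TREES
    cv_folds: int = 10
    train_fraction: float = 0.8
    esp_mode: str = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.esp_mode not in ESP_MODES:
            raise PipelineError(f"esp_mode must be one of {ESP_MODES}, got {self.esp_mode!r}")
        if self.cv_folds < 2:
            raise PipelineError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if not 0.0 < self.prob_comb_threshold < 1.0:
            raise PipelineError("prob_comb_threshold must lie in (0, 1)")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise PipelineError(f"configuration is missing the {what} input")
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"{what} input does not exist: {p}")
    return p


def library_fingerprint(labeled: Sequence[curation.LabeledCompound]) -> str:
    payload = json.dumps(
        [(lc.record.compound_id, lc.record.plc50, lc.label.value) for lc in labeled]
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class QsarRunResult:
    """Trained model plus its evaluation reports and domain."""

    model: qsar.ClassifierModel
    test_report: qsar.PerformanceReport
    cross_report: qsar.PerformanceReport
    domain: qsar.DomainModel
    config_hash: str
    fingerprint: str

    def esp(self, mode: str = "mean") -> float:
        """The specificity statistic used as the consensus fusion weight."""
        if mode == "test":
            return self.test_report.specificity
        if mode == "cross":
            return self.cross_report.specificity
        if mode == "mean":
            return 0.5 * (self.test_report.specificity + self.cross_report.specificity)
        raise PipelineError(f"unknown esp mode {mode!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "library_fingerprint": self.fingerprint,
                "n_trees": self.model.n_trees,
                "seed": self.model.seed,
                "apd_threshold": round(self.domain.apd_threshold, 6),
                "test": json.loads(self.test_report.to_json()),
                "cross": json.loads(self.cross_report.to_json()),
            },
            indent=2,
            sort_keys=True,
        )


def run_qsar(config: PipelineConfig, out_dir: str | Path | None = None) -> QsarRunResult:
    """Train and evaluate the QSAR model from configured inputs."""
    library_path = _require(config.library_csv, "compound library")
    descriptors_path = _require(config.descriptors_csv, "descriptor matrix")
    records = curation.read_library_csv(library_path.read_text())
    labeled = curation.label_activity(records, config.plc50_threshold)
    matrix = qsar.read_descriptor_matrix(descriptors_path.read_text())
    result = fit_and_evaluate(labeled, matrix, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "qsar_report.json").write_text(result.to_json() + "\n")
    return result


def fit_and_evaluate(
    labeled: Sequence[curation.LabeledCompound],
    matrix: qsar.DescriptorMatrix,
    config: PipelineConfig,
) -> QsarRunResult:
    """In-memory QSAR stage: split, train, test-evaluate, cross-validate."""
    ids = [lc.record.compound_id for lc in labeled]
    matrix = matrix.subset(ids)
    train, test = qsar.stratified_split(
        labeled, qsar.SplitSpec(train_fraction=config.train_fraction, seed=config.seed)
    )
    train_matrix = matrix.subset([lc.record.compound_id for lc in train])
    test_matrix = matrix.subset([lc.record.compound_id for lc in test])
    model = qsar.train_forest(
        train_matrix, [lc.label for lc in train], n_trees=config.rf_trees, seed=config.seed
    )
    test_report = qsar.evaluate(model, test_matrix.drop_columns(
        [c for c in test_matrix.descriptor_names if c not in model.descriptor_names]
    ), [lc.label for lc in test])
    cross_report = qsar.cross_validate(
        labeled, matrix, k=config.cv_folds, seed=config.seed, n_trees=config.rf_trees
    )
    domain = qsar.fit_apd(train_matrix, z=config.apd_z)
    return QsarRunResult(
        model=model,
        test_report=test_report,
        cross_report=cross_report,
        domain=domain,
        config_hash=config.config_hash(),
        fingerprint=library_fingerprint(labeled),
    )


@dataclass
class ScreenReport:
    """Consensus tables, multi-target hits, and the risk-free final list."""

    results: list[cons.ConsensusResult]
    multitarget: list[cons.MultiTargetHit]
    risk_free: list[cons.MultiTargetHit]
    required_enzymes: tuple[str, ...]
    config_hash: str = ""
    fingerprint: str = ""

    @property
    def final_compound_ids(self) -> list[str]:
        return [h.compound_id for h in self.risk_free]

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "input_fingerprint": self.fingerprint,
                "required_enzymes": list(self.required_enzymes),
                "n_consensus_results": len(self.results),
                "multitarget": json.loads(cons.hits_to_json(self.multitarget)),
                "risk_free": json.loads(cons.hits_to_json(self.risk_free)),
            },
            indent=2,
            sort_keys=True,
        )


def screen_library(
    tables: Mapping[str, docking.DockingScoreTable],
    p_activity: Mapping[str, float],
    esp: float,
    required_enzymes: Sequence[str],
    profiles: Sequence[toxicity.ToxicityProfile] | None = None,
    prob_comb_threshold: float = cons.PROB_COMB_THRESHOLD,
) -> ScreenReport:
    """Core screen: docking calls -> consensus fusion -> selection ->
    multi-target intersection -> toxicity filter.

    ``profiles`` may be omitted (no toxicity information), in which case
    the risk-free list equals the multi-target list.
    """
    required = tuple(required_enzymes)
    missing = [e for e in required if e not in tables]
    if missing:
        raise PipelineError(f"no docking table for required enzyme(s): {missing}")
    results: list[cons.ConsensusResult] = []
    for enzyme, table in tables.items():
        if not table.ligand_scores:  # an empty screen yields no calls
            continue
        calls = docking.call_actives(table)
        results.extend(cons.consensus_results(calls, p_activity, esp))
    selected = [r for r in results if r.prob_comb > prob_comb_threshold]
    hits = cons.intersect_targets(cons.MultiTargetTable.from_results(selected), required)
    risk_free = _apply_toxicity(hits, profiles)
    return ScreenReport(
        results=results,
        multitarget=hits,
        risk_free=risk_free,
        required_enzymes=required,
    )


def screen_with_reported_consensus(
    tables: Mapping[str, docking.DockingScoreTable],
    consensus_df: pd.DataFrame,
    required_enzymes: Sequence[str],
    profiles: Sequence[toxicity.ToxicityProfile] | None = None,
    prob_comb_threshold: float = cons.PROB_COMB_THRESHOLD,
) -> ScreenReport:
    """Screen with externally reported combined probabilities.

    The docking activity condition (energy strictly below the reference
    inhibitor's) is recomputed from the tables; the combined probability is
    taken from ``consensus_df`` (columns compound_id, enzyme_id, prob_comb,
    optional p_activity) rather than recomputed — the normal path when the
    consensus was produced against a larger screening bank than the table
    subset at hand.
    """
    required = tuple(required_enzymes)
    missing = [e for e in required if e not in tables]
    if missing:
        raise PipelineError(f"no docking table for required enzyme(s): {missing}")
    needed = {"compound_id", "enzyme_id", "prob_comb"}
    if not needed <= set(consensus_df.columns):
        raise PipelineError(f"consensus table needs columns {sorted(needed)}")
    active: dict[tuple[str, str], float] = {}
    for enzyme, table in tables.items():
        if not table.ligand_scores:
            continue
        for call in docking.call_actives(table):
            if call.is_potentially_active:
                active[(call.compound_id, enzyme)] = call.prob_dc
    results: list[cons.ConsensusResult] = []
    for row in consensus_df.itertuples(index=False):
        key = (str(row.compound_id), str(row.enzyme_id))
        prob_dc = active.get(key, 0.0)
        pa = float(getattr(row, "p_activity", float("nan")))
        results.append(
            cons.ConsensusResult(
                compound_id=key[0],
                enzyme_id=key[1],
                prob_dc=prob_dc,
                p_activity=pa,
                esp=float("nan"),
                prob_comb=float(row.prob_comb),
            )
        )
    selected = [
        r
        for r in results
        if r.prob_comb > prob_comb_threshold
        and (r.compound_id, r.enzyme_id) in active
    ]
    hits = cons.intersect_targets(cons.MultiTargetTable.from_results(selected), required)
    risk_free = _apply_toxicity(hits, profiles)
    return ScreenReport(
        results=results,
        multitarget=hits,
        risk_free=risk_free,
        required_enzymes=required,
    )


def _apply_toxicity(
    hits: Sequence[cons.MultiTargetHit],
    profiles: Sequence[toxicity.ToxicityProfile] | None,
) -> list[cons.MultiTargetHit]:
    if profiles is None:
        return list(hits)
    clean = {p.compound_id for p in toxicity.filter_risk_free(profiles)}
    return [h for h in hits if h.compound_id in clean]


def run_screen(config: PipelineConfig, out_dir: str | Path | None = None) -> ScreenReport:
    """File-based screen from configured inputs.

    Requires a docking CSV and a reported-consensus CSV (the file-level
    route into the screen); toxicity input is optional. The in-memory
    :func:`screen_library` is the route when a trained model supplies the
    QSAR probabilities directly.
    """
    docking_path = _require(config.docking_csv, "docking table")
    consensus_path = _require(config.consensus_csv, "consensus table")
    tables = docking.read_docking_tables(docking_path.read_text())
    consensus_df = pd.read_csv(consensus_path, dtype={"compound_id": str})
    profiles = None
    if config.toxicity_csv is not None:
        profiles = toxicity.read_toxicity_table(
            _require(config.toxicity_csv, "toxicity table").read_text()
        )
    required = config.required_enzymes or tuple(tables)
    report = screen_with_reported_consensus(
        tables,
        consensus_df,
        required,
        profiles,
        prob_comb_threshold=config.prob_comb_threshold,
    )
    report.config_hash = config.config_hash()
    report.fingerprint = hashlib.sha256(
        docking_path.read_bytes() + consensus_path.read_bytes()
    ).hexdigest()[:16]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cons.results_to_frame(report.results).to_csv(out / "consensus.csv", index=False)
        (out / "screen_report.json").write_text(report.to_json() + "\n")
        pd.DataFrame({"compound_id": report.final_compound_ids}).to_csv(
            out / "final_candidates.csv", index=False
        )
    return report


__all__ = [
    "ESP_MODES",
    "PipelineConfig",
    "PipelineError",
    "QsarRunResult",
    "ScreenReport",
    "fit_and_evaluate",
    "library_fingerprint",
    "run_qsar",
    "run_screen",
    "screen_library",
    "screen_with_reported_consensus",
]
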