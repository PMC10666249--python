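"""End-to-end orchestration: curation -> EDA -> scaffolds -> SALI -> QSAR -> AD.

Each stage reads its inputs from the run directory and writes its
artifacts back there, so stages can be re-run individually from cached
intermediates; :func:`run_all` chains them and records a manifest with
file digests, stage timings and the seed. All randomness flows from the
single configured seed, so two runs with the same config produce
digest-identical artifact bundles (timings live only in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .applicability import ADModel, fit_ad, in_domain
from .curation import clean_records, read_activity_export, read_curated, write_curated
from .descriptors import (
    SmilesParseError,
    descriptor_matrix,
    fragment_fingerprint,
    physchem_table,
)
from .eda import describe_by_class, mann_whitney_u, pca
from .qsar import QSARModel
from .sali import build_network, detect_cliffs, export_network, sali_matrix
from .scaffolds import (
    diversity_frame,
    diversity_report,
    scaffold_activity_landscape,
    scaffold_frequencies,
    scaffold_records,
    select_prevalent_subset,
    write_whitelist,
)
from .synthetic import emulate_study_shape, write_activity_export

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "sarscape_run"
    input_csv: str | None = None     # ChEMBL-style export; None -> simulate
    simulate: bool = True
    seed: int = 42
    # scaffolds
    min_scaffold_freq: int = 10
    prevalent_subset_only: bool = False  # model only the prevalent-scaffold subset
    # sali
    sim_floor: float = 0.8
    cliff_mode: str = "top_fraction"
    cliff_param: float = 0.01
    # qsar
    run_qsar: bool = True
    algorithms: list[str] = field(default_factory=lambda: ["extra_trees", "lightgbm"])
    split_ratio: float = 0.8
    balance_mode: str = "balance_then_split"
    cv_folds: int = 10
    n_estimators: int = 100
    variance_threshold: float = 0.1
    correlation_threshold: float = 0.95
    # applicability domain
    ad_components: int = 2
    ad_scaffold_gate: bool = False

    @classmethod
    def full_549(cls, out_dir: str = "sarscape_run", seed: int = 42) -> "PipelineConfig":
        """All compounds, 80:20 split, PCA-box AD."""
        return cls(out_dir=out_dir, seed=seed, split_ratio=0.8, ad_scaffold_gate=False)

    @classmethod
    def subset_168(cls, out_dir: str = "sarscape_run", seed: int = 42) -> "PipelineConfig":
        """Prevalent-scaffold subset, 75:25 split, scaffold + box AD."""
        return cls(
            out_dir=out_dir,
            seed=seed,
            prevalent_subset_only=True,
            split_ratio=0.75,
            ad_scaffold_gate=True,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class RunManifest:
    seed: int
    version: str
    config: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "version": self.version,
                    "config": self.config,
                    "stage_seconds": self.stage_seconds,
                    "digests": self.digests,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# stages (each reads/writes the run directory)

def stage_simulate(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    records, truth = emulate_study_shape(seed=cfg.seed)
    write_activity_export(records, out / "activity_export.csv")
    truth.to_csv(out / "ground_truth.csv", index=False)


def stage_curate(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    source = cfg.input_csv if cfg.input_csv else out / "activity_export.csv"
    records = read_activity_export(source)
    curated = clean_records(records)
    logger.info("curation: %d raw -> %d curated", len(records), len(curated))
    write_curated(curated, out / "curated.csv")


def stage_eda(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    curated = read_curated(out / "curated.csv")
    table = physchem_table(
        [c.canonical_smiles for c in curated], [c.record_id for c in curated]
    )
    labels = pd.Series([c.bioclass.value for c in curated], index=table.index)
    describe_by_class(table, labels).to_csv(out / "eda_stats.csv", index=False)
    tests = []
    act = table[labels == "active"]
    ina = table[labels == "inactive"]
    for col in table.columns:
        u, p = mann_whitney_u(act[col], ina[col])
        tests.append({"descriptor": col, "u": u, "p_two_sided": p})
    pd.DataFrame(tests).to_csv(out / "eda_utests.csv", index=False)
    res = pca(table, n_components=3)
    loadings = res.loadings.T.copy()
    loadings.loc["cumulated_variance_pct"] = res.cumulative_variance_pct
    loadings.to_csv(out / "pca_loadings.csv")
    res.scores.round(6).to_csv(out / "pca_scores.csv")


def stage_scaffolds(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    curated = read_curated(out / "curated.csv")
    records = scaffold_records(curated)
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "murcko": [r.murcko_smiles for r in records],
            "skeleton": [r.skeleton_smiles for r in records],
        }
    ).to_csv(out / "scaffold_table.csv", index=False)
    diversity_frame(diversity_report(curated, records)).to_csv(
        out / "scaffold_diversity.csv", index=False
    )
    ranked, acyclic = scaffold_frequencies(records)
    pd.DataFrame(ranked, columns=["scaffold", "count"]).to_csv(
        out / "scaffold_frequencies.csv", index=False
    )
    scaffold_activity_landscape(curated, records).to_csv(
        out / "scaffold_landscape.csv", index=False
    )
    _, whitelist = select_prevalent_subset(curated, records, cfg.min_scaffold_freq)
    write_whitelist(whitelist, out / "scaffold_whitelist.smi")


def stage_sali(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    curated = read_curated(out / "curated.csv")
    fps = {c.record_id: fragment_fingerprint(c.canonical_smiles) for c in curated}
    edges = sali_matrix(curated, fps, sim_floor=cfg.sim_floor)
    if edges:
        edges = detect_cliffs(edges, mode=cfg.cliff_mode, param=cfg.cliff_param)
    scaffolds = scaffold_records(curated)
    ranked, _ = scaffold_frequencies(scaffolds)
    counts = dict(ranked)
    freq = {
        r.compound_id: counts.get(r.murcko_smiles, 0) for r in scaffolds
    }
    network = build_network(curated, edges, scaffold_freq=freq)
    export_network(network, out / "sali_network.graphml", fmt="graphml")
    export_network(network, out / "sali_edges.csv", fmt="edgelist")


def stage_qsar(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    curated = read_curated(out / "curated.csv")
    whitelist: list[str] = []
    if cfg.prevalent_subset_only:
        curated, whitelist = select_prevalent_subset(curated, min_freq=cfg.min_scaffold_freq)
    matrix = descriptor_matrix(
        [c.canonical_smiles for c in curated], [c.record_id for c in curated]
    )
    labels = np.array([c.bioclass.value for c in curated])
    model = QSARModel(
        matrix=matrix,
        labels=labels,
        variance_threshold=cfg.variance_threshold,
        correlation_threshold=cfg.correlation_threshold,
        split_ratio=cfg.split_ratio,
        balance_mode=cfg.balance_mode,
        cv_folds=cfg.cv_folds,
        seed=cfg.seed,
        n_estimators=cfg.n_estimators,
    )
    results = model.fit(algorithms=cfg.algorithms)
    results.summary().round(6).to_csv(out / "validation_summary.csv", index=False)
    (out / "validation_reports.json").write_text(
        json.dumps(
            {a: json.loads(r.to_json()) for a, r in results.reports.items()},
            indent=2,
            sort_keys=True,
        )
    )
    retained = results.filter_trace.retained
    (out / "filter_trace.json").write_text(
        json.dumps(
            {
                "dropped_low_variance": results.filter_trace.dropped_low_variance,
                "dropped_correlated": results.filter_trace.dropped_correlated,
                "retained": retained,
            },
            indent=2,
            sort_keys=True,
        )
    )
    # applicability domain on the filtered training features
    if not cfg.prevalent_subset_only:
        _, whitelist = select_prevalent_subset(curated, min_freq=cfg.min_scaffold_freq)
    ad = fit_ad(
        matrix[retained],
        scaffold_whitelist=set(whitelist),
        n_components=cfg.ad_components,
        use_scaffold_gate=cfg.ad_scaffold_gate,
    )
    ad.to_json(out / "ad_model.json")
    best = max(results.reports, key=lambda a: results.reports[a].cv["mcc"])
    joblib.dump(
        {"classifier": results.models[best], "retained": retained, "best": best},
        out / "model.joblib",
    )


_STAGES = {
    "simulate": stage_simulate,
    "curate": stage_curate,
    "eda": stage_eda,
    "scaffolds": stage_scaffolds,
    "sali": stage_sali,
    "qsar": stage_qsar,
}


def run_all(cfg: PipelineConfig) -> RunManifest:
    """Execute all configured stages in order and write the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=cfg.seed, version=__version__, config=asdict(cfg))
    stages = [s for s in _STAGES if (s != "simulate" or cfg.simulate) and (s != "qsar" or cfg.run_qsar)]
    for name in stages:
        t0 = time.perf_counter()
        try:
            _STAGES[name](cfg)
        except Exception as exc:
            raise StageError(name, exc) from exc
        manifest.stage_seconds[name] = time.perf_counter() - t0
    for path in sorted(out.iterdir()):
        if path.is_file() and path.name not in ("run_manifest.json", "model.joblib"):
            manifest.digests[path.name] = _digest(path)
    manifest.write(out / "run_manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# prediction with AD gating

ABSTAIN = "ABSTAIN"


def predict(bundle_dir: str | Path, query_smiles: list[str]) -> pd.DataFrame:
    """Per-query AD verdict and predicted class (ABSTAIN when out of domain).

    Queries pass through the identical preprocessing chain used in
    training: descriptors -> stored retained features -> model. Invalid
    SMILES yield a per-row error entry without stopping the run.
    """
    bundle_dir = Path(bundle_dir)
    ad = ADModel.from_json(bundle_dir / "ad_model.json")
    saved = joblib.load(bundle_dir / "model.joblib")
    clf, retained = saved["classifier"], saved["retained"]
    rows = []
    for smiles in query_smiles:
        try:
            feats = descriptor_matrix([smiles])[retained]
        except (SmilesParseError, KeyError) as exc:
            rows.append(
                {"smiles": smiles, "in_domain": False, "prediction": ABSTAIN,
                 "reasons": f"error:{exc}"}
            )
            continue
        ok, reasons = in_domain(ad, smiles, feats[ad.feature_names])
        if not ok:
            rows.append(
                {"smiles": smiles, "in_domain": False, "prediction": ABSTAIN,
                 "reasons": ";".join(reasons)}
            )
        else:
            pred = clf.predict(feats[clf.feature_names])[0]
            rows.append({"smiles": smiles, "in_domain": True, "prediction": pred, "reasons": ""})
    return pd.DataFrame(rows, columns=["smiles", "in_domain", "prediction", "reasons"])
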