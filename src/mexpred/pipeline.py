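"""End-to-end orchestration: filter -> extract -> align -> train -> predict.

:func:`run_pipeline` wires the modules together with a single config
object, writes every artifact (feature tables, cross-validation report,
prediction table, projection and catalog archives) plus a manifest that
echoes all effective settings, library versions and input checksums, so
a run can be reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import DataError, read_microexons, read_microindels
from .features import (
    ArrayConservationTrack,
    Preprocessor,
    extract_feature_table,
    read_feature_table,
    read_residue_annotations,
    read_residue_mappings,
    write_feature_table,
)
from .model import (
    DEFAULT_K,
    DEFAULT_SEED,
    DEFAULT_THRESHOLD,
    ReferenceCatalog,
    SVMConfig,
    cross_validate,
    predict_target,
    predictions_to_frame,
    train_classifier,
)
from .synthetic import ShiftScenario, generate_domains
from .tca import DEFAULT_M, DEFAULT_MU, KernelSpec, fit_tca

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; echoed into the manifest."""

    out_dir: Path
    # either pre-computed feature tables ...
    source_features: Path | None = None
    target_features: Path | None = None
    # ... or raw records plus providers for the extraction stage
    source_records: Path | None = None
    source_mappings: Path | None = None
    target_records: Path | None = None
    target_mappings: Path | None = None
    residue_annotations: Path | None = None
    conservation_track: Path | None = None
    require_conservation: bool = False
    # ... or a fully synthetic scenario
    synthetic: bool = False
    scenario: ShiftScenario = field(default_factory=ShiftScenario)
    # knobs
    n_window: int = 2
    kernel: str = "linear"
    gamma: float | None = None
    m: int = DEFAULT_M
    mu: float = DEFAULT_MU
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    threshold: float = DEFAULT_THRESHOLD
    k: int = DEFAULT_K
    n_folds: int = 10
    seed: int = DEFAULT_SEED

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, Path):
                out[key] = str(value)
        scenario = out["scenario"]
        for key, value in list(scenario.items()):
            if isinstance(value, np.ndarray):
                scenario[key] = value.tolist()
        return out


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with path.open("rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _extract_stage(config: RunConfig, which: str, cache_dir: Path):
    """Extract features for one domain, cached by input checksums."""
    records_path = getattr(config, f"{which}_records")
    mappings_path = getattr(config, f"{which}_mappings")
    inputs = [records_path, mappings_path, config.residue_annotations]
    if config.conservation_track is not None:
        inputs.append(config.conservation_track)
    elif config.require_conservation:
        raise PipelineError("extract", "conservation track required but not provided")
    key_material = "|".join(
        f"{p.name}:{_sha256(p)}" for p in inputs if p is not None
    ) + f"|n_window={config.n_window}|{which}"
    cache_key = hashlib.sha256(key_material.encode()).hexdigest()[:16]
    cached = cache_dir / f"features_{which}_{cache_key}.tsv"
    if cached.exists():
        logger.info("extract[%s]: cache hit %s", which, cached.name)
        return read_feature_table(cached, domain_tag=which)

    if which == "source":
        records = read_microindels(records_path, label="unknown")
    else:
        records = read_microexons(records_path)
    mappings = read_residue_mappings(mappings_path)
    if len(mappings) != len(records):
        raise PipelineError(
            "extract", f"{which}: {len(records)} records but {len(mappings)} mappings"
        )
    proteins = read_residue_annotations(config.residue_annotations)
    if config.conservation_track is not None:
        provider = ArrayConservationTrack.from_tsv(config.conservation_track)
    else:
        from .features import ConstantConservation

        provider = ConstantConservation(float("nan"))
    table = extract_feature_table(records, mappings, proteins, provider, config.n_window)
    labels = None
    if which == "source":
        labels = np.array(
            [1 if r.label == "functional" else 0 for r in records], dtype=int
        )
    cache_dir.mkdir(parents=True, exist_ok=True)
    write_feature_table(table, cached, labels)
    return read_feature_table(cached, domain_tag=which)


def _load_domains(config: RunConfig, cache_dir: Path):
    if config.synthetic:
        source, target, hidden = generate_domains(config.scenario)
        return source, target, hidden
    if config.source_features and config.target_features:
        source = read_feature_table(config.source_features, domain_tag="source")
        target = read_feature_table(config.target_features, domain_tag="target")
        return source, target, None
    if config.source_records and config.target_records:
        source = _extract_stage(config, "source", cache_dir)
        target = _extract_stage(config, "target", cache_dir)
        return source, target, None
    raise PipelineError(
        "inputs",
        "provide feature tables, raw records with providers, or --synthetic",
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full prediction pipeline; returns a result summary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache_dir = out_dir / "cache"

    stage = "inputs"
    try:
        source, target, hidden_labels = _load_domains(config, cache_dir)
        if source.labels is None:
            raise DataError("source domain must carry labels")

        stage = "preprocess"
        preprocessor = Preprocessor()
        source_std = preprocessor.fit_transform(source.matrix)
        target_std = preprocessor.transform(target.matrix)

        stage = "tca"
        spec = KernelSpec(config.kernel, config.gamma)
        projection = fit_tca(
            source_std.to_numpy(), target_std.to_numpy(), spec, config.m, config.mu
        )
        projection.save(out_dir / "tca_projection.joblib")

        stage = "evaluate"
        svm_config = SVMConfig(kernel=config.svm_kernel, C=config.svm_C)
        report = cross_validate(
            projection.source_embedding,
            source.labels,
            n_folds=config.n_folds,
            seed=config.seed,
            config=svm_config,
        )
        (out_dir / "cv_report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n"
        )

        stage = "train"
        model = train_classifier(
            projection.source_embedding, source.labels, svm_config, config.seed
        )

        stage = "predict"
        record_ids = [str(i) for i in target.matrix.index]
        predictions = predict_target(
            model, projection.target_embedding, config.threshold, record_ids
        )
        table = predictions_to_frame(predictions)
        table.to_csv(out_dir / "predictions.tsv", sep="\t", index=False)

        stage = "catalog"
        catalog = ReferenceCatalog(
            features=target_std.to_numpy(),
            probabilities=table["probability"].to_numpy(),
            record_ids=record_ids,
        )
        catalog.save(out_dir / "reference_catalog.joblib")
    except (DataError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    n_functional = int((table["label"] == "functional").sum())
    summary = {
        "n_source": len(source),
        "n_target": len(target),
        "m": projection.m,
        "cv": report.to_dict(),
        "n_functional": n_functional,
        "functional_fraction": n_functional / len(table),
    }
    if hidden_labels is not None:
        predicted = (table["label"] == "functional").to_numpy().astype(int)
        summary["target_accuracy"] = float((predicted == hidden_labels).mean())

    import sklearn
    import scipy

    manifest = {
        "package": {"name": "mexpred", "version": __version__},
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "config": config.to_dict(),
        "inputs": {
            str(p): _sha256(Path(p))
            for p in (
                config.source_features, config.target_features,
                config.source_records, config.target_records,
                config.residue_annotations, config.conservation_track,
            )
            if p is not None
        },
        "summary": summary,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return summary
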