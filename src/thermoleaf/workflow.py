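"""End-to-end orchestration: frames → masks → features → screening →
classification → reports.

Every stochastic stage derives its seed deterministically from the single
global seed, so a rerun with the same configuration is bit-identical for all
deterministic outputs (feature table, screen results, reports).

Segmentation and feature extraction never see treatment labels; labels enter
only at the screening and classification stages.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, features, io, leafmask, screen, synthetic

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "extract_feature_table", "run_pipeline",
           "simulate_to_dir"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one full pipeline run."""

    input_dir: Path | None = None
    manifest: Path | None = None
    output_dir: Path = Path("thermoleaf_run")
    segmentation: leafmask.SegmentationConfig = leafmask.SegmentationConfig()
    alpha: float = 0.05
    train_fraction: float = 0.75
    search_iterations: int = 25
    cv_folds: int = 10
    seed: int = 0
    strict: bool = False

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        tag = zlib.crc32(stage.encode()) % (2**31 - 1)
        ss = np.random.SeedSequence([self.seed, tag])
        return int(ss.generate_state(1)[0] % (2**31 - 1))


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML or JSON file.

    Top-level keys mirror RunConfig fields; a nested ``segmentation`` mapping
    mirrors :class:`~thermoleaf.leafmask.SegmentationConfig`. Keyword
    overrides win over file values.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text) or {}
    else:
        data = json.loads(text)
    seg = leafmask.SegmentationConfig(**data.pop("segmentation", {}))
    for key in ("input_dir", "manifest", "output_dir"):
        if key in data and data[key] is not None:
            data[key] = Path(data[key])
    data.update(overrides)
    return RunConfig(segmentation=seg, **data)


def extract_feature_table(
    samples: list[tuple[io.ThermalFrame, np.ndarray | None]],
    seg_config: leafmask.SegmentationConfig = leafmask.SegmentationConfig(),
    strict: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Segment (where no mask is given) and extract features for each frame.

    Returns the feature table and the ids of frames that failed segmentation
    or the pixel floor; failures are skipped unless ``strict``.
    """
    rows = []
    failures = []
    for frame, mask in samples:
        try:
            if mask is None:
                mask = leafmask.segment_leaf(frame, seg_config)
            fv = features.extract_features(frame, mask)
            rows.append((frame, fv))
        except (leafmask.SegmentationError, features.InsufficientDataError) as exc:
            if strict:
                raise RuntimeError(f"sample {frame.sample_id}: {exc}") from exc
            log.warning("skipping %s: %s", frame.sample_id, exc)
            failures.append(frame.sample_id)
    return features.features_to_frame(rows), failures


def _load_samples(config: RunConfig) -> list[tuple[io.ThermalFrame, None]]:
    if config.manifest is None:
        raise ValueError("run_pipeline needs a manifest (or pass samples directly)")
    manifest = io.load_manifest(config.manifest)
    base = Path(config.input_dir) if config.input_dir else Path(config.manifest).parent
    out = []
    for row in manifest:
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        frame = io.parse_thermal_csv(
            p,
            sample_id=row.sample_id,
            metadata={
                "genotype": row.genotype,
                "treatment": row.treatment,
                "timepoint": row.timepoint,
                "drought_stage": row.drought_stage,
            },
        )
        out.append((frame, None))
    return out


@dataclass
class RunResult:
    feature_table: pd.DataFrame
    screen_results: list
    kept: list[str]
    report_rf: classify.EvalReport
    report_mlp: classify.EvalReport
    comparison: dict
    failures: list[str]
    output_dir: Path | None = None


def classify_feature_table(
    table: pd.DataFrame,
    kept: list[str],
    train_fraction: float = 0.75,
    cv_folds: int = 10,
    search_iterations: int = 25,
    seed: int = 0,
    search_space: dict | None = None,
) -> tuple[classify.EvalReport, classify.EvalReport, dict]:
    """Train and validate both pipelines on the screened feature columns."""
    y = table["treatment"].to_numpy()
    X = table[kept]
    t_idx, v_idx = classify.split_dataset(
        y, classify.SplitSpec(train_fraction=train_fraction, seed=seed)
    )
    reports = {}
    for model in ("rf", "mlp"):
        cfg = classify.PipelineConfig(
            model=model,
            cv_folds=cv_folds,
            search_iterations=search_iterations,
            seed=seed,
            search_space=search_space,
        )
        result = classify.tune_and_train(X.iloc[t_idx], y[t_idx], cfg)
        reports[model] = classify.evaluate(
            result, X.iloc[v_idx], y[v_idx], model=model
        )
    comparison = classify.compare_models(reports["rf"], reports["mlp"])
    return reports["rf"], reports["mlp"], comparison


def run_pipeline(
    config: RunConfig,
    samples: list[tuple[io.ThermalFrame, np.ndarray | None]] | None = None,
) -> RunResult:
    """Run the full pipeline and (if ``output_dir`` is set) write all
    artifacts: feature table, screen results, reports, comparison, resolved
    config.

    ``samples`` may be passed directly (e.g. synthetic scenes); otherwise
    frames are loaded via the manifest in ``config``.
    """
    if samples is None:
        samples = _load_samples(config)
    table, failures = extract_feature_table(
        samples, config.segmentation, strict=config.strict
    )
    results = screen.screen_features(table, alpha=config.alpha)
    kept = screen.kept_features(results)
    if not kept:
        raise RuntimeError("screening kept no features; nothing to classify")
    report_rf, report_mlp, comparison = classify_feature_table(
        table,
        kept,
        train_fraction=config.train_fraction,
        cv_folds=config.cv_folds,
        search_iterations=config.search_iterations,
        seed=config.stage_seed("classify"),
    )
    out = RunResult(
        feature_table=table,
        screen_results=results,
        kept=kept,
        report_rf=report_rf,
        report_mlp=report_mlp,
        comparison=comparison,
        failures=failures,
    )
    if config.output_dir is not None:
        out.output_dir = _write_artifacts(config, out)
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_artifacts(config: RunConfig, result: RunResult) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.feature_table.to_csv(out / "feature_table.csv", index=False)
    screen.screen_to_frame(result.screen_results).to_csv(
        out / "screen_results.csv", index=False
    )
    for name, report in (("rf", result.report_rf), ("mlp", result.report_mlp)):
        (out / f"report_{name}.txt").write_text(report.to_text() + "\n")
        pd.DataFrame(
            report.confusion, index=classify.CLASS_ORDER, columns=classify.CLASS_ORDER
        ).to_csv(out / f"confusion_{name}.csv")
    (out / "comparison.json").write_text(
        json.dumps(result.comparison, indent=2, default=_json_default) + "\n"
    )
    cfg = asdict(config)
    cfg["segmentation"] = asdict(config.segmentation)
    (out / "config.json").write_text(
        json.dumps(cfg, indent=2, default=_json_default) + "\n"
    )
    if result.failures:
        (out / "failures.txt").write_text("\n".join(result.failures) + "\n")
    return out


def simulate_to_dir(
    out_dir: str | Path,
    n_per_class: int,
    dd_offset: float = synthetic.DEFAULT_DD_OFFSET,
    seed: int = 0,
    spec: synthetic.LeafSceneSpec = synthetic.LeafSceneSpec(),
) -> Path:
    """Write a synthetic cohort as thermal CSVs + manifest + truth masks.

    Masks are written as 0/255 single-channel PNGs next to the CSVs.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.generate_cohort(n_per_class, spec, dd_offset, seed)
    records = []
    for sample in cohort:
        sid = sample.frame.sample_id
        io.write_thermal_csv(sample.frame, out_dir / f"{sid}.csv")
        iio.imwrite(
            out_dir / f"{sid}_truth.png",
            (sample.truth_mask * 255).astype(np.uint8),
        )
        records.append(
            {
                "sample_id": sid,
                "path": f"{sid}.csv",
                "genotype": "synthetic",
                "treatment": sample.treatment,
                "timepoint": "unknown",
                "drought_stage": "unknown",
                "replicate": "1",
            }
        )
    pd.DataFrame(records).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir
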