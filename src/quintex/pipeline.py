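"""End-to-end orchestration: preprocess -> encode -> features -> select -> SVM.

A :class:`RunConfig` bundles every stage's parameters and round-trips through
flat YAML/JSON.  :func:`run_pipeline` executes the stages on an in-memory
dataset (as produced by :func:`quintex.synthdata.make_dataset` or loaded via
:func:`quintex.io.load_directory`) and returns the evaluation report along
with the feature table and selection ranking.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import featselect, histfeat, kspatial, preprocess
from .classify import ExperimentPlan, EvaluationReport, evaluate
from .encoder import DEFAULT_SCALES, NeighborhoodSpec, ThresholdRule, encode_image
from .preprocess import PreprocessConfig

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compute_features"]


@dataclass
class RunConfig:
    """Flat bundle of stage parameters, serialisable to YAML/JSON."""

    scale: float = 1.0
    median_size: int = 3
    roi_mode: str = "none"
    remove_pectoral: bool = False
    scales: tuple[tuple[float, int], ...] = tuple(
        (s.radius, s.n_points) for s in DEFAULT_SCALES
    )
    p1: float = 0.02
    p2: float = 0.07
    variant: str = "riu4"
    feature_set: str = "concat"  # hist | kspec | concat
    r_min: int = 1
    r_max: int = 10
    bandwidth: str | float = "auto"
    selection: str = "rfe"  # dps | rfe | fir | none
    dps_percent: float = 95.0
    top_n: int | str | None = None  # int, "sweep", or None (= all)
    scheme: str = "kfold"
    k: int = 10
    runs: int = 1
    kernels: tuple[str, ...] = ("rbf", "poly", "sigmoid")
    gammas: tuple[float, ...] = ExperimentPlan().gammas
    Cs: tuple[float, ...] = ExperimentPlan().Cs
    degrees: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    inner_k: int = 3
    seed: int = 0

    def neighborhoods(self) -> tuple[NeighborhoodSpec, ...]:
        return tuple(NeighborhoodSpec(r, p) for r, p in self.scales)

    def threshold_rule(self) -> ThresholdRule:
        return ThresholdRule(self.p1, self.p2)

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(self.scale, self.median_size, self.roi_mode)

    def plan(self) -> ExperimentPlan:
        return ExperimentPlan(
            scheme=self.scheme,
            k=self.k,
            runs=self.runs,
            seed=self.seed,
            kernels=tuple(self.kernels),
            gammas=tuple(float(g) for g in self.gammas),
            Cs=tuple(float(c) for c in self.Cs),
            degrees=tuple(int(d) for d in self.degrees),
            inner_k=self.inner_k,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales"] = [list(s) for s in d["scales"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("scales", "kernels", "gammas", "Cs", "degrees"):
            if key in d:
                d[key] = tuple(tuple(v) if isinstance(v, list) else v for v in d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    report: EvaluationReport
    features: pd.DataFrame
    ranking: featselect.SelectionRanking | None
    selected: list[str]
    config: RunConfig

    def checkpoint_hash(self) -> str:
        """Stable digest of the feature table (reruns must reproduce it)."""
        payload = self.features.to_csv(float_format="%.10g").encode()
        return hashlib.sha256(payload).hexdigest()


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _prepare(rec: dict, config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    image = np.asarray(rec["image"], dtype=np.float64)
    mask = rec.get("mask")
    if mask is None:
        mask = preprocess.segment_breast(image)
        if config.remove_pectoral and rec.get("view", "").upper() == "MLO":
            mask = preprocess.remove_pectoral(image, mask, view="MLO")
    else:
        mask = np.asarray(mask, dtype=bool)
    image, mask = preprocess.denoise_and_rescale(image, mask, config.preprocess_config())
    if config.roi_mode == "central_square":
        image, mask = preprocess.extract_roi_central_square(image, mask)
    return image, mask


def compute_features(records: list[dict], config: RunConfig) -> pd.DataFrame:
    """Preprocess + encode + featurise every record into one table.

    Also stores the raw-count histogram columns needed by DPS under the
    attribute ``frame.attrs['raw_hist']``.
    """
    rows = []
    raw_hists = []
    specs = config.neighborhoods()
    rule = config.threshold_rule()
    r_range = range(config.r_min, config.r_max + 1)
    for rec in records:
        try:
            image, mask = _prepare(rec, config)
        except Exception as exc:  # noqa: BLE001
            raise StageError("preprocess", exc) from exc
        try:
            codes = encode_image(image, mask, specs, rule, config.variant)
        except Exception as exc:  # noqa: BLE001
            raise StageError("encode", exc) from exc
        try:
            hist = histfeat.histogram_vector(codes, normalize=True)
            raw_hists.append(histfeat.histogram_vector(codes, normalize=False))
            if config.feature_set == "hist":
                fv = hist
            else:
                kspec = kspatial.kspectrum(
                    codes, r_range=r_range, bandwidth=config.bandwidth
                )
                fv = kspec if config.feature_set == "kspec" else histfeat.concat_features(hist, kspec)
        except Exception as exc:  # noqa: BLE001
            raise StageError("features", exc) from exc
        rows.append((fv, rec.get("label"), rec.get("woman_id")))
    frame = histfeat.features_to_frame(rows)
    frame.attrs["raw_hist"] = histfeat.features_to_frame(
        [(h, r.get("label"), r.get("woman_id")) for h, r in zip(raw_hists, records)]
    )
    return frame


def _rank(frame: pd.DataFrame, config: RunConfig) -> featselect.SelectionRanking | None:
    names = [c for c in frame.columns if c not in ("label", "woman_id")]
    X = frame[names].to_numpy()
    y = frame["label"].to_numpy()
    if config.selection == "none":
        return None
    if config.selection == "dps":
        source = frame.attrs.get("raw_hist")
        if config.feature_set == "hist" and source is not None:
            hist_names = [c for c in source.columns if c not in ("label", "woman_id")]
            vectors = [
                histfeat.FeatureVector(row, hist_names)
                for row in source[hist_names].to_numpy()
            ]
        else:  # K-spectrum entries can be negative; DPS uses |value|
            vectors = [histfeat.FeatureVector(row, names) for row in X]
        return featselect.dps_select(vectors, config.dps_percent)
    if config.selection == "rfe":
        return featselect.rfe_rank(X, y, names)
    if config.selection == "fir":
        return featselect.fir_rank(X, y, names, seed=config.seed)
    raise ValueError(f"unknown selection method {config.selection!r}")


def run_pipeline(records: list[dict], config: RunConfig) -> PipelineResult:
    """Run the full workflow and evaluate with the configured CV scheme."""
    labels = {rec.get("label") for rec in records}
    if len(labels) < 2:
        raise StageError("input", ValueError("need at least 2 classes"))
    frame = compute_features(records, config)
    names = [c for c in frame.columns if c not in ("label", "woman_id")]
    X = frame[names].to_numpy()
    y = frame["label"].to_numpy()
    groups = frame["woman_id"].to_numpy()
    try:
        ranking = _rank(frame, config)
    except Exception as exc:  # noqa: BLE001
        raise StageError("select", exc) from exc
    plan = config.plan()
    if ranking is None:
        selected = names
    elif config.top_n == "sweep":
        sweep = featselect.top_n_sweep(ranking, X, y, names, plan, groups=groups)
        selected = [n for n in ranking.top(sweep.best_n) if n in set(names)]
    elif config.top_n is None:
        n_sel = ranking.n_selected or len(ranking.names)
        selected = [n for n in ranking.top(n_sel) if n in set(names)]
    else:
        selected = [n for n in ranking.top(int(config.top_n)) if n in set(names)]
    cols = [names.index(n) for n in selected]
    try:
        report = evaluate(X[:, cols], y, groups=groups, plan=plan)
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc
    return PipelineResult(
        report=report, features=frame, ranking=ranking, selected=selected, config=config
    )
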