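"""End-to-end orchestration: simulate (or load) → preprocess → band power →
PLI → graph metrics → LASSO screening → routed correlations.

A run is a pure function of (inputs, config, seed): the run directory
contains every stage output plus a manifest with the resolved config, the
package version, and a SHA-256 hash per artifact, so identical runs are
byte-identical.
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
import yaml

from . import __version__
from .association import (
    TARGETS,
    assemble_features,
    correlate_selected,
    lasso_select,
    summarize_cohort,
)
from .connectivity import band_pli
from .network import DEFAULT_SPARSITIES, graph_metric_sweep
from .preprocess import RawRecording, preprocess_recording
from .spectral import DEFAULT_BANDS, Band, RoiSpec, band_power, roi_average
from .synthetic import DEFAULT_ROI, SimulationConfig, simulate_cohort

log = logging.getLogger("eeg2tms")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str | None, cause: Exception):
        self.stage = stage
        self.subject = subject
        where = f"stage={stage}" + (f" subject={subject}" if subject else "")
        super().__init__(f"pipeline failed at {where}: {cause}")


@dataclass(frozen=True)
class PipelineConfig:
    """Structured configuration for a full run; round-trips through YAML."""

    simulation: SimulationConfig | None = None
    data_dir: str | None = None
    target_rate: float | None = None
    filter_band: tuple[float, float] = (0.1, 40.0)
    epoch_length: float = 2.0
    reject_threshold: float = 100.0
    bands: tuple[Band, ...] = DEFAULT_BANDS
    roi_channels: tuple[str, ...] = DEFAULT_ROI
    sparsities: tuple[float, ...] = DEFAULT_SPARSITIES
    binarize: bool = False  # weighted graphs: PLI value as the edge weight
    edge_fraction: float = 0.1
    pli_average: str = "epochs"
    lasso_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and self.data_dir is None:
            raise ValueError("config needs a simulation block or a data_dir")
        if not self.roi_channels:
            raise ValueError("config needs a non-empty ROI channel list")

    @property
    def roi(self) -> RoiSpec:
        return RoiSpec("sensorimotor", frozenset(self.roi_channels))

    # ---- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        doc = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = doc["simulation"]
            sim["coupling_pairs"] = [
                list(dataclasses.astuple(cp))
                for cp in self.simulation.coupling_pairs
            ]
        doc["bands"] = [[b.name, b.lo, b.hi] for b in self.bands]
        return plain(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        from .synthetic import CouplingEnsemble, CouplingSpec, ExcitabilityModel

        doc = dict(doc)
        sim = doc.get("simulation")
        if sim is not None:
            sim = dict(sim)
            sim["coupling_pairs"] = tuple(
                CouplingSpec(int(i), int(j), str(b), float(lag), float(s))
                for i, j, b, lag, s in sim.get("coupling_pairs", ())
            )
            if isinstance(sim.get("excitability"), dict):
                sim["excitability"] = ExcitabilityModel(**sim["excitability"])
            if isinstance(sim.get("ensemble"), dict):
                ens = dict(sim["ensemble"])
                for key in ("members", "lag_range"):
                    if key in ens:
                        ens[key] = tuple(ens[key])
                sim["ensemble"] = CouplingEnsemble(**ens)
            if sim.get("channel_labels") is not None:
                sim["channel_labels"] = tuple(sim["channel_labels"])
            if sim.get("latent_range") is not None:
                sim["latent_range"] = tuple(sim["latent_range"])
            doc["simulation"] = SimulationConfig(**sim)
        if "bands" in doc:
            doc["bands"] = tuple(Band(str(n), float(lo), float(hi))
                                 for n, lo, hi in doc["bands"])
        for key in ("filter_band", "roi_channels", "sparsities"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------------
# per-subject feature extraction
# --------------------------------------------------------------------------

def extract_subject_features(
    rec: RawRecording, config: PipelineConfig
) -> dict[str, float]:
    """All 30 EEG features for one subject: 6 ROI band powers plus 4 network
    AUC metrics × 6 bands."""
    roi = config.roi
    epochs = preprocess_recording(
        rec,
        target_rate=config.target_rate,
        band=config.filter_band,
        epoch_length=config.epoch_length,
        reject_threshold=config.reject_threshold,
    )
    table = band_power(epochs, config.bands)
    features = {
        f"power_{name}": val for name, val in roi_average(table, roi).items()
    }
    for band in config.bands:
        pli = band_pli(epochs, band, config.edge_fraction, config.pli_average)
        sweep = graph_metric_sweep(
            pli, config.sparsities, binarize=config.binarize, roi=roi
        )
        for metric, value in sweep.auc.items():
            features[f"{metric}_auc_{band.name}"] = value
    return features


def build_feature_table(
    recordings, subject_ids, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(roi_power, network_auc) frames indexed by subject id."""
    roi_labels = set(config.roi_channels)
    for rec, sid in zip(recordings, subject_ids):
        missing = roi_labels - set(rec.channel_labels)
        if missing:
            raise ValueError(
                f"ROI channels {sorted(missing)} absent from {sid}"
            )
    power_rows, net_rows = [], []
    for rec, sid in zip(recordings, subject_ids):
        try:
            feats = extract_subject_features(rec, config)
        except Exception as err:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError("features", sid, err) from err
        power_rows.append({k: v for k, v in feats.items()
                           if k.startswith("power_")})
        net_rows.append({k: v for k, v in feats.items()
                         if not k.startswith("power_")})
    idx = pd.Index(subject_ids, name="subject_id")
    return (pd.DataFrame(power_rows, index=idx),
            pd.DataFrame(net_rows, index=idx))


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the whole analysis and write the run directory.

    Outputs: ``cohort_features.csv``, per-target LASSO reports
    (JSON + coefficient CSV), correlation tables, the Table-1-style summary,
    and ``manifest.json`` with config, version and artifact hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        missing = set(config.roi_channels) - set(config.simulation.channel_labels)
        if missing:
            raise ValueError(
                f"ROI channels {sorted(missing)} absent from the simulated montage"
            )
        log.info("simulating cohort of %d subjects", config.simulation.n_subjects)
        try:
            recordings, targets, _truth = simulate_cohort(config.simulation)
        except Exception as err:
            raise PipelineError("simulate", None, err) from err
    else:
        from .io import read_cohort

        recordings, targets = read_cohort(config.data_dir)
    subject_ids = list(targets.index)

    roi_power, network_auc = build_feature_table(recordings, subject_ids, config)
    try:
        table = assemble_features(roi_power, network_auc, targets)
    except Exception as err:
        raise PipelineError("assemble", None, err) from err
    table.to_csv(out / "cohort_features.csv", float_format="%.10g")

    for target in TARGETS:
        try:
            fit = lasso_select(table, target, folds=config.lasso_folds,
                               seed=config.seed)
            corr = correlate_selected(table, fit)
        except Exception as err:
            raise PipelineError(f"associate[{target}]", None, err) from err
        report = {
            "target": target,
            "lambda_min": fit.lambda_min,
            "cv_folds": config.lasso_folds,
            "cv_seed": fit.cv_seed,
            "selected": list(fit.selected),
            "dropped_constant": list(fit.dropped_constant),
            "intercept": fit.intercept,
        }
        (out / f"lasso_{target}.json").write_text(
            json.dumps(report, indent=1, sort_keys=True)
        )
        coef = pd.DataFrame({
            "standardized": fit.coef_standardized,
            "original_scale": fit.coef_original,
        })
        coef.index.name = "feature"
        coef.to_csv(out / f"lasso_{target}_coefficients.csv",
                    float_format="%.10g")
        corr.to_csv(out / f"correlations_{target}.csv", index=False,
                    float_format="%.10g")

    metrics, target_summary = summarize_cohort(table)
    metrics.to_csv(out / "summary_metrics.csv", float_format="%.10g")
    target_summary.to_csv(out / "summary_targets.csv", float_format="%.10g")

    artifacts = sorted(p.name for p in out.iterdir()
                       if p.name != "manifest.json")
    manifest = {
        "package": "eeg2tms",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    log.info("run complete: %s", out)
    return manifest
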