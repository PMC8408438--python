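"""Pipeline driver: simulate/load -> phase-encode screen -> pRF fit -> stats.

Stages mirror the analysis order of a phase-encoded somatotopy study:
voxels are first screened by winner-take-all lag correlation, survivors
are fit with Gaussian and DoG ellipse pRF models and compared by model
evidence, and map-level statistics are computed from the fits.  Every
output directory carries a manifest naming the configuration hash and
seeds that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .fitting import compare_models, fit_voxels
from .hemodynamics import DoubleGammaHRF
from .phase_encoding import (assign_lags, build_lagged_references,
                             combine_directions, lag_to_digit)
from .space import BACKWARD, FORWARD, HandSpace
from .stats import relative_volume, suppression_index
from .synthetic import simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; serializes losslessly to JSON."""

    out_dir: str = "somatoprf_out"
    input_dir: str | None = None      # dataset dir; None -> simulate
    n_voxels_per_digit: int = 10
    snr: float = 2.0
    seed: int = 0
    lag_threshold: float = 0.25       # phase-encoding inclusion cutoff
    posterior_prob_threshold: float = 0.95
    evidence_band: float = 3.0
    n_permutations: int = 1000
    n_boot: int = 1000
    fit_models: tuple[str, ...] = ("gaussian_ellipse", "dog_ellipse")
    space: dict = field(default_factory=lambda: HandSpace().to_dict())

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["fit_models"] = tuple(d.get("fit_models", ("gaussian_ellipse", "dog_ellipse")))
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write TSV outputs plus a manifest.

    Returns a results bundle (dict of in-memory results and output paths).
    Any stage failure aborts with the stage name; a PARTIAL marker is left
    in the output directory alongside whatever was already written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash, "seed": config.seed,
                      "stages": {}}
    (out / "config.json").write_text(config.to_json())
    stage = "setup"
    try:
        space = HandSpace.from_dict(config.space)
        hemo = DoubleGammaHRF()

        stage = "data"
        if config.input_dir:
            ds = sio.load_dataset(config.input_dir)
        else:
            from .synthetic import default_layout
            ds = simulate_dataset(
                layout=default_layout(space, n_per_digit=config.n_voxels_per_digit),
                space=space, snr=config.snr or None, seed=config.seed)
        offsets = np.concatenate([[0], np.cumsum([d.n_timebins for d in ds.designs])])
        runs = {(d.dimension, d.direction): (d, int(offsets[i]), int(offsets[i + 1]))
                for i, d in enumerate(ds.designs)}
        fwd, f0, f1 = runs[("between_digit", FORWARD)]
        bwd, b0, b1 = runs[("between_digit", BACKWARD)]
        logger.info("stage data: %d voxels in", ds.n_voxels)
        manifest["stages"]["data"] = {"voxels_in": ds.n_voxels}

        stage = "phase_encoding"
        refs_f = build_lagged_references(fwd)
        refs_b = build_lagged_references(bwd)
        la_f = assign_lags(ds.bold[:, f0:f1], refs_f, tr=fwd.tr,
                           threshold=config.lag_threshold, direction=FORWARD)
        la_b = assign_lags(ds.bold[:, b0:b1], refs_b, tr=bwd.tr,
                           threshold=config.lag_threshold, direction=BACKWARD)
        combined = combine_directions(la_f, la_b, fwd)
        rows = []
        for a in la_f + la_b + combined:
            digit = ""
            if a.included:
                digit = lag_to_digit(a, fwd, space)
            rows.append({"voxel_id": a.voxel_id, "direction": a.direction,
                         "best_lag_s": a.best_lag, "max_r": a.max_r,
                         "included": a.included, "digit_label": digit})
        pd.DataFrame(rows).to_csv(out / "phase_encoding.tsv", sep="\t", index=False)
        survivors = [a.voxel_id for a in combined if a.included]
        logger.info("stage phase_encoding: %d voxels in, %d out",
                    ds.n_voxels, len(survivors))
        manifest["stages"]["phase_encoding"] = {
            "voxels_in": ds.n_voxels, "voxels_out": len(survivors)}
        if not survivors:
            raise RuntimeError("no voxels survived phase-encoding screening")

        stage = "prf_fitting"
        fits = {}
        for model in config.fit_models:
            fits[model] = fit_voxels(ds.bold[survivors], ds.designs, space,
                                     model=model, hemodynamics=hemo,
                                     voxel_ids=survivors)
        manifest["stages"]["prf_fitting"] = {
            "voxels_in": len(survivors),
            "models": list(config.fit_models)}

        stage = "model_comparison"
        comparisons = []
        if "gaussian_ellipse" in fits and "dog_ellipse" in fits:
            comparisons = [compare_models(g, d) for g, d in
                           zip(fits["gaussian_ellipse"], fits["dog_ellipse"])]
        for model, flist in fits.items():
            sio.write_fits_tsv(flist, out / f"fits_{model}.tsv", comparisons or None)
        if comparisons:
            pd.DataFrame([{"voxel_id": c.voxel_id, "delta_f": c.delta_f,
                           "verdict": c.verdict} for c in comparisons]
                         ).to_csv(out / "model_comparison.tsv", sep="\t", index=False)
        manifest["stages"]["model_comparison"] = {
            "n_compared": len(comparisons)}

        stage = "statistics"
        report = fits.get("dog_ellipse") or next(iter(fits.values()))
        included = [f for f in report
                    if f.posterior_model_prob > config.posterior_prob_threshold]
        labels = [space.segment_of(f.params.x0) for f in included]
        stats_summary: dict = {"n_included": len(included)}
        if labels:
            stats_summary["relative_volume"] = relative_volume(labels)
        si_values = {}
        for f, lab in zip(included, labels):
            if f.model == "dog_ellipse" and f.params.beta_e > 0:
                si_values.setdefault(lab, []).append(suppression_index(f.params))
        stats_summary["suppression_index_mean"] = {
            lab: float(np.mean(v)) for lab, v in si_values.items()}
        (out / "stats_summary.json").write_text(json.dumps(stats_summary, indent=2))
        manifest["stages"]["statistics"] = {"voxels_in": len(report),
                                            "voxels_included": len(included)}

        manifest["status"] = "complete"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return {"dataset": ds, "phase": combined, "fits": fits,
                "comparisons": comparisons, "stats": stats_summary,
                "out_dir": out, "manifest": manifest}
    except Exception as exc:
        manifest["status"] = "PARTIAL"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "PARTIAL").write_text(f"failed in stage {stage}: {exc}\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
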