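"""Run the full workflow: dating -> chronology -> CT -> proxy reconstruction.

Each stage reads its inputs from the configuration, writes CSV/JSON outputs
into the output directory and records its status in a run log (with the
config hash and seed) so any run can be replayed. Stage failures are
reported per stage; independent later stages still run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from . import chronology, ct, io, proxies, useries
from .config import PipelineConfig

__all__ = ["run_pipeline"]

log = logging.getLogger("coralmound")


def _mgca_calibration(cfg: PipelineConfig) -> proxies.MgCaCalibration:
    return proxies.MgCaCalibration(cfg.mgca_a, cfg.mgca_b, cfg.mgca_sd2_a, cfg.mgca_sd2_b)


def _paleotemp(cfg: PipelineConfig) -> proxies.PaleotempEquation:
    return proxies.PaleotempEquation(cfg.paleotemp_k0, cfg.paleotemp_k1,
                                     cfg.paleotemp_k2, cfg.paleotemp_scale_offset)


def _density(cfg: PipelineConfig) -> proxies.DensityCalibration:
    return (proxies.REGIONAL_DENSITY if cfg.density_calibration == "regional"
            else proxies.GLOBAL_DENSITY)


def run_pipeline(cfg: PipelineConfig, out_dir) -> Dict[str, Dict]:
    """Execute all configured stages; returns a per-stage status/result map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: Dict[str, Dict] = {}
    dates = None

    # --- U-series dating ---------------------------------------------------
    if cfg.useries_csv:
        try:
            df = io.read_table(cfg.useries_csv, io.USERIES_SCHEMA)
            dated = useries.date_table(df, seed=cfg.seed)
            dated.to_csv(out / "useries_ages.csv", index=False)
            dates = [
                chronology.CoralDate(
                    depth=row.depth_cm, age=row.age_ka, sd2=row.sd2_age_ka,
                    reliable=bool(row.reliable), sample_id=str(row.sample_id))
                for row in dated.itertuples()
                if row.age_ka is not None and np.isfinite(row.age_ka) and row.age_ka > 0
            ]
            status["date"] = {"ok": True, "n": len(dated)}
        except Exception as exc:  # noqa: BLE001 - stage isolation
            status["date"] = {"ok": False, "error": f"{exc}"}
            log.error("stage 'date' failed: %s", exc)
    else:
        status["date"] = {"ok": True, "skipped": "no useries_csv"}

    # --- chronology --------------------------------------------------------
    if dates:
        try:
            clusters = chronology.identify_clusters(
                dates, cfg.max_age_gap_ka, cfg.max_depth_gap_cm)
            rows = [{
                "cluster": i + 1, "depth_min_cm": c.depth_min,
                "depth_max_cm": c.depth_max, "age_min_ka": c.age_min,
                "age_max_ka": c.age_max, "ar_cm_per_kyr": c.ar,
                "n_dates": len(c.member_ids),
            } for i, c in enumerate(clusters)]
            pd.DataFrame(rows).to_csv(out / "clusters.csv", index=False)
            reversals = (chronology.detect_reversals(dates)
                         if len(dates) >= 2 else [])
            status["chronology"] = {
                "ok": True, "n_clusters": len(clusters),
                "n_reversals": len(reversals),
            }
        except Exception as exc:  # noqa: BLE001
            status["chronology"] = {"ok": False, "error": f"{exc}"}
            log.error("stage 'chronology' failed: %s", exc)
    else:
        status["chronology"] = {"ok": True, "skipped": "no dated corals"}

    # --- CT quantification -------------------------------------------------
    if cfg.ct_volume:
        try:
            vol = io.read_volume(cfg.ct_volume, cfg.ct_voi_mask)
            slices, summary, _ = ct.quantify(
                vol, threshold=cfg.ct_threshold, min_voxels=cfg.ct_min_voxels,
                denoise_first=cfg.ct_denoise)
            pd.DataFrame([s.__dict__ for s in slices]).to_csv(
                out / "coral_content.csv", index=False)
            (out / "coral_content_summary.json").write_text(json.dumps(summary))
            status["ct_quant"] = {"ok": True, **summary}
        except Exception as exc:  # noqa: BLE001
            status["ct_quant"] = {"ok": False, "error": f"{exc}"}
            log.error("stage 'ct-quant' failed: %s", exc)
    else:
        status["ct_quant"] = {"ok": True, "skipped": "no ct_volume"}

    # --- proxy reconstruction ----------------------------------------------
    if cfg.foram_csv:
        try:
            df = io.read_table(cfg.foram_csv, io.FORAM_SCHEMA)
            samples = [
                proxies.ForamSample(
                    depth=r.depth_cm, mgca=r.mgca, d18o_c=r.d18o_c,
                    alca=getattr(r, "alca", float("nan")),
                    feca=getattr(r, "feca", float("nan")),
                    sd2_mgca=getattr(r, "sd2_mgca", 0.1),
                    sd2_d18o=getattr(r, "sd2_d18o", 0.06))
                for r in df.itertuples()
            ]
            rows = proxies.reconstruct_downcore(
                samples,
                calibration=_mgca_calibration(cfg),
                equation=_paleotemp(cfg),
                density_calibration=_density(cfg),
                regression=proxies.SalinityRegression(
                    cfg.salinity_slope, cfg.salinity_intercept),
                pressure=float(cfg.water_depth_m) * 1.0053,
                uncertainty_method=cfg.uncertainty_method,
                n_monte_carlo=cfg.monte_carlo_n,
                seed=cfg.seed,
            )
            proxies.rows_to_frame(rows).to_csv(out / "reconstruction.csv", index=False)
            try:
                qc = proxies.screen_contamination(samples)
            except ValueError:
                qc = {"n": len(samples), "pass": None, "r2": {}}
            (out / "contamination_qc.json").write_text(json.dumps(qc, default=str))
            status["reconstruct"] = {"ok": True, "n": len(rows),
                                     "qc_pass": qc.get("pass")}
        except Exception as exc:  # noqa: BLE001
            status["reconstruct"] = {"ok": False, "error": f"{exc}"}
            log.error("stage 'reconstruct' failed: %s", exc)
    else:
        status["reconstruct"] = {"ok": True, "skipped": "no foram_csv"}

    run_log = {
        "config": asdict(cfg),
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "stages": status,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return status
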