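"""End-to-end orchestration of a validation run.

A study is organised as ``<root>/day<D>/rep<R>/*.tif`` (one directory
per TEM specimen, 10 images each in the reference design: 5 days x 3
replicate specimens).  The pipeline analyses every image with one fixed
set of detection parameters, pools the retained particles per specimen,
takes the specimen medians of the minimal Feret diameter, runs the
day-factor ANOVA uncertainty chain, and (when a reference value is
configured) the trueness assessment on the modal ECD.  Every output
carries the seed, a configuration hash and the package version so a
report can be regenerated and compared bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detection import DetectionParams, analyze_micrograph
from .imaging import load_micrograph
from .intra import CrmReference, budget_from_design, trueness
from .size_stats import median_min_feret, modal_ecd

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "export_report", "summarize_records"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything needed to reproduce one validation run."""

    input_dir: str
    out_dir: str
    params: DetectionParams = field(default_factory=DetectionParams)
    pixel_size_nm: float | None = None
    fov_nm: float | None = None
    material: str = "material"
    u_cal_pct: float = 0.0
    crm_value_nm: float | None = None
    crm_u_nm: float | None = None
    seed: int = 0

    def crm(self) -> CrmReference | None:
        if self.crm_value_nm is None:
            return None
        return CrmReference(value_nm=self.crm_value_nm, u_nm=self.crm_u_nm or 0.0)

    def config_hash(self) -> str:
        # hash only analysis-relevant settings, not filesystem locations,
        # so re-running the same analysis elsewhere reproduces the report
        payload = {
            k: v for k, v in asdict(self).items() if k not in ("input_dir", "out_dir")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _discover(root: Path) -> list[tuple[int, int, Path]]:
    found = []
    for day_dir in sorted(root.glob("day*")):
        try:
            day = int(day_dir.name.removeprefix("day"))
        except ValueError:
            continue
        for rep_dir in sorted(day_dir.glob("rep*")):
            try:
                rep = int(rep_dir.name.removeprefix("rep"))
            except ValueError:
                continue
            for img in sorted(rep_dir.iterdir()):
                if img.suffix.lower() in {".tif", ".tiff", ".png"}:
                    found.append((day, rep, img))
    if not found:
        raise PipelineError(
            f"no images under {root}; expected layout day<D>/rep<R>/image.tif"
        )
    return found


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen (day, replicate) distribution summary.

    One row per specimen with the particle count, the median minimal
    Feret diameter, and the modal ECD (NaN when fewer than 10 particles
    make the normal fit unstable).
    """
    rows = []
    for (day, rep), grp in records.groupby(["day", "replicate"]):
        ferets = grp["min_feret_nm"].to_numpy(dtype=float)
        ecds = grp["ecd_nm"].to_numpy(dtype=float)
        rows.append(
            {
                "day": day,
                "replicate": rep,
                "n": len(grp),
                "median_min_feret_nm": median_min_feret(ferets),
                "modal_ecd_nm": modal_ecd(ecds) if len(ecds) >= 10 else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values(["day", "replicate"]).reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Analyse a day/replicate image tree and compute the full budget."""
    root = Path(config.input_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images = _discover(root)

    all_records = []
    for day, rep, path in images:
        mg = load_micrograph(
            path,
            pixel_size_nm=config.pixel_size_nm,
            fov_nm=config.fov_nm,
            material=config.material,
            day=day,
            replicate=rep,
            image_index=None,
        )
        retained, _log = analyze_micrograph(mg, config.params)
        retained = retained.assign(day=day, replicate=rep)
        all_records.append(retained)
    non_empty = [r for r in all_records if len(r)]
    if not non_empty:
        raise PipelineError("no particles survive the quantification filters anywhere")
    records = pd.concat(non_empty, ignore_index=True)

    empty = [
        (d, r)
        for (d, r), grp in records.groupby(["day", "replicate"])
        if len(grp) == 0
    ]
    seen = {(d, r) for d, r, _ in images}
    have = set(records.groupby(["day", "replicate"]).groups)
    missing = sorted(seen - have) + empty
    if missing:
        raise PipelineError(
            "no particles survive the quantification filters for specimen(s) "
            + ", ".join(f"day{d}/rep{r}" for d, r in missing)
        )

    specimens = summarize_records(records)
    days = sorted(specimens["day"].unique())
    reps = sorted(specimens["replicate"].unique())
    medians = (
        specimens.pivot(index="day", columns="replicate", values="median_min_feret_nm")
        .reindex(index=days, columns=reps)
        .to_numpy()
    )
    if np.isnan(medians).any():
        raise PipelineError("incomplete day x replicate design")

    budget = budget_from_design(
        medians, config.u_cal_pct, crm=config.crm(), material=config.material
    )
    c_m = budget.anova.c_m

    report = {
        "material": config.material,
        "software_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_images": len(images),
        "n_particles_retained": int(len(records)),
        "c_m_nm": c_m,
        "budget_pct": {
            k: getattr(budget, k)
            for k in ("u_r", "u_day", "u_ip", "u_cal", "u_t", "u_c", "ucx")
        },
        "anova": {
            "ms_within": budget.anova.ms_within,
            "ms_between": budget.anova.ms_between,
            "nu_within": budget.anova.nu_within,
            "sd_nm": budget.anova.sd,
        },
    }
    crm = config.crm()
    if crm is not None:
        ecd_means = specimens["modal_ecd_nm"].to_numpy(dtype=float)
        c_m_ecd = float(np.nanmean(ecd_means))
        assessment = trueness(c_m_ecd, budget.u_c * c_m_ecd / 100.0, crm)
        report["trueness"] = {
            "c_m_modal_ecd_nm": c_m_ecd,
            "delta_m_nm": assessment.delta_m,
            "u_delta_nm": assessment.u_delta,
            "U_delta_nm": assessment.U_delta,
            "no_significant_bias": assessment.no_significant_bias,
        }

    records.to_csv(out / "particles.csv", index=False)
    specimens.to_csv(out / "specimens.csv", index=False)
    export_report(report, out / "report.json")
    return report


def _round_floats(obj, ndigits=4):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def export_report(report: dict, path) -> None:
    """Write the JSON report: rounded display copy plus raw values."""
    payload = {k: v for k, v in report.items() if v not in (None, {}, [])}
    out = {"summary": _round_floats(payload), "raw": payload}
    Path(path).write_text(json.dumps(out, indent=2, default=float) + "\n")
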