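"""End-to-end pipeline driver: simulate -> quantify -> voxel stats -> SEM.

`run_pipeline` chains the library stages on synthetic inputs into a run
directory with maps, tables, fit reports, a log and a manifest.  Everything
is deterministic given the global seed: per-stage seeds are derived from it
with `numpy.random.SeedSequence`, and the manifest records a SHA-256
checksum for every output so reruns can be compared file by file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__, io
from .core import KineticParams, StatImage, martinostat_frame_schedule
from .kinetics import BasisGrid, make_r1_map
from .pet_quant import TRACER_PROTOCOLS, compute_suvr, rbv_correct, roi_extract
from .sem_mediation import (
    compare_models,
    five_model_suite,
    mediation_effects,
)
from .sem_mediation.fit import fit_model
from .synthetic_data import (
    CohortSpec,
    PhantomSpec,
    RegionSpec,
    make_phantom,
    simulate_cohort,
    simulate_dynamic_pet,
    simulate_reference_tac,
)
from .voxel_stats import DesignMatrix, fdr_bh, voxelwise_auc, voxelwise_glm

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic-pipeline run."""

    out_dir: str
    seed: int = 0
    stages: tuple = ("simulate", "quantify", "stats", "sem")
    tracer: str = "martinostat"
    grid_size: int = 24
    voxel_size_mm: float = 2.0
    n_per_group: int = 8          # subjects per group for the voxel stages
    group_effect: float = -0.12   # AD-group SUVR shift in the target region
    image_noise_sd: float = 0.05
    fdr_q: float = 0.05
    alpha: float = 0.05
    psf_fwhm_mm: float = 8.0
    cohort_sizes: tuple = (25, 28, 15, 26)
    sem_models: tuple = (
        "hdac_mediation",
        "hdac_after_atrophy",
        "hdac_first",
        "hdac_between",
        "classical_cascade",
    )

    def __post_init__(self):
        unknown = set(self.stages) - {"simulate", "quantify", "stats", "sem"}
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        if self.tracer not in TRACER_PROTOCOLS:
            raise ValueError(f"unknown tracer {self.tracer!r}")
        if int(self.seed) < 0 or int(self.seed) >= 2**31:
            raise ValueError("seed must be in [0, 2^31)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**io.load_config(path))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        order = ("simulate", "quantify", "stats", "sem")
        child = np.random.SeedSequence(self.seed).spawn(len(order))[order.index(stage)]
        return int(child.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _demo_phantom(cfg: RunConfig):
    g = cfg.grid_size
    c = g // 2
    quarter = max(g // 4, 4)
    size = (quarter,) * 3
    spec = PhantomSpec(
        grid_shape=(g, g, g),
        voxel_size_mm=cfg.voxel_size_mm,
        regions=(
            RegionSpec(1, (2, 2, 2), size, "target"),
            RegionSpec(2, (c, c, c), size, "reference_white_matter"),
            RegionSpec(3, (2, c, c), size, "target"),
        ),
    )
    return spec, make_phantom(spec)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages, returning the run directory.

    Partial failure leaves completed stages' outputs intact; the failing
    stage is named in the log and the exception re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list = []
    log_path = out / "run.log"
    logger = logging.getLogger(f"hdacscope.run.{id(config)}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)

    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()
    logger.info("hdacscope %s", __version__)
    logger.info("config hash %s", cfg_hash)
    logger.info("global seed %d", config.seed)
    io.save_config(cfg_dict, out / "config.yaml")

    def record(path: Path, stage: str, inputs: list):
        manifest.append(
            {
                "path": str(path.relative_to(out)),
                "stage": stage,
                "inputs": inputs,
                "sha256": _sha256(path),
            }
        )

    state: dict = {}
    stage = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            seed = config.stage_seed(stage)
            logger.info("stage %s seed %d", stage, seed)
            spec, labelmap = _demo_phantom(config)
            schedule = martinostat_frame_schedule()
            ref_tac = simulate_reference_tac(schedule, 50.0, 0.0004, 0.02)
            params = {
                1: KineticParams(0.8, 0.1, 0.5),
                3: KineticParams(1.1, 0.12, 0.3),
            }
            dyn = simulate_dynamic_pet(
                labelmap,
                params,
                ref_tac,
                schedule,
                noise_sd=config.image_noise_sd,
                seed=seed,
                reference_labels=spec.reference_labels(),
            )
            io.write_image(labelmap, out / "phantom_labels.nii.gz")
            io.write_image(dyn, out / "dynamic.nii.gz")
            record(out / "phantom_labels.nii.gz", stage, [])
            record(out / "dynamic.nii.gz", stage, ["phantom_labels.nii.gz"])
            record(out / "dynamic_frames.tsv", stage, ["dynamic.nii.gz"])
            state.update(labelmap=labelmap, dynamic=dyn, spec=spec, schedule=schedule)
            logger.info("stage %s done", stage)

        if "quantify" in config.stages:
            stage = "quantify"
            logger.info("stage %s", stage)
            labelmap, dyn, spec = state["labelmap"], state["dynamic"], state["spec"]
            protocol = TRACER_PROTOCOLS[config.tracer]
            w0, w1 = protocol.window_min
            sched = dyn.schedule
            sel = np.where((sched.starts >= w0 * 60 - 1e-6) & (sched.ends <= w1 * 60 + 1e-6))[0]
            from .core import DynamicImage, FrameSchedule

            window = DynamicImage(
                dyn.data[..., sel],
                dyn.affine,
                FrameSchedule(sched.starts[sel], sched.durations[sel]),
            )
            suvr = compute_suvr(window, protocol, labelmap, spec.reference_labels())
            io.write_image(suvr, out / "suvr.nii.gz")
            record(out / "suvr.nii.gz", stage, ["dynamic.nii.gz"])

            rbv = rbv_correct(suvr, labelmap, config.psf_fwhm_mm)
            io.write_image(rbv.image, out / "suvr_pvc.nii.gz")
            record(out / "suvr_pvc.nii.gz", stage, ["suvr.nii.gz"])

            brain = np.ones(labelmap.data.shape, dtype=bool)
            r1 = make_r1_map(dyn, labelmap.mask(spec.reference_labels()), labelmap.data > 0,
                             grid=BasisGrid(n=32), smoothing_fwhm=0.0)
            io.write_image(r1, out / "r1.nii.gz")
            record(out / "r1.nii.gz", stage, ["dynamic.nii.gz"])

            rois = roi_extract(suvr, labelmap, {"target_a": 1, "reference": 2, "target_b": 3})
            io.write_table(rois, out / "roi_suvr.tsv")
            record(out / "roi_suvr.tsv", stage, ["suvr.nii.gz"])
            state.update(suvr=suvr)
            logger.info("stage %s done", stage)

        if "stats" in config.stages:
            stage = "stats"
            seed = config.stage_seed(stage)
            logger.info("stage %s seed %d", stage, seed)
            labelmap = state["labelmap"]
            rng = np.random.default_rng(seed)
            base = np.ones(labelmap.data.shape)
            target = labelmap.data == 1
            n = config.n_per_group
            controls, patients = [], []
            for i in range(n):
                im = base + rng.normal(0, 0.05, size=base.shape)
                controls.append(StatImage(im, labelmap.affine, tag="SUVR"))
            for i in range(n):
                im = base + rng.normal(0, 0.05, size=base.shape)
                im[target] += config.group_effect
                patients.append(StatImage(im, labelmap.affine, tag="SUVR"))
            images = controls + patients
            group = np.r_[np.zeros(n), np.ones(n)]
            design = DesignMatrix(
                np.column_stack([np.ones(2 * n), group]),
                ["intercept", "group"],
                [0.0, 1.0],
            )
            glm = voxelwise_glm(images, design)
            reject, thr = fdr_bh(glm.p, q=config.fdr_q)
            auc = voxelwise_auc(controls, patients)
            io.write_image(glm.t, out / "tmap.nii.gz")
            io.write_image(glm.p, out / "pmap.nii.gz")
            io.write_image(auc, out / "aucmap.nii.gz")
            for f in ("tmap", "pmap", "aucmap"):
                record(out / f"{f}.nii.gz", stage, ["suvr.nii.gz"])
            with open(out / "fdr.json", "w") as fh:
                json.dump(
                    {"q": config.fdr_q, "threshold": thr, "n_rejected": int(reject.sum())},
                    fh,
                    indent=2,
                )
            record(out / "fdr.json", stage, ["pmap.nii.gz"])
            logger.info(
                "stage %s done (%d voxels below FDR threshold %.2g)",
                stage,
                int(reject.sum()),
                thr,
            )

        if "sem" in config.stages:
            stage = "sem"
            seed = config.stage_seed(stage)
            logger.info("stage %s seed %d", stage, seed)
            sizes = config.cohort_sizes
            cohort = simulate_cohort(
                CohortSpec(
                    n_cu_young=sizes[0],
                    n_cu_elderly=sizes[1],
                    n_mci=sizes[2],
                    n_ad=sizes[3],
                    seed=seed,
                )
            )
            io.write_table(cohort, out / "cohort.tsv")
            record(out / "cohort.tsv", stage, [])
            suite = {k: v for k, v in five_model_suite().items() if k in config.sem_models}
            if len(suite) >= 2:
                table, best, fits = compare_models(suite, cohort)
                table.insert(0, "parameter", table.index)
                io.write_table(table, out / "sem_comparison.tsv")
                record(out / "sem_comparison.tsv", stage, ["cohort.tsv"])
                fit = fits.get("hdac_mediation")
            else:
                name = next(iter(suite))
                fit = fit_model(suite[name], cohort)
            if fit is not None:
                med = {
                    "tau_atrophy": asdict(mediation_effects(fit, "tau", "hdac", "atrophy")),
                    "tau_cognition": asdict(mediation_effects(fit, "tau", "hdac", "cognition")),
                    "fit": {
                        "chi2": fit.chi2,
                        "df": fit.df,
                        "p": fit.p_value,
                        "rmsea": fit.rmsea,
                        "srmr": fit.srmr,
                        "cfi": fit.cfi,
                        "aic": fit.aic,
                        "bic": fit.bic,
                        "r2": fit.r2,
                    },
                }
                with open(out / "sem_mediation.json", "w") as fh:
                    json.dump(med, fh, indent=2)
                record(out / "sem_mediation.json", stage, ["cohort.tsv"])
            logger.info("stage %s done", stage)
    except Exception:
        logger.exception("stage %s failed", stage)
        with open(out / "manifest.json", "w") as fh:
            json.dump({"complete": False, "failed_stage": stage, "outputs": manifest}, fh, indent=2)
        raise
    finally:
        handler.close()
        logger.removeHandler(handler)

    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "complete": True,
                "version": __version__,
                "config_hash": cfg_hash,
                "seed": config.seed,
                "outputs": manifest,
                "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
            },
            fh,
            indent=2,
        )
    return out
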