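"""End-to-end study orchestration.

``run_study`` reproduces the full experimental design: simulate the
23-acquisition phantom study, quantify every acquisition with the five
ROI/VOI methods, and evaluate accuracy/precision into the agreement report.
Everything is reproducible bit-for-bit from the :class:`StudyConfig` (all
randomness derives from ``master_seed``).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, gtm
from .manual import quantify_manual
from .phantom import (
    Acquisition,
    AcquisitionConfig,
    DEFAULT_DESIGN,
    PhantomGeometry,
    build_phantom,
    fill_activities,
    generate_study,
    save_acquisition,
    simulate_spect,
)
from .results import QuantResult, results_to_frame
from .templates import quantify_threebox, quantify_twobox

__all__ = ["StudyConfig", "StudyOutput", "run_study", "quantify_acquisition",
           "make_fixture", "ALL_METHODS"]

log = logging.getLogger("datquant")

ALL_METHODS = ("manual", "twobox", "threebox", "voi_mri_like", "voi_ct_like")


@dataclass
class StudyConfig:
    """Full specification of one simulated phantom study."""

    design: tuple = DEFAULT_DESIGN
    psf_fwhm: float = 11.0
    post_filter_fwhm: float = 6.0
    expected_total_counts: float = 3.0e6
    matrix_size: int = 128
    n_slices: int = 96
    voxel_size: float = 2.13
    jitter_cv: float = 0.10
    master_seed: int = 0
    methods: tuple = ALL_METHODS
    manual_top_k: int = 5
    composite_threshold: float = 0.05
    gtm_include_reference: bool = True

    def acquisition_config(self) -> AcquisitionConfig:
        return AcquisitionConfig(
            psf_fwhm=self.psf_fwhm,
            expected_total_counts=self.expected_total_counts,
            post_filter_fwhm=self.post_filter_fwhm,
            matrix_size=self.matrix_size,
            n_slices=self.n_slices,
            voxel_size=self.voxel_size,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = [list(pair) for pair in self.design]
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = tuple(tuple(p) for p in d["design"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StudyOutput:
    geometry: PhantomGeometry
    acquisitions: list
    results: pd.DataFrame
    report: pd.DataFrame
    voi_models: dict


def _voi_seeds(master_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence([int(master_seed), 7])
    children = ss.spawn(2)
    return {
        "mri_like": int(children[0].generate_state(1)[0] % (2 ** 31)),
        "ct_like": int(children[1].generate_state(1)[0] % (2 ** 31)),
    }


def build_voi_models(geometry: PhantomGeometry, config: StudyConfig) -> dict:
    """VOI sets + GTM models for the structural-imaging variants in use.

    The GTM blur mirrors the simulation chain (PSF stage then post-filter
    stage) so the correction model matches the data-generating resolution.
    """
    seeds = _voi_seeds(config.master_seed)
    stages = [f for f in (config.psf_fwhm, config.post_filter_fwhm) if f > 0]
    models = {}
    for method, provenance in (("voi_mri_like", "mri_like"), ("voi_ct_like", "ct_like")):
        if method not in config.methods:
            continue
        voi_set = gtm.make_voi_set(geometry, provenance=provenance,
                                   perturbation_seed=seeds[provenance])
        model = gtm.compute_gtm(voi_set, stages, geometry,
                                include_reference=config.gtm_include_reference)
        models[method] = (voi_set, model)
    return models


def quantify_acquisition(
    acq: Acquisition,
    geometry: PhantomGeometry,
    config: StudyConfig,
    voi_models: dict,
) -> list[QuantResult]:
    """Run every enabled method on one acquisition."""
    out: list[QuantResult] = []
    if "manual" in config.methods:
        out += quantify_manual(acq, geometry, k=config.manual_top_k)
    if "twobox" in config.methods:
        out += quantify_twobox(acq, geometry,
                               threshold_fraction=config.composite_threshold)
    if "threebox" in config.methods:
        out += quantify_threebox(acq, geometry,
                                 threshold_fraction=config.composite_threshold)
    for method, (voi_set, model) in voi_models.items():
        out += gtm.quantify_voi(acq, voi_set, model, method)
    return out


def run_study(
    config: StudyConfig | None = None,
    out_dir=None,
    write_volumes: bool = True,
) -> StudyOutput:
    """Simulate, quantify and evaluate a full study.

    When ``out_dir`` is given, writes the acquisitions (NIfTI + JSON
    sidecars), the per-acquisition results CSV, the agreement report
    (CSV/JSON/text) and the resolved configuration YAML.
    """
    config = config or StudyConfig()
    t0 = time.perf_counter()
    log.info("simulating study: %d acquisitions, master_seed=%d",
             sum(r for _, r in config.design), config.master_seed)
    geometry, acquisitions = generate_study(
        design=config.design,
        config=config.acquisition_config(),
        jitter_cv=config.jitter_cv,
        master_seed=config.master_seed,
    )
    log.info("simulation done in %.1fs", time.perf_counter() - t0)

    t1 = time.perf_counter()
    voi_models = build_voi_models(geometry, config)
    results: list[QuantResult] = []
    for acq in acquisitions:
        log.debug("quantifying %s (fill seed %d)", acq.acquisition_id, acq.fill.seed)
        results += quantify_acquisition(acq, geometry, config, voi_models)
    fills = {acq.acquisition_id: acq.fill for acq in acquisitions}
    frame = results_to_frame(results, fills)
    report = agreement.evaluate_study(frame)
    log.info("quantification + evaluation done in %.1fs", time.perf_counter() - t1)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        if write_volumes:
            acq_dir = out_dir / "acquisitions"
            for acq in acquisitions:
                save_acquisition(acq, geometry, acq_dir)
        frame.to_csv(out_dir / "results.csv", index=False)
        agreement.write_report(report, out_dir)
        log.info("study written to %s", out_dir)

    return StudyOutput(geometry=geometry, acquisitions=acquisitions,
                       results=frame, report=report, voi_models=voi_models)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

def make_fixture(
    size: str = "tiny",
    seed: int = 0,
    nominal_ratio: float = 10.0,
    jitter_cv: float = 0.0,
    noiseless: bool = False,
) -> tuple[PhantomGeometry, Acquisition]:
    """A phantom plus one simulated acquisition.

    ``tiny`` uses a 48^3 grid at 4 mm voxels with down-scaled wells and a
    smaller shell, fast enough for unit tests; ``default`` is the paper-scale
    geometry (128 x 128 x 96 at 2.13 mm).
    """
    if size == "tiny":
        geometry = build_phantom(
            voxel_size=4.0,
            matrix_size=48,
            n_slices=48,
            shell_semiaxes_mm=(42.0, 52.0, 32.0),
            striatal_z_extent_mm=40.0,
            nominal_volumes={"CA_R": 4.0, "CA_L": 3.9, "PU_R": 4.6, "PU_L": 5.1},
        )
        config = AcquisitionConfig(
            matrix_size=48, n_slices=48, voxel_size=4.0,
            expected_total_counts=3.0e5, seed=seed + 1,
        )
    elif size == "default":
        geometry = build_phantom()
        config = AcquisitionConfig(seed=seed + 1)
    else:
        raise ValueError("size must be 'tiny' or 'default'")
    activity, record = fill_activities(geometry, nominal_ratio,
                                       jitter_cv=jitter_cv, seed=seed)
    acq = simulate_spect(activity, config, geometry, fill=record,
                         noiseless=noiseless, acquisition_id=f"fixture_{size}")
    return geometry, acq
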