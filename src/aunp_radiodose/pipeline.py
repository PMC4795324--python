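"""End-to-end orchestration: scenario config -> activity, depth dose, field map.

A :class:`Scenario` bundles every knob of the chain (nuclide override,
nanoparticle geometry, tumor, surface loading, transport settings, optics)
and serializes to YAML with round-trip equality.  :func:`run_scenario`
executes reference data -> surface activity -> Monte Carlo tally -> depth
dose -> field map, logs one line per stage, and returns a :class:`Report`
that can be written as JSON + CSV.  Stage failures propagate as
:class:`~aunp_radiodose.errors.PipelineStageError` with the stage name.
"""
from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .beta_transport import (
    MicroCellTally,
    ShellTally,
    TumorModel,
    depth_dose_profile,
    run_tally,
)
from .dosimetry_core import SourceLoading, surface_activity
from .errors import PipelineStageError
from .nuclear_optical_data import beta_spectrum, load_au198
from .plasmonics import GridSpec, NanoParticle, field_map

__all__ = ["Scenario", "Report", "run_scenario", "generate_fixture_scenarios",
           "default_depths_mm"]

log = logging.getLogger("aunp_radiodose.pipeline")


def default_depths_mm(tumor_radius_cm: float) -> tuple[float, ...]:
    """Tally depths 0.3, 0.8, ... mm, in 0.5 mm steps, staying inside the tumor."""
    out, d = [], 0.3
    while d <= 10.0 * tumor_radius_cm - 0.2 + 1e-9:
        out.append(round(d, 1))
        d += 0.5
    return tuple(out)


@dataclass(frozen=True)
class Scenario:
    """A complete, serializable description of one diagnosis+therapy run."""

    name: str
    tumor_radius_cm: float = 0.25
    tumor_density_g_cm3: float = 1.05
    np_core_nm: float = 30.0
    np_hydro_nm: float = 70.0
    half_life_d: float = 2.7
    particles_per_decay: float = 1.0
    c_r: float = 1.0
    specific_activity_fraction: float = 1.0
    covering_fraction: float = 0.5
    uptake_fraction: float = 0.6
    footprint_area_cm2: Optional[float] = None
    lambda_bio_per_h: float = 0.0
    wavelength_nm: float = 250.0
    eps_medium: float = 1.77
    n_histories: int = 100_000
    seed: int = 12345
    tally_mode: str = "shells"
    depths_mm: Optional[tuple[float, ...]] = None
    shell_thickness_mm: float = 0.5
    scattering: bool = False
    fieldmap_extent_nm: float = 60.0
    fieldmap_points_per_axis: int = 21

    def __post_init__(self) -> None:
        if self.tally_mode not in ("shells", "microcells"):
            raise ValueError("tally_mode must be 'shells' or 'microcells'")
        if self.n_histories < 1000:
            raise ValueError("n_histories must be at least 1000")
        if self.depths_mm is not None:
            object.__setattr__(
                self, "depths_mm", tuple(float(d) for d in self.depths_mm)
            )

    # -- derived pieces -------------------------------------------------
    @property
    def tumor(self) -> TumorModel:
        return TumorModel(self.tumor_radius_cm, self.tumor_density_g_cm3)

    @property
    def nanoparticle(self) -> NanoParticle:
        return NanoParticle(self.np_core_nm, self.np_hydro_nm)

    def loading(self) -> SourceLoading:
        return SourceLoading.from_nanoparticle(
            self.nanoparticle,
            c_r=self.c_r,
            specific_activity_fraction=self.specific_activity_fraction,
            covering_fraction=self.covering_fraction,
            uptake_fraction=self.uptake_fraction,
            footprint_area_cm2=self.footprint_area_cm2,
        )

    def resolved_depths_mm(self) -> tuple[float, ...]:
        return (
            self.depths_mm
            if self.depths_mm is not None
            else default_depths_mm(self.tumor_radius_cm)
        )

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["depths_mm"] is not None:
            d["depths_mm"] = list(d["depths_mm"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        if d.get("depths_mm") is not None:
            d["depths_mm"] = tuple(d["depths_mm"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class Report:
    """Everything one run produced, with units in the serialized form."""

    scenario: dict
    activity_mci: float
    lambda_eff_per_h: float
    depth_mm: tuple
    dose_gy: tuple
    dose_stderr_gy: tuple
    t_mev_per_g: tuple
    t_stderr: tuple
    max_dose_gy: float
    max_dose_depth_mm: float
    max_enhancement: float
    max_enhancement_at_nm: tuple
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, exc) from exc

    return wrap


def run_scenario(scenario: Scenario, outdir=None) -> Report:
    """Execute the full chain for one scenario; deterministic given its seed."""
    nuclide = _stage("reference-data")(
        load_au198, half_life_d=scenario.half_life_d,
        particles_per_decay=scenario.particles_per_decay,
    )
    spectrum = _stage("reference-data")(beta_spectrum, nuclide, 512)
    log.info(
        "stage=reference-data nuclide=%s e_mean=%.4f MeV", nuclide.name,
        nuclide.e_mean_mev,
    )

    activity = _stage("activity")(
        surface_activity, scenario.loading(), scenario.tumor_radius_cm, nuclide
    )
    log.info("stage=activity A=%.4g mCi", activity)

    depths = scenario.resolved_depths_mm()
    if scenario.tally_mode == "shells":
        tally = _stage("tally-geometry")(
            ShellTally.from_depths, scenario.tumor, depths,
            scenario.shell_thickness_mm,
        )
    else:
        tally = _stage("tally-geometry")(
            MicroCellTally.from_depths, scenario.tumor, depths
        )
    result = _stage("transport")(
        run_tally, scenario.tumor, tally, scenario.n_histories, scenario.seed,
        nuclide=nuclide, spectrum=spectrum, scattering=scenario.scattering,
    )
    log.info(
        "stage=transport histories=%d seed=%d mode=%s",
        scenario.n_histories, scenario.seed, scenario.tally_mode,
    )

    profile = _stage("dose")(
        depth_dose_profile, result, activity, nuclide, scenario.lambda_bio_per_h
    )
    dmax, dmax_depth = profile.max_dose()
    log.info("stage=dose max=%.4g Gy at %.1f mm", dmax, dmax_depth)

    ext, npts = scenario.fieldmap_extent_nm, scenario.fieldmap_points_per_axis
    grid = GridSpec((-ext, ext, npts), (-ext, ext, npts), (-ext, ext, npts))
    fmap = _stage("fieldmap")(
        field_map, [scenario.nanoparticle], scenario.wavelength_nm, grid,
        eps_medium=scenario.eps_medium,
    )
    fmax, floc = fmap.max_enhancement()
    log.info("stage=fieldmap max_enhancement=%.3f", fmax)

    report = Report(
        scenario=scenario.to_dict(),
        activity_mci=float(activity),
        lambda_eff_per_h=float(profile.lambda_eff_per_h),
        depth_mm=tuple(float(x) for x in profile.depth_mm),
        dose_gy=tuple(float(x) for x in profile.dose_gy),
        dose_stderr_gy=tuple(float(x) for x in profile.dose_stderr_gy),
        t_mev_per_g=tuple(float(x) for x in profile.t_mev_per_g),
        t_stderr=tuple(float(x) for x in profile.t_stderr),
        max_dose_gy=float(dmax),
        max_dose_depth_mm=float(dmax_depth),
        max_enhancement=float(fmax),
        max_enhancement_at_nm=tuple(float(x) for x in floc),
        provenance={
            "seed": scenario.seed,
            "n_histories": scenario.n_histories,
            "version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    )

    if outdir is not None:
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        profile.to_csv(out / "depth_dose.csv")
        # central x-y plane keeps the on-disk map compact; the full 3-D
        # map is regenerable from the scenario
        fmap.plane_frame("z", 0.0).to_csv(out / "fieldmap.csv", index=False)
    return report


def generate_fixture_scenarios() -> list[Scenario]:
    """The two reference tumor scenarios plus a fast smoke scenario.

    Both reference scenarios use the 30/70 nm nanoparticle, the 2.7 d
    half-life and 60% uptake; the smoke scenario runs 10^3 histories on a
    coarse field grid so the full chain finishes in seconds.
    """
    common = dict(np_core_nm=30.0, np_hydro_nm=70.0, uptake_fraction=0.6)
    return [
        Scenario(name="tumor-r0.25cm", tumor_radius_cm=0.25, **common),
        Scenario(name="tumor-r0.5cm", tumor_radius_cm=0.5, **common),
        Scenario(
            name="smoke", tumor_radius_cm=0.25, n_histories=1000,
            fieldmap_points_per_axis=9, **common,
        ),
    ]
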