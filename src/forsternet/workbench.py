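"""Configuration-driven pipeline: couplings -> rates -> excitons -> absorbance.

A :class:`RunConfig` (YAML or dict, strict schema) names either a structure
file plus spectra manifest or a synthetic fixture spec, together with the
model knobs (medium refractive index, IC lifetimes, bands, configuration
variants, windows, seed).  The three stage runners write delimited-text and
JSON reports whose headers embed the tool version, a config hash and the
seed, so re-running an identical config reproduces outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .absorbance import Irradiance, contribution_report
from .core import Band, PigmentClass, SpectralRole
from .coupling import (
    Medium,
    class_pair_averages,
    coupling_matrix,
    dipoles_for_band,
    export_coupling,
)
from .excitons import (
    STANDARD_CONFIGURATIONS,
    PigmentConfiguration,
    apply_configuration,
    build_hamiltonian,
    build_site_energy_table,
    diagonalize,
    ipr_summary,
)
from .kinetics import ICModel, export_efficiencies, site_eet_summary
from .spectra import AxisKind, SpectralLibrary, Spectrum, ValueKind
from .structure_io import AxisTable, ResidueMap, default_axis_table, parse_pigment_sites
from .synthetic_data import (
    FixtureSpec,
    make_toy_complex,
    make_toy_irradiance,
    make_toy_shift_table,
    make_toy_spectral_library,
    make_wt_census,
)

log = logging.getLogger("forsternet")

_KNOWN_KEYS = {
    "seed",
    "structure",
    "residue_map",
    "axis_table",
    "spectra_manifest",
    "fixture",
    "medium_n",
    "bands",
    "multimer_order",
    "ic_lifetimes_ns",
    "variants",
    "crt_in_q",
    "weight_threshold",
    "windows",
    "scenes",
    "depth_m",
    "cl_factor",
    "shift_scale_ev",
    "output_dir",
}

_FIXTURE_KEYS = {
    "seed",
    "n_chl_a",
    "n_chl_b",
    "n_chl_c1",
    "n_crt",
    "box_angstrom",
    "min_distance_angstrom",
}

_VARIANTS = {c.label: c for c in STANDARD_CONFIGURATIONS}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected at load."""

    seed: int = 2024
    structure: Optional[str] = None
    residue_map: Optional[str] = None
    axis_table: Optional[str] = None
    spectra_manifest: Optional[str] = None
    fixture: dict = field(
        default_factory=lambda: {"n_chl_a": 8, "n_chl_b": 3, "n_crt": 3}
    )
    medium_n: float = 1.4
    bands: tuple = ("Q", "B")
    multimer_order: int = 1
    ic_lifetimes_ns: dict = field(default_factory=dict)
    variants: tuple = ("WT", "ALL_CHL_A", "NO_CRT", "ALL_CHL_A_NO_CRT")
    crt_in_q: bool = True
    weight_threshold: float = 0.1
    windows: dict = field(default_factory=lambda: {"full": (350.0, 800.0), "b_band": (350.0, 500.0)})
    scenes: tuple = ("surface", "depth")
    depth_m: float = 100.0
    cl_factor: Optional[float] = None
    shift_scale_ev: float = 0.02
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for name, window in self.windows.items():
            lo, hi = window
            if hi <= lo:
                raise ValueError(f"window {name!r} is malformed: ({lo}, {hi})")
        for label in self.variants:
            if label not in _VARIANTS:
                raise ValueError(f"unknown configuration variant {label!r}")
        for band in self.bands:
            Band(band)
        for path_attr in ("structure", "residue_map", "axis_table", "spectra_manifest"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{path_attr} path does not exist: {p}")
        unknown_fixture = set(self.fixture) - _FIXTURE_KEYS
        if unknown_fixture:
            raise ValueError(f"unknown fixture keys: {sorted(unknown_fixture)}")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(raw)
        for key in ("bands", "variants", "scenes"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def header(self) -> dict:
        return {"tool": f"forsternet {__version__}", "config": self.config_hash, "seed": self.seed}


# ---------------------------------------------------------------------------
# Input assembly


def load_spectral_library(manifest_path: str | Path) -> SpectralLibrary:
    """Load a spectral library from a YAML manifest.

    The manifest maps dotted keys ``class.band.role`` to two-column spectrum
    files (paths relative to the manifest), plus optional top-level
    ``peaks_nm`` and ``dipoles_debye`` maps with dotted ``class.band`` keys.
    """
    base = Path(manifest_path).parent
    raw = yaml.safe_load(Path(manifest_path).read_text()) or {}
    spectra: dict = {}
    peaks: dict = {}
    dipoles: dict = {}
    value_kinds = {
        SpectralRole.ABSORPTION: ValueKind.ABSORBANCE,
        SpectralRole.EMISSION: ValueKind.EMISSION,
        SpectralRole.EXTINCTION: ValueKind.EXTINCTION,
    }
    for key, val in raw.items():
        if key == "peaks_nm":
            for k, v in val.items():
                cls_name, band_name = k.split(".")
                peaks[(PigmentClass(cls_name), Band(band_name))] = float(v)
            continue
        if key == "dipoles_debye":
            for k, v in val.items():
                cls_name, band_name = k.split(".")
                dipoles[(PigmentClass(cls_name), Band(band_name))] = float(v)
            continue
        cls_name, band_name, role_name = key.split(".")
        role = SpectralRole(role_name)
        spec = Spectrum.from_text(base / val, AxisKind.WAVELENGTH_NM, value_kinds[role])
        spectra[(PigmentClass(cls_name), Band(band_name), role)] = spec
    for (cls, band, role), spec in spectra.items():
        if role is SpectralRole.ABSORPTION and (cls, band) not in peaks:
            peaks[(cls, band)] = spec.peak_position()
    return SpectralLibrary(spectra=spectra, peaks_nm=peaks, dipoles_debye=dipoles)


@dataclass
class StudyInputs:
    """Materialized inputs for one run: pigments, tables, spectra, scenes."""

    pigments: list
    axis_table: AxisTable
    library: SpectralLibrary
    shifts_cm1: dict
    fixture: Optional[FixtureSpec]

    @property
    def classes(self) -> dict:
        return {p.site_id: p.pigment_class for p in self.pigments}


def assemble_inputs(config: RunConfig) -> StudyInputs:
    """Build pigments + spectral library either from files or the fixture."""
    if config.structure is not None:
        residue_map = (
            ResidueMap.from_text(config.residue_map) if config.residue_map else None
        )
        axis_table = (
            AxisTable.from_text(config.axis_table) if config.axis_table else default_axis_table()
        )
        pigments, report = parse_pigment_sites(config.structure, residue_map, None, axis_table)
        log.info("parsed %s: %s", config.structure, report)
        if config.spectra_manifest is None:
            raise ValueError("structure runs require a spectra manifest")
        library = load_spectral_library(config.spectra_manifest)
        shifts: dict = {}
        fixture = None
    else:
        fixture = FixtureSpec(seed=config.seed, **{k: v for k, v in config.fixture.items() if k != "seed"})
        pigments, axis_table = make_toy_complex(fixture)
        library = make_toy_spectral_library(fixture)
        shifts = make_toy_shift_table(pigments, config.seed, config.shift_scale_ev)
    return StudyInputs(pigments, axis_table, library, shifts, fixture)


def _ic_model(config: RunConfig) -> ICModel:
    model = ICModel.default()
    for key, tau in config.ic_lifetimes_ns.items():
        cls_name, band_name = key.split(".")
        model.lifetimes_ns[(PigmentClass(cls_name), Band(band_name))] = float(tau)
    return model


# ---------------------------------------------------------------------------
# Stage runners


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2f s", stage, time.perf_counter() - self.t0)

    return _Timer()


def run_couplings(config: RunConfig, inputs: Optional[StudyInputs] = None) -> dict:
    """Coupling matrices and class-pair averages per requested band."""
    inputs = inputs or assemble_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    medium = Medium(config.medium_n)
    out: dict = {"matrices": {}, "averages": {}}
    with _timed("couplings"):
        for band_name in config.bands:
            band = Band(band_name)
            dipoles = dipoles_for_band(inputs.pigments, inputs.axis_table, inputs.library, band)
            matrix = coupling_matrix([p.site_id for p in inputs.pigments], dipoles, band, medium)
            averages = class_pair_averages(matrix, inputs.classes, config.multimer_order)
            export_coupling(matrix, outdir / f"couplings_{band.value}.tsv", config.header())
            avg_path = outdir / f"class_pair_averages_{band.value}.tsv"
            avg_path.write_text(
                "# " + json.dumps(config.header(), sort_keys=True) + "\n"
                + averages.to_csv(sep="\t", index=False, float_format="%.6e")
            )
            out["matrices"][band] = matrix
            out["averages"][band] = averages
    return out


def run_rates(config: RunConfig, inputs: Optional[StudyInputs] = None) -> dict:
    """Per-donor FRET rate tables and EET efficiencies per band."""
    inputs = inputs or assemble_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ic_model = _ic_model(config)
    couplings = run_couplings(config, inputs)
    out: dict = {}
    with _timed("rates"):
        for band, matrix in couplings["matrices"].items():
            table, efficiencies = site_eet_summary(matrix, inputs.library, ic_model, inputs.classes)
            table.to_text(outdir / f"rates_{band.value}.tsv")
            export_efficiencies(
                efficiencies, outdir / f"efficiencies_{band.value}.json", config.header()
            )
            out[band] = {"rates": table, "efficiencies": efficiencies}
    return out


def run_excitons(config: RunConfig, inputs: Optional[StudyInputs] = None) -> dict:
    """Per-band, per-variant exciton results and the IPR^-1 summary table."""
    inputs = inputs or assemble_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    medium = Medium(config.medium_n)
    variants = [_VARIANTS[label] for label in config.variants] or [_VARIANTS["WT"]]
    results: dict = {}
    with _timed("excitons"):
        for variant in variants:
            pigments_v = apply_configuration(inputs.pigments, variant)
            for band_name in config.bands:
                band = Band(band_name)
                pigs = pigments_v
                if band is Band.Q and not config.crt_in_q:
                    pigs = [p for p in pigs if p.pigment_class is not PigmentClass.CRT]
                    if not pigs:
                        continue
                dipoles = dipoles_for_band(pigs, inputs.axis_table, inputs.library, band)
                matrix = coupling_matrix([p.site_id for p in pigs], dipoles, band, medium)
                energies = build_site_energy_table(
                    pigs, band, inputs.library, inputs.shifts_cm1
                )
                res = diagonalize(build_hamiltonian(energies, matrix))
                results[(variant.label, band)] = res
    summary = ipr_summary(results)
    summary_path = Path(config.output_dir) / "ipr_summary.tsv"
    summary_path.write_text(
        "# " + json.dumps({**config.header(), "crt_in_q": config.crt_in_q}, sort_keys=True)
        + "\n"
        + summary.to_csv(sep="\t", index=False, float_format="%.6f")
    )
    return {"results": results, "summary": summary}


def run_absorbance(config: RunConfig, inputs: Optional[StudyInputs] = None) -> dict:
    """Per-class photon-absorption contributions per window and scene."""
    inputs = inputs or assemble_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if inputs.fixture is None:
        raise ValueError("absorbance stage currently requires a fixture-based census")
    census = make_wt_census(inputs.fixture, config.cl_factor)
    report: dict = {"metadata": config.header(), "scenes": {}}
    with _timed("absorbance"):
        for scene in config.scenes:
            irr: Irradiance = make_toy_irradiance(scene, config.depth_m)
            report["scenes"][scene] = contribution_report(
                census, inputs.library, irr, config.windows
            )
    (outdir / "absorbance_contributions.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n"
    )
    return report
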