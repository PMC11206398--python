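"""End-to-end analysis driver: ensembles -> thermo -> alignment -> spectra -> report.

Given a set of per-compound manifests, :func:`run_pipeline` computes, for
each compound, conformer strain energies and Boltzmann populations, the
plane-anchored crystal-vs-minimum RMSD, the principal absorption band of the
global minimum and crystal pose with its Δλmax shift, and broadened +
difference spectra; it then assembles the per-compound descriptor table and
the correlation block (dipole vs ln IC50, Δλmax vs ln IC50, blue-shift
potency separation). Failures are isolated per compound and collected on the
result rather than aborting the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import align as _align
from . import potency as _potency
from . import spectra as _spectra
from . import thermo as _thermo
from .ensembles import CompoundEnsemble
from .errors import ValidationError
from .io import load_ensemble

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "build_descriptor_table"]

logger = logging.getLogger(__name__)

DESCRIPTOR_COLUMNS = [
    "substituent",
    "dipole_gm_D",
    "lambda_cal_nm",
    "f_cal",
    "lambda_crystal_nm",
    "f_crystal",
    "delta_lambda_nm",
    "shift_class",
    "ic50_nM",
    "ln_ic50",
    "rmsd_A",
    "strain_crystal_kcal_mol",
    "pop_gm_pct",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of one analysis run.

    ``anchors`` are atom *names* resolved through each manifest's atom map;
    compounds whose map lacks an anchor fall back to full Kabsch
    superposition for the RMSD.
    """

    manifests: tuple[Path, ...]
    temperature_K: float = _thermo.ROOM_TEMPERATURE_K
    f_threshold: float = 0.5
    fwhm_eV: float = _spectra.DEFAULT_FWHM_EV
    grid: tuple[float, float, float] = _spectra.DEFAULT_GRID
    subset_policy: str = "heavy_atoms"
    anchors: tuple[str, ...] = ("C1", "C4", "C10")
    lambda_window: Optional[tuple[float, float]] = None
    output_dir: Optional[Path] = None

    def __post_init__(self):
        object.__setattr__(
            self, "manifests", tuple(Path(m) for m in self.manifests)
        )
        if len(self.manifests) == 0:
            raise ValidationError("pipeline needs at least one compound manifest")
        for m in self.manifests:
            if not m.exists():
                raise ValidationError(f"manifest not found: {m}")
        if self.output_dir is not None:
            out = Path(self.output_dir).resolve()
            object.__setattr__(self, "output_dir", out)
            for m in self.manifests:
                if out == m.resolve().parent or out in m.resolve().parents:
                    raise ValidationError(
                        f"output_dir {out} would overwrite inputs under it"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path, output_dir: Optional[Path] = None) -> "PipelineConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        base = path.parent
        grid = doc.get("grid", _spectra.DEFAULT_GRID)
        window = doc.get("lambda_window")
        return cls(
            manifests=tuple(base / m for m in doc["compounds"]),
            temperature_K=float(doc.get("temperature_K", _thermo.ROOM_TEMPERATURE_K)),
            f_threshold=float(doc.get("f_threshold", 0.5)),
            fwhm_eV=float(doc.get("fwhm_eV", _spectra.DEFAULT_FWHM_EV)),
            grid=tuple(float(g) for g in grid),
            subset_policy=doc.get("subset_policy", "heavy_atoms"),
            anchors=tuple(doc.get("anchors", ("C1", "C4", "C10"))),
            lambda_window=None if window is None else tuple(window),
            output_dir=output_dir,
        )


@dataclass
class PipelineResult:
    descriptor_table: pd.DataFrame
    correlations: dict
    strain_tables: dict  # substituent -> StrainTable (with populations)
    failures: dict  # substituent/manifest -> error message
    run_manifest: dict
    output_files: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _analyze_compound(ensemble: CompoundEnsemble, config: PipelineConfig) -> dict:
    row: dict = {c: np.nan for c in DESCRIPTOR_COLUMNS}
    row["substituent"] = ensemble.substituent
    gm = ensemble.global_minimum
    row["dipole_gm_D"] = gm.dipole_moment

    strain = _thermo.strain_energies(ensemble)
    pops = _thermo.boltzmann_populations(strain, config.temperature_K)
    row["pop_gm_pct"] = 100.0 * pops.population_of(gm.label)

    crystal = ensemble.crystal_reference
    if crystal is not None:
        row["strain_crystal_kcal_mol"] = float(
            strain.strain_kcal[list(strain.labels).index(crystal.label)]
        )
        anchors = config.anchors if all(
            a in ensemble.atom_map for a in config.anchors
        ) else None
        row["rmsd_A"] = _align.crystal_vs_minimum_rmsd(
            ensemble, policy=config.subset_policy, anchors=anchors
        )

    spectra_out: dict[str, _spectra.BroadenedSpectrum] = {}
    if gm.label in ensemble.stick_spectra:
        lam, f = _spectra.lambda_max(
            ensemble.sticks_for(gm),
            f_threshold=config.f_threshold,
            window=config.lambda_window,
        )
        row["lambda_cal_nm"], row["f_cal"] = lam, f
        spectra_out["global_minimum"] = _spectra.broaden(
            ensemble.sticks_for(gm), config.fwhm_eV, config.grid
        )
    if crystal is not None and crystal.label in ensemble.stick_spectra:
        lam, f = _spectra.lambda_max(
            ensemble.sticks_for(crystal),
            f_threshold=config.f_threshold,
            window=config.lambda_window,
        )
        row["lambda_crystal_nm"], row["f_crystal"] = lam, f
        spectra_out["crystal"] = _spectra.broaden(
            ensemble.sticks_for(crystal), config.fwhm_eV, config.grid
        )
    if not np.isnan(row["lambda_cal_nm"]) and not np.isnan(row["lambda_crystal_nm"]):
        shift = _spectra.peak_shift(
            row["lambda_cal_nm"], row["lambda_crystal_nm"], ensemble.substituent
        )
        row["delta_lambda_nm"] = shift.delta_lambda_nm
        row["shift_class"] = shift.shift_class
        if len(spectra_out) == 2:
            spectra_out["difference_cal_minus_crystal"] = _spectra.difference_spectrum(
                spectra_out["global_minimum"], spectra_out["crystal"]
            )
    if ensemble.ic50_nM is not None:
        row["ic50_nM"] = ensemble.ic50_nM
        row["ln_ic50"] = _potency.ln_ic50(ensemble.ic50_nM)
    return {"row": row, "strain": pops, "spectra": spectra_out}


def build_descriptor_table(rows: Sequence[dict]) -> pd.DataFrame:
    table = pd.DataFrame(list(rows))
    return table.reindex(columns=DESCRIPTOR_COLUMNS)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis over every configured compound.

    Deterministic given identical inputs. Per-compound exceptions are caught
    and collected in ``result.failures`` (the CLI turns a non-empty failure
    set into a nonzero exit status); an empty compound list is rejected at
    configuration time.
    """
    rows: list[dict] = []
    strain_tables: dict = {}
    failures: dict[str, str] = {}
    all_spectra: dict[str, dict] = {}

    for manifest in config.manifests:
        name = str(manifest)
        try:
            ensemble = load_ensemble(manifest)
            name = ensemble.substituent
            out = _analyze_compound(ensemble, config)
        except Exception as exc:  # isolate per-compound failures
            logger.error("compound %s failed: %s", name, exc)
            failures[name] = str(exc)
            continue
        rows.append(out["row"])
        strain_tables[name] = out["strain"]
        all_spectra[name] = out["spectra"]

    table = build_descriptor_table(rows)

    correlations: dict = {}
    usable = table.dropna(subset=["ln_ic50"]) if "ln_ic50" in table else table.iloc[0:0]
    if len(usable) >= 3:
        correlations["dipole_vs_ln_ic50"] = _potency.correlate(
            usable["dipole_gm_D"], usable["ln_ic50"]
        )
        with_shift = usable.dropna(subset=["delta_lambda_nm"])
        if len(with_shift) >= 3:
            correlations["delta_lambda_vs_ln_ic50"] = _potency.correlate(
                with_shift["delta_lambda_nm"], with_shift["ln_ic50"]
            )
            correlations["shift_potency"] = _potency.shift_potency_report(with_shift)

    run_manifest = {
        "parameters": {
            "temperature_K": config.temperature_K,
            "f_threshold": config.f_threshold,
            "fwhm_eV": config.fwhm_eV,
            "grid": list(config.grid),
            "subset_policy": config.subset_policy,
            "anchors": list(config.anchors),
            "lambda_window": None
            if config.lambda_window is None
            else list(config.lambda_window),
        },
        "inputs": {str(m): _sha256(m) for m in config.manifests},
        "failures": failures,
    }

    output_files: list[Path] = []
    if config.output_dir is not None:
        outdir = config.output_dir
        outdir.mkdir(parents=True, exist_ok=True)
        table_path = outdir / "descriptor_table.csv"
        table.to_csv(table_path, index=False)
        output_files.append(table_path)
        for sub, tab in strain_tables.items():
            p = outdir / f"{sub}_populations.csv"
            tab.to_csv(p)
            output_files.append(p)
        for sub, specs in all_spectra.items():
            for kind, spec in specs.items():
                p = outdir / f"{sub}_{kind}_spectrum.csv"
                spec.to_csv(p)
                output_files.append(p)
        corr_doc = {
            k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
            for k, v in correlations.items()
        }
        (outdir / "correlations.json").write_text(json.dumps(corr_doc, indent=2))
        (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
        output_files += [outdir / "correlations.json", outdir / "run_manifest.json"]

    return PipelineResult(
        descriptor_table=table,
        correlations=correlations,
        strain_tables=strain_tables,
        failures=failures,
        run_manifest=run_manifest,
        output_files=output_files,
    )
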