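"""Synthetic ensemble bundles with known ground truth.

The generator emulates the data shapes of a halogen-substituted
4-anilinoquinazoline study: per compound, a global-minimum conformer, a
handful of low-lying local minima within a few kcal/mol, and a crystal-pose
reference lying higher in energy; per structure, a 30-state singlet stick
spectrum with one dominant transition near 330 nm (f between 0.5 and 0.7)
above a congested 180-320 nm region; and a monotone dipole-to-potency link.
Geometries are built from a hard-coded idealized heavy-atom scaffold whose
only degrees of freedom are the anilino-phenyl dihedral and the two methoxy
torsions, so structural ground truth is exactly the applied perturbation.

Nothing here aims at quantum-chemical realism — the point is that every
latent quantity (strain ordering, spectral-shift sign, crystal RMSD, the
dipole-potency link) is recorded in a :class:`GroundTruth` object so the
analysis pipeline can be checked end to end.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import align as _align
from . import spectra as _spectra
from . import thermo as _thermo
from .ensembles import (
    CompoundEnsemble,
    ConformerRecord,
    ExcitedState,
    Geometry,
    Role,
    StickSpectrum,
)
from .errors import ValidationError
from .io import write_stick_table, write_xyz

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "CompoundTruth",
    "anilinoquinazoline_template",
    "apply_torsion",
    "generate_bundle",
    "recovery_check",
    "RecoveryReport",
    "write_bundle_tree",
]

# Total electronic energies (hartree) of the real series' global minima,
# used as energy baselines so synthetic energies have realistic magnitudes.
_ENERGY_BASE = {
    "H": -933.798880,
    "F": -1033.081728,
    "Cl": -1393.425183,
    "Br": -3507.379134,
    "I": -1230.996026,
}

# Global-minimum dipole moments (Debye) of the real series; the default
# dipole->potency link is anchored on these.
_SERIES_DIPOLES = {"H": 5.8286, "F": 7.7915, "Cl": 8.0755, "Br": 8.2320, "I": 7.9890}

_BOND = 1.40  # idealized aromatic bond length, Å


def _hexagon(center: np.ndarray, u: np.ndarray, v: np.ndarray, phase: float = 0.0):
    """Six vertices of a regular hexagon in the plane spanned by u, v."""
    pts = []
    for k in range(6):
        ang = phase + k * math.pi / 3.0
        pts.append(center + _BOND * (math.cos(ang) * u + math.sin(ang) * v))
    return pts


def anilinoquinazoline_template(substituent: str) -> tuple[Geometry, dict]:
    """Idealized heavy-atom 4-anilinoquinazoline scaffold with substituent X.

    Returns the geometry plus a metadata dict with the named anchor atoms
    (C1, C4, C10 on the quinazoline core), the anilino-phenyl torsion axis
    and its moving atoms, and the two methoxy torsion handles.
    """
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])

    # fused bicyclic core: ring A at the origin, ring B across the 0-1 edge
    ring_a = _hexagon(np.zeros(3), ex, ey)
    shared_mid = 0.5 * (ring_a[0] + ring_a[1])
    ring_b_center = 2.0 * shared_mid
    ring_b_all = _hexagon(ring_b_center, ex, ey)
    ring_b_new = [ring_b_all[k] for k in (0, 1, 2, 5)]

    symbols = ["C", "C", "N", "C", "N", "C"] + ["C"] * 4
    coords = list(ring_a) + ring_b_new

    # anilino bridge: N-H linker then the X-phenyl ring, grown radially
    # outward from ring-A vertex 3
    u = ring_a[3] / np.linalg.norm(ring_a[3])
    n_linker = ring_a[3] + _BOND * u
    ipso = ring_a[3] + 2.0 * _BOND * u
    phenyl_center = ring_a[3] + 3.0 * _BOND * u

    # base phenyl plane tilted 30 degrees out of the core plane
    perp = np.cross(ez, u)
    perp /= np.linalg.norm(perp)
    tilt = math.radians(30.0)
    w = math.cos(tilt) * perp + math.sin(tilt) * ez
    phenyl = _hexagon(phenyl_center, u, w, phase=math.pi)  # vertex 0 == ipso

    symbols += ["N"]
    coords += [n_linker]
    symbols += ["C"] * 6
    coords += [phenyl[0]] + phenyl[1:]

    # halogen (or H) at the phenyl meta position, radial from the ring center
    meta = phenyl[2]
    out = (meta - phenyl_center) / np.linalg.norm(meta - phenyl_center)
    x_pos = meta + _BOND * out
    symbols += [substituent]
    coords += [x_pos]

    # two methoxy arms (-O-CH3) on the carbocyclic ring
    methoxy_meta = []
    for ring_atom_idx, pt in ((6, ring_b_new[0]), (7, ring_b_new[1])):
        r = (pt - ring_b_center) / np.linalg.norm(pt - ring_b_center)
        o_pos = pt + _BOND * r
        c_pos = o_pos + _BOND * (0.8 * r + 0.6 * ez)
        symbols += ["O", "C"]
        coords += [o_pos, c_pos]
        o_idx, c_idx = len(symbols) - 2, len(symbols) - 1
        methoxy_meta.append({"axis": (ring_atom_idx, o_idx), "moving": [c_idx]})

    geometry = Geometry(tuple(symbols), np.array(coords))
    meta_info = {
        "anchors": {"C1": 0, "C4": 3, "C10": 6},
        "phenyl_axis": (10, 11),
        "phenyl_moving": list(range(12, 18)),  # ring beyond ipso + X
        "methoxy": methoxy_meta,
    }
    return geometry, meta_info


def apply_torsion(
    coords: np.ndarray,
    axis: tuple[int, int],
    moving: Sequence[int],
    angle_deg: float,
) -> np.ndarray:
    """Rotate ``moving`` atoms about the axis through two atoms (Rodrigues)."""
    out = np.array(coords, dtype=float)
    a, b = out[axis[0]], out[axis[1]]
    k = b - a
    k = k / np.linalg.norm(k)
    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    for i in moving:
        v = out[i] - a
        out[i] = a + v * c + np.cross(k, v) * s + k * np.dot(k, v) * (1 - c)
    return out


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the synthetic study, with defaults set to the study conditions.

    Five compounds (X = H, F, Cl, Br, I), five conformers each within
    3 kcal/mol of the minimum, crystal references up to ~9 kcal/mol, 30
    singlet states with the principal band near 330 nm (f 0.5-0.7), the real
    series' global-minimum dipoles driving a monotone decreasing
    dipole -> ln IC50 link, and blue spectral shifts for the most potent
    compounds with |Δλmax| in the observed 1.1-3.3 nm range.
    """

    seed: int
    substituents: tuple[str, ...] = ("H", "F", "Cl", "Br", "I")
    conformers_per_compound: int = 5
    strain_energy_scale_kcal: float = 3.0
    crystal_strain_range_kcal: tuple[float, float] = (0.8, 9.0)
    n_states: int = 30
    principal_band_center_nm: float = 330.0
    principal_f_range: tuple[float, float] = (0.5, 0.7)
    weak_band_range_nm: tuple[float, float] = (180.0, 318.0)
    weak_f_max: float = 0.45
    dipole_range_D: tuple[float, float] = (0.5, 9.0)
    gm_dipoles_D: Optional[tuple[float, ...]] = None
    potency_slope_per_D: float = -2.94
    potency_intercept: float = 20.51
    potency_noise_sd: float = 0.3
    delta_lambda_range_nm: tuple[float, float] = (1.1, 3.3)
    blue_fraction: float = 0.4
    spectral_jitter_sd_nm: float = 0.5
    crystal_torsion_deg: tuple[float, float] = (4.0, 42.0)
    conformer_torsion_deg: float = 30.0

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed is mandatory and must be an integer")
        if self.conformers_per_compound < 1:
            raise ValidationError("need at least one conformer per compound")
        if self.n_states < 1:
            raise ValidationError("need at least one excited state")
        for name in (
            "principal_f_range",
            "weak_band_range_nm",
            "dipole_range_D",
            "delta_lambda_range_nm",
            "crystal_strain_range_kcal",
            "crystal_torsion_deg",
        ):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValidationError(f"invalid range for {name}: ({lo}, {hi})")
        if self.principal_f_range[0] < 0.5:
            raise ValidationError(
                "principal_f_range must stay >= 0.5 so the principal band "
                "always satisfies the oscillator-strength rule"
            )
        if self.weak_f_max >= 0.5:
            raise ValidationError("weak_f_max must stay below the f >= 0.5 rule")
        if self.weak_band_range_nm[1] >= 320.0:
            raise ValidationError("weak bands must stay below the 320 nm window")
        if not (0 <= self.blue_fraction <= 1):
            raise ValidationError("blue_fraction must lie in [0, 1]")
        if self.strain_energy_scale_kcal <= 0:
            raise ValidationError("strain_energy_scale_kcal must be positive")
        if self.gm_dipoles_D is not None and len(self.gm_dipoles_D) != len(
            self.substituents
        ):
            raise ValidationError("gm_dipoles_D length must match substituents")

    @property
    def n_compounds(self) -> int:
        return len(self.substituents)


@dataclass(frozen=True)
class CompoundTruth:
    """Latent parameters behind one generated compound."""

    substituent: str
    dipole_gm_D: float
    ln_ic50_true: float
    ln_ic50_observed: float
    delta_lambda_true_nm: float
    shift_sign: int  # -1 blue, +1 red
    crystal_torsion_deg: float
    crystal_rmsd_A: float
    crystal_strain_kcal: float
    strain_order: tuple[str, ...]  # non-crystal labels, ascending strain
    strain_kcal: dict


@dataclass(frozen=True)
class GroundTruth:
    seed: int
    compounds: dict  # substituent -> CompoundTruth

    def to_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "compounds": {
                k: dataclasses.asdict(v) for k, v in self.compounds.items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        compounds = {}
        for k, v in doc["compounds"].items():
            v = dict(v)
            v["strain_order"] = tuple(v["strain_order"])
            compounds[k] = CompoundTruth(**v)
        return cls(seed=doc["seed"], compounds=compounds)


def _principal_state(wavelength: float, f: float) -> ExcitedState:
    return ExcitedState(
        index=1,
        wavelength_nm=wavelength,
        oscillator_strength=f,
        transition_label="HOMO->LUMO",
        contribution_percent=49.0,
    )


def _stick_spectrum(
    rng: np.random.Generator, spec: GeneratorSpec, owner: str, principal_nm: float
) -> StickSpectrum:
    f_principal = rng.uniform(*spec.principal_f_range)
    weak_wl = rng.uniform(*spec.weak_band_range_nm, size=spec.n_states - 1)
    weak_f = rng.uniform(0.01, spec.weak_f_max, size=spec.n_states - 1)
    states = [_principal_state(principal_nm, f_principal)]
    for j, (wl, f) in enumerate(
        sorted(zip(weak_wl, weak_f), key=lambda t: -t[0]), start=2
    ):
        states.append(ExcitedState(index=j, wavelength_nm=wl, oscillator_strength=f))
    return StickSpectrum(owner_label=owner, states=tuple(states))


def generate_bundle(
    spec: GeneratorSpec,
) -> tuple[list[CompoundEnsemble], GroundTruth]:
    """Generate one synthetic study: a bundle per compound plus ground truth.

    Deterministic under the spec's seed (same seed, identical output). The
    crystal pose of each compound is the scaffold with a known anilino-phenyl
    torsion whose magnitude grows with potency, so crystal RMSD ordering
    follows potency ordering by construction; the crystal stick spectrum is
    the global-minimum band displaced by the latent Δλmax plus jitter.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds

    if spec.gm_dipoles_D is not None:
        dipoles = np.array(spec.gm_dipoles_D, dtype=float)
    else:
        dipoles = np.array(
            [
                _SERIES_DIPOLES.get(s, float(rng.uniform(*spec.dipole_range_D)))
                for s in spec.substituents
            ]
        )
    ln_true = spec.potency_intercept + spec.potency_slope_per_D * dipoles
    ln_obs = ln_true + rng.normal(0.0, spec.potency_noise_sd, size=n)

    # most potent compounds (smallest true ln IC50) get a blue crystal shift
    # and the largest crystal distortion
    potency_rank = np.argsort(np.argsort(ln_true))  # 0 = most potent
    n_blue = int(math.floor(spec.blue_fraction * n))
    t_lo, t_hi = spec.crystal_torsion_deg
    if n > 1:
        torsions = t_hi - (t_hi - t_lo) * potency_rank / (n - 1)
    else:
        torsions = np.array([t_hi])

    bundles: list[CompoundEnsemble] = []
    truths: dict[str, CompoundTruth] = {}
    for i, sub in enumerate(spec.substituents):
        template, meta = anilinoquinazoline_template(sub)
        base = _ENERGY_BASE.get(sub, -1000.0 - 57.0 * i)

        shift_sign = -1 if potency_rank[i] < n_blue else 1
        delta_true = shift_sign * rng.uniform(*spec.delta_lambda_range_nm)
        cal_center = spec.principal_band_center_nm + rng.uniform(-3.0, 3.0)

        conformers: list[ConformerRecord] = []
        sticks: dict[str, StickSpectrum] = {}

        # global minimum: unperturbed scaffold
        gm_label = "conf-1"
        conformers.append(
            ConformerRecord(
                label=gm_label,
                total_energy=base,
                dipole_moment=float(dipoles[i]),
                geometry=template,
                role_tag=Role.GLOBAL_MINIMUM,
            )
        )
        sticks[gm_label] = _stick_spectrum(rng, spec, gm_label, cal_center)

        # local minima: exponential-tail strain energies, random torsions
        n_local = spec.conformers_per_compound - 1
        se_local = []
        while len(se_local) < n_local:
            draw = rng.exponential(spec.strain_energy_scale_kcal / 3.0)
            if draw <= spec.strain_energy_scale_kcal:
                se_local.append(draw)
        se_local = sorted(se_local)
        for j, se in enumerate(se_local, start=2):
            label = f"conf-{j}"
            coords = apply_torsion(
                template.coords,
                meta["phenyl_axis"],
                meta["phenyl_moving"],
                rng.uniform(-spec.conformer_torsion_deg, spec.conformer_torsion_deg),
            )
            for arm in meta["methoxy"]:
                coords = apply_torsion(
                    coords, arm["axis"], arm["moving"], rng.uniform(-30.0, 30.0)
                )
            conformers.append(
                ConformerRecord(
                    label=label,
                    total_energy=base + se / _thermo.HARTREE_TO_KCAL_PER_MOL,
                    dipole_moment=float(rng.uniform(*spec.dipole_range_D)),
                    geometry=template.with_coords(coords),
                )
            )
            sticks[label] = _stick_spectrum(
                rng, spec, label, cal_center + rng.normal(0.0, 1.0)
            )

        # crystal pose: known distortion, strain tied to the distortion size
        torsion = float(torsions[i])
        s_lo, s_hi = spec.crystal_strain_range_kcal
        frac = (torsion - t_lo) / (t_hi - t_lo) if t_hi > t_lo else 1.0
        crystal_se = s_lo + (s_hi - s_lo) * frac
        sign = 1.0 if rng.random() < 0.5 else -1.0
        coords = apply_torsion(
            template.coords, meta["phenyl_axis"], meta["phenyl_moving"], sign * torsion
        )
        for arm in meta["methoxy"]:
            coords = apply_torsion(coords, arm["axis"], arm["moving"], 0.5 * torsion)
        crystal_geom = template.with_coords(coords)
        conformers.append(
            ConformerRecord(
                label="crystal",
                total_energy=base + crystal_se / _thermo.HARTREE_TO_KCAL_PER_MOL,
                dipole_moment=float(rng.uniform(*spec.dipole_range_D)),
                geometry=crystal_geom,
                role_tag=Role.CRYSTAL_REFERENCE,
            )
        )
        sticks["crystal"] = _stick_spectrum(
            rng,
            spec,
            "crystal",
            cal_center + delta_true + rng.normal(0.0, spec.spectral_jitter_sd_nm),
        )

        ensemble = CompoundEnsemble(
            substituent=sub,
            conformers=tuple(conformers),
            stick_spectra=sticks,
            ic50_nM=float(np.exp(ln_obs[i])),
            atom_map=dict(meta["anchors"]),
        )
        bundles.append(ensemble)

        anchors = list(meta["anchors"].values())
        gm_anch = _align.plane_anchor_align(template, anchors)
        cr_anch = _align.plane_anchor_align(crystal_geom, anchors)
        rmsd = _align.rmsd_between(gm_anch, cr_anch, indices=template.heavy_indices)
        strain = {
            c.label: (c.total_energy - base) * _thermo.HARTREE_TO_KCAL_PER_MOL
            for c in conformers
        }
        truths[sub] = CompoundTruth(
            substituent=sub,
            dipole_gm_D=float(dipoles[i]),
            ln_ic50_true=float(ln_true[i]),
            ln_ic50_observed=float(ln_obs[i]),
            delta_lambda_true_nm=float(delta_true),
            shift_sign=shift_sign,
            crystal_torsion_deg=torsion,
            crystal_rmsd_A=float(rmsd),
            crystal_strain_kcal=float(crystal_se),
            strain_order=tuple(
                c.label for c in conformers if c.role_tag is not Role.CRYSTAL_REFERENCE
            ),
            strain_kcal={k: float(v) for k, v in strain.items()},
        )

    return bundles, GroundTruth(seed=int(spec.seed), compounds=truths)


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of re-deriving the generator's latent structure via the pipeline."""

    passed: bool
    failures: tuple[str, ...]
    sign_matches: dict  # substituent -> bool
    n_compounds: int

    @property
    def sign_recovery_rate(self) -> float:
        return sum(self.sign_matches.values()) / max(len(self.sign_matches), 1)


def recovery_check(
    bundles: Sequence[CompoundEnsemble],
    ground_truth: GroundTruth,
    temperature_K: float = _thermo.ROOM_TEMPERATURE_K,
    f_threshold: float = 0.5,
    rmsd_tol: float = 1e-6,
) -> RecoveryReport:
    """Run the full analysis on generated bundles and compare with ground truth.

    Checks, per compound: the sign of the recovered Δλmax equals the latent
    shift sign; the strain-energy ordering of the minima equals the generated
    ordering; the global minimum is the most populated conformer at the
    analysis temperature; and the plane-anchored crystal RMSD matches the
    generator's bookkeeping value. Every mismatch is reported with the
    offending compound's name.
    """
    failures: list[str] = []
    sign_matches: dict[str, bool] = {}
    for ens in bundles:
        truth: CompoundTruth = ground_truth.compounds[ens.substituent]

        lam_cal, _ = _spectra.lambda_max(
            ens.sticks_for(ens.global_minimum), f_threshold=f_threshold
        )
        crystal = ens.crystal_reference
        lam_cry, _ = _spectra.lambda_max(
            ens.sticks_for(crystal), f_threshold=f_threshold
        )
        rec = _spectra.peak_shift(lam_cal, lam_cry, ens.substituent)
        ok = int(np.sign(rec.delta_lambda_nm)) == truth.shift_sign
        sign_matches[ens.substituent] = bool(ok)
        if not ok:
            failures.append(
                f"{ens.substituent}: recovered shift {rec.shift_class} "
                f"(Δλ={rec.delta_lambda_nm:+.2f} nm) disagrees with ground truth"
            )

        strain = _thermo.strain_energies(ens)
        minima = [
            (lbl, se)
            for lbl, se in zip(strain.labels, strain.strain_kcal)
            if lbl != crystal.label
        ]
        recovered_order = tuple(lbl for lbl, _ in sorted(minima, key=lambda t: t[1]))
        if recovered_order != truth.strain_order:
            failures.append(
                f"{ens.substituent}: strain ordering {recovered_order} != "
                f"generated {truth.strain_order}"
            )

        pops = _thermo.boltzmann_populations(strain, temperature_K)
        top = pops.labels[int(np.argmax(pops.population_fractions))]
        if top != ens.global_minimum.label:
            failures.append(
                f"{ens.substituent}: most populated conformer is {top!r}, "
                f"not the global minimum"
            )

        rmsd = _align.crystal_vs_minimum_rmsd(
            ens, policy="heavy_atoms", anchors=("C1", "C4", "C10")
        )
        if abs(rmsd - truth.crystal_rmsd_A) > rmsd_tol:
            failures.append(
                f"{ens.substituent}: RMSD {rmsd:.6f} Å != ground truth "
                f"{truth.crystal_rmsd_A:.6f} Å"
            )

    return RecoveryReport(
        passed=not failures,
        failures=tuple(failures),
        sign_matches=sign_matches,
        n_compounds=len(bundles),
    )


def write_bundle_tree(
    bundles: Sequence[CompoundEnsemble],
    ground_truth: GroundTruth,
    outdir: str | Path,
) -> Path:
    """Write a complete on-disk study: manifests, XYZ, stick tables, config.

    Layout: one directory per compound with ``manifest.yaml``, per-conformer
    XYZ and TSV files; ``ground_truth.json`` and a ready-to-run
    ``pipeline.yaml`` at the top level. Returns the pipeline config path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_paths = []
    for ens in bundles:
        cdir = outdir / ens.substituent
        cdir.mkdir(exist_ok=True)
        entries = []
        for c in ens.conformers:
            xyz = f"{c.label}.xyz"
            write_xyz(c.geometry, cdir / xyz, comment=f"{ens.substituent} {c.label}")
            entry = {
                "label": c.label,
                "xyz": xyz,
                "energy_hartree": float(c.total_energy),
                "dipole_D": float(c.dipole_moment),
                "role": c.role_tag.value,
            }
            if c.label in ens.stick_spectra:
                tsv = f"{c.label}_sticks.tsv"
                write_stick_table(ens.stick_spectra[c.label], cdir / tsv)
                entry["sticks"] = tsv
            entries.append(entry)
        doc = {
            "substituent": ens.substituent,
            "ic50_nM": float(ens.ic50_nM),
            "atom_map": {k: int(v) for k, v in ens.atom_map.items()},
            "conformers": entries,
        }
        mpath = cdir / "manifest.yaml"
        mpath.write_text(yaml.safe_dump(doc, sort_keys=False))
        manifest_paths.append(f"{ens.substituent}/manifest.yaml")

    ground_truth.to_json(outdir / "ground_truth.json")
    config = {
        "compounds": manifest_paths,
        "temperature_K": _thermo.ROOM_TEMPERATURE_K,
        "f_threshold": 0.5,
        "fwhm_eV": _spectra.DEFAULT_FWHM_EV,
        "grid": list(_spectra.DEFAULT_GRID),
        "subset_policy": "heavy_atoms",
        "anchors": ["C1", "C4", "C10"],
    }
    cfg_path = outdir / "pipeline.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return cfg_path
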