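"""Study driver: the gas-opt -> PCM-reopt -> high-density-single-point
solvation workflow for the twenty ammonium/oxonium benchmark cations, with
deviation statistics against the literature reference values.

The reported quantity per molecule is the positive magnitude

    -[ E_total^PCM(960 tesserae/sphere, PCM geometry)
       - E_total^gas(gas geometry) ]   in kcal/mol,

i.e. the total-energy drop on transfer from vacuum to the dielectric,
including solute electronic and geometric relaxation.  The bare
interaction free energy 0.5 q.V at the final point is reported alongside.
"""

from __future__ import annotations

import json
import time
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np

from .cavity import molecular_frame
from .cpcm import SolventModel, dielectric_scale, solvated_scf
from .molecule import Molecule
from .nddo import SCFError, scf
from .optfreq import OPT_THRESHOLD, optimize
from .parameters import load_parameters
from .solvation_gradient import gas_gradient, total_gradient
from .units import EV, HARTREE_KCAL

logger = logging.getLogger(__name__)

# SMILES of the benchmark set (ammonium A1-A10, oxonium O1-O10) and the
# literature reference solvation magnitudes (kcal/mol) they are compared to.
FIXTURE_SMILES = {
    "A1": "[NH4+]",
    "A2": "C[NH3+]",
    "A3": "CC[NH3+]",
    "A4": "CCC[NH3+]",
    "A5": "CC([NH3+])C",
    "A6": "CCCC[NH3+]",
    "A7": "CC([NH3+])(C)C",
    "A8": "C[NH2+]C",
    "A9": "CC[NH2+]CC",
    "A10": "C[NH+](C)C",
    "O1": "C[OH2+]",
    "O2": "CC[OH2+]",
    "O3": "C[OH+]C",
    "O4": "C[OH+]CC",
    "O5": "C1C[OH+]CC1",
    "O6": "CC[OH+]CC",
    "O7": "C[OH+]c1ccccc1",
    "O8": "CC(=[OH+])C",
    "O9": "CC(C)C(=[OH+])C(C)C",
    "O10": "COC(=[OH+])C",
}

# Chudinov et al. D-PCM literature values (the "Ref" comparison column).
REFERENCE_DGSOLV = {
    "A1": 83.9, "A2": 73.7, "A3": 70.2, "A4": 69.9, "A5": 67.1,
    "A6": 69.3, "A7": 64.1, "A8": 65.9, "A9": 59.5, "A10": 59.7,
    "O1": 74.1, "O2": 69.2, "O3": 65.1, "O4": 61.1, "O5": 59.6,
    "O6": 57.4, "O7": 54.5, "O8": 62.5, "O9": 53.2, "O10": 60.0,
}

AMMONIUM_IDS = tuple(f"A{i}" for i in range(1, 11))
OXONIUM_IDS = tuple(f"O{i}" for i in range(1, 11))
ALL_IDS = AMMONIUM_IDS + OXONIUM_IDS


def load_fixture(molecule_id: str) -> Molecule:
    """Pre-built 3D starting geometry for one benchmark cation."""
    if molecule_id not in FIXTURE_SMILES:
        raise KeyError(
            f"unknown molecule id {molecule_id!r}; valid ids: {', '.join(ALL_IDS)}"
        )
    path = resources.files("sepcm.data.fixtures").joinpath(f"{molecule_id}.xyz")
    with path.open() as fh:
        return Molecule.from_xyz_string(fh.read())


@dataclass
class StudyConfig:
    method: str = "PM3"
    epsilon: float = 78.39
    f_form: str = "eps"
    radii_table: dict | None = None  # None -> Bondi
    radii_scale: float = 1.2
    n_tesserae_opt: int = 60
    n_tesserae_single_point: int = 960
    opt_threshold: float = OPT_THRESHOLD
    max_opt_steps: int = 100
    molecules: tuple = ALL_IDS
    coordinate_jitter: float = 0.0  # bohr, applied to fixture coordinates
    random_seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["molecules"] = list(d["molecules"])  # JSON-stable form
        return d


@dataclass
class SolvationOutcome:
    molecule_id: str
    smiles: str
    magnitude: float | None  # kcal/mol, positive convention
    dg_el: float | None  # kcal/mol, bare 0.5 q.V at the final point
    reference: float | None
    deviation: float | None  # computed - reference
    gas_converged: bool
    pcm_converged: bool
    pcm_stalled: bool
    gas_steps: int
    pcm_steps: int
    sum_q: float | None
    f: float
    n_tesserae: int | None = None
    error: str | None = None


@dataclass
class StudyReport:
    config: dict
    rows: list  # SolvationOutcome
    mean_signed_deviation: dict  # table key -> mean over converged entries

    def to_json_dict(self) -> dict:
        return {
            "config": self.config,
            "rows": [asdict(r) for r in self.rows],
            "mean_signed_deviation": self.mean_signed_deviation,
        }


def solvation_free_energy_pipeline(
    mol: Molecule,
    method: str = "PM3",
    solvent: SolventModel | None = None,
    radii_table: dict | None = None,
    radii_scale: float = 1.2,
    n_tesserae_opt: int = 60,
    n_tesserae_single_point: int = 960,
    opt_threshold: float = OPT_THRESHOLD,
    max_opt_steps: int = 100,
):
    """Three-stage solvation magnitude for one molecule.

    1. gas-phase geometry optimization;
    2. re-optimization in the C-PCM field at the working tessera density;
    3. single point at the high tessera density on the solvated geometry.

    Returns a dict with energies (hartree), the reported magnitude
    (kcal/mol) and the two optimization results.  A stalled PCM
    optimization is flagged and its best geometry still used, a known
    failure mode for the smallest cations on this kind of surface.
    """
    solvent = solvent or SolventModel()
    params = load_parameters(method)

    def gas_eg(m):
        state = scf(m, params)
        if not state.converged:
            raise SCFError("gas SCF not converged during optimization")
        g = gas_gradient(m, params, state)
        return state.total_energy / EV, g

    gas_opt = optimize(mol, gas_eg, threshold=opt_threshold, max_steps=max_opt_steps)
    e_gas = gas_opt.energy  # hartree

    frame = molecular_frame(gas_opt.molecule.coords)
    last_density = {"p": None}

    def pcm_eg(m):
        state = solvated_scf(
            m,
            params,
            solvent,
            n_per_sphere=n_tesserae_opt,
            radii_table=radii_table,
            radii_scale=radii_scale,
            frame=frame,
            p0=last_density["p"],
        )
        if not state.converged:
            raise SCFError("PCM SCF not converged during optimization")
        last_density["p"] = state.density
        # lazy gradient: only evaluated at accepted line-search points
        return state.total_energy / EV, lambda: total_gradient(
            m, params, state, cavity_scheme="forward"
        ).total

    pcm_opt = optimize(
        gas_opt.molecule,
        pcm_eg,
        threshold=opt_threshold,
        max_steps=max_opt_steps,
        initial_hessian=gas_opt.hessian_approx,
    )

    final_state = solvated_scf(
        pcm_opt.molecule,
        params,
        solvent,
        n_per_sphere=n_tesserae_single_point,
        radii_table=radii_table,
        radii_scale=radii_scale,
        frame=frame,
    )
    if not final_state.converged:
        raise SCFError("PCM SCF not converged at the high-density single point")
    e_pcm = final_state.total_energy / EV
    magnitude = -(e_pcm - e_gas) * HARTREE_KCAL
    return {
        "magnitude": magnitude,
        "dg_el": final_state.pcm.dg_el_kcal,
        "e_gas": e_gas,
        "e_pcm": e_pcm,
        "sum_q": final_state.pcm.total_charge,
        "f": final_state.pcm.f,
        "n_tesserae": final_state.pcm.cavity.n_tesserae,
        "gas_opt": gas_opt,
        "pcm_opt": pcm_opt,
        "final_state": final_state,
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the solvation pipeline over the configured molecule set.

    Partial failures never abort the study; they are flagged per molecule
    and excluded from the aggregate mean signed deviations.
    """
    solvent = SolventModel(config.epsilon, config.f_form)
    rng = np.random.default_rng(config.random_seed)
    rows = []
    for mid in config.molecules:
        t0 = time.time()
        mol = load_fixture(mid)
        if config.coordinate_jitter > 0.0:
            mol = mol.with_coords(
                mol.coords + rng.normal(scale=config.coordinate_jitter, size=mol.coords.shape)
            )
        ref = REFERENCE_DGSOLV.get(mid)
        try:
            out = solvation_free_energy_pipeline(
                mol,
                method=config.method,
                solvent=solvent,
                radii_table=config.radii_table,
                radii_scale=config.radii_scale,
                n_tesserae_opt=config.n_tesserae_opt,
                n_tesserae_single_point=config.n_tesserae_single_point,
                opt_threshold=config.opt_threshold,
                max_opt_steps=config.max_opt_steps,
            )
            rows.append(
                SolvationOutcome(
                    molecule_id=mid,
                    smiles=FIXTURE_SMILES[mid],
                    magnitude=out["magnitude"],
                    dg_el=out["dg_el"],
                    reference=ref,
                    deviation=None if ref is None else out["magnitude"] - ref,
                    gas_converged=out["gas_opt"].converged,
                    pcm_converged=out["pcm_opt"].converged,
                    pcm_stalled=out["pcm_opt"].stalled,
                    gas_steps=out["gas_opt"].steps,
                    pcm_steps=out["pcm_opt"].steps,
                    sum_q=out["sum_q"],
                    f=out["f"],
                    n_tesserae=out["n_tesserae"],
                )
            )
            logger.info(
                "%s: %.2f kcal/mol (ref %s) in %.1f s",
                mid, out["magnitude"], ref, time.time() - t0,
            )
        except Exception as exc:  # flagged, never fatal
            logger.warning("%s failed: %s", mid, exc)
            rows.append(
                SolvationOutcome(
                    molecule_id=mid,
                    smiles=FIXTURE_SMILES[mid],
                    magnitude=None,
                    dg_el=None,
                    reference=ref,
                    deviation=None,
                    gas_converged=False,
                    pcm_converged=False,
                    pcm_stalled=False,
                    gas_steps=0,
                    pcm_steps=0,
                    sum_q=None,
                    f=dielectric_scale(solvent),
                    error=str(exc),
                )
            )
    msd = {}
    for key, ids in (("ammonium", AMMONIUM_IDS), ("oxonium", OXONIUM_IDS)):
        devs = [
            r.deviation
            for r in rows
            if r.molecule_id in ids and r.deviation is not None
        ]
        if devs:
            msd[key] = float(np.mean(devs))
    return StudyReport(config=config.as_dict(), rows=rows, mean_signed_deviation=msd)


def write_report(report: StudyReport, basepath, formats=("json", "csv", "markdown")):
    """Serialize a study report; returns the written file paths."""
    import os

    written = []
    base = str(basepath)
    if "json" in formats:
        path = base + ".json"
        with open(path, "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=1, sort_keys=True)
        written.append(path)
    columns = [
        "molecule_id", "smiles", "reference", "magnitude", "deviation",
        "dg_el", "pcm_converged", "pcm_stalled",
    ]
    if "csv" in formats:
        path = base + ".csv"
        with open(path, "w") as fh:
            fh.write(",".join(columns) + "\n")
            for r in report.rows:
                d = asdict(r)
                fh.write(",".join(_fmt(d[c]) for c in columns) + "\n")
            for key, v in sorted(report.mean_signed_deviation.items()):
                fh.write(f"AVG_{key},,,,{v:.2f},,,\n")
        written.append(path)
    if "markdown" in formats:
        path = base + ".md"
        with open(path, "w") as fh:
            fh.write("| SMILES | id | Ref | computed | deviation |\n")
            fh.write("|---|---|---|---|---|\n")
            for r in report.rows:
                mag = "-" if r.magnitude is None else f"{r.magnitude:.1f}"
                dev = "-" if r.deviation is None else f"{r.deviation:+.1f}"
                ref = "-" if r.reference is None else f"{r.reference:.1f}"
                fh.write(f"| {r.smiles} | {r.molecule_id} | {ref} | {mag} | {dev} |\n")
            for key, v in sorted(report.mean_signed_deviation.items()):
                fh.write(f"| AVG ({key}) | | | | {v:+.1f} |\n")
        written.append(path)
    return written


def read_report(path) -> StudyReport:
    with open(path) as fh:
        d = json.load(fh)
    return StudyReport(
        config=d["config"],
        rows=[SolvationOutcome(**r) for r in d["rows"]],
        mean_signed_deviation=d["mean_signed_deviation"],
    )


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return f"{v:.6f}"
    return str(v)
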