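"""End-to-end pipelines tying the modules together.

``run_pipeline`` executes the trajectory chain: RDF -> shell boundaries ->
per-frame W_abc labelling -> per-subpopulation C1(t) and bi-exponential
fits -> retardation factors -> Empirical-Rule classification -> hydration
number h.  ``run_drs`` executes the spectroscopy chain: conductivity
removal -> double-Debye fits -> depolarization decomposition -> N_hyd per
concentration.  Both write a JSON/CSV artifact bundle stamped with a hash
of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .traj_io import Trajectory, WaterTopology, read_trajectory, build_water_topology
from .structure import ShellBoundaries, HBCriteria, compute_rdf, find_shell_minima
from .hydration import (
    label_trajectory,
    subpopulation_taus,
    bulk_reference_tau,
    retardation_factors,
    classify_empirical_rule,
    hydration_number,
)
from .drs import (
    DielectricSpectrum,
    remove_conductivity,
    fit_double_debye,
    static_depolarization,
    drs_hydration_number,
)

logger = logging.getLogger("aquadyn")

__all__ = ["RunConfig", "run_pipeline", "run_drs", "load_config"]


@dataclass
class RunConfig:
    """Validated configuration of the hydration pipeline.

    Defaults mirror the analysis protocol: 11 ps HB window, 16 ps dipole
    window, ~1024 time origins, 4 error blocks, the geometric HB criteria,
    and a 3-sigma Empirical-Rule band.
    """

    input_path: str | None = None
    cation: str = "Mg"
    anion: str = "Cl"
    cation_shells: tuple[float, float] | str = "auto"
    anion_shells: tuple[float, float] | str = "auto"
    shell_fallback_cation: tuple[float, float] = (3.0, 5.0)
    shell_fallback_anion: tuple[float, float] = (2.9, 5.0)
    hb_window: float = 11.0
    c1_window: float = 16.0
    target_origins: int = 1024
    fit_start: float = 0.2
    hb_criteria: HBCriteria = field(default_factory=HBCriteria)
    n_blocks: int = 4
    n_sigma: float = 3.0
    sigma_mode: str = "combined"
    rdf_bin_width: float = 0.05
    output_dir: str = "aquadyn_out"
    seed: int = 0
    dt: float | None = None

    def validate(self, traj: Trajectory | None = None) -> None:
        if self.hb_window <= 0 or self.c1_window <= 0:
            raise ValueError("correlation windows must be positive")
        if self.n_blocks < 2:
            raise ValueError("need at least 2 error blocks")
        if traj is not None:
            for sp, what in ((self.cation, "cation"), (self.anion, "anion")):
                if not np.any(traj.elements == sp):
                    raise ValueError(f"{what} species {sp!r} not found in trajectory")
            if self.c1_window > traj.span:
                raise ValueError("c1_window longer than the trajectory span")

    def config_hash(self) -> str:
        # identifies the analysis, not where its artifacts land
        payload = {k: str(v) for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML (unknown keys rejected)."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "hb_criteria" in data and isinstance(data["hb_criteria"], dict):
        data["hb_criteria"] = HBCriteria(**data["hb_criteria"])
    for key in ("cation_shells", "anion_shells", "shell_fallback_cation",
                "shell_fallback_anion"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def _resolve_shells(
    traj: Trajectory,
    pair: tuple[str, str],
    setting,
    fallback: tuple[float, float],
    bin_width: float,
):
    if setting != "auto":
        return ShellBoundaries(r_min1=setting[0], r_min2=setting[1], pair=pair), None
    r_max = float(traj.cell.min()) / 2
    rdf = compute_rdf(traj, pair, r_max=r_max, bin_width=bin_width)
    return find_shell_minima(rdf, fallback=fallback), rdf


def run_pipeline(
    config: RunConfig,
    traj: Trajectory | None = None,
    topology: WaterTopology | None = None,
):
    """Run the full hydration-number chain and write the artifact bundle.

    A trajectory object may be passed directly (e.g. a synthetic one);
    otherwise ``config.input_path`` is read.  Returns the
    :class:`~aquadyn.hydration.HydrationResult`.
    """
    if traj is None:
        if config.input_path is None:
            raise ValueError("no trajectory given: set input_path or pass traj")
        traj = read_trajectory(config.input_path, dt=config.dt)
    config.validate(traj)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_lines = [f"aquadyn {__version__} config_hash={chash} seed={config.seed}"]

    def stage(name):
        logger.info("stage: %s", name)
        log_lines.append(f"stage: {name}")

    if topology is None:
        stage("topology")
        topology = build_water_topology(traj)

    stage("shell boundaries")
    cat_shells, cat_rdf = _resolve_shells(
        traj, (config.cation, "O"), config.cation_shells,
        config.shell_fallback_cation, config.rdf_bin_width,
    )
    an_shells, an_rdf = _resolve_shells(
        traj, (config.anion, "H"), config.anion_shells,
        config.shell_fallback_anion, config.rdf_bin_width,
    )
    for rdf, name in ((cat_rdf, "rdf_cation_O"), (an_rdf, "rdf_anion_H")):
        if rdf is not None:
            pd.DataFrame({"r_A": rdf.r_centers, "g": rdf.g}).to_csv(
                outdir / f"{name}.csv", index=False
            )

    stage("subpopulation labelling")
    labels = label_trajectory(
        traj, topology, config.cation, config.anion, cat_shells, an_shells
    )

    stage("per-subpopulation reorientation times")
    table = subpopulation_taus(
        traj, topology, labels,
        window=config.c1_window, fit_start=config.fit_start,
        n_blocks=config.n_blocks, target_origins=config.target_origins,
    )

    stage("retardation factors and classification")
    bulk_tau = bulk_reference_tau(table)
    table = retardation_factors(table, bulk_tau)
    table = classify_empirical_rule(
        table, n_sigma=config.n_sigma, sigma_mode=config.sigma_mode
    )

    stage("hydration number")
    n_salt = int(topology.ion_indices.get(config.cation, np.empty(0)).size)
    if n_salt == 0:
        raise ValueError(f"no {config.cation} ions; cannot normalize per salt unit")
    result = hydration_number(table, n_salt, bulk_tau=bulk_tau)

    table.to_csv(outdir / "subpopulations.csv")
    curves = table.attrs.get("c1_curves", {})
    if curves:
        tables_dir = outdir / "tables"
        tables_dir.mkdir(exist_ok=True)
        for name, (lags, values) in curves.items():
            pd.DataFrame({"lag_ps": lags, "value": values}).to_csv(
                tables_dir / f"c1_{name}.csv", index=False
            )
    payload = {
        "config_hash": chash,
        "version": __version__,
        "seed": config.seed,
        "cation_shells": [cat_shells.r_min1, cat_shells.r_min2],
        "anion_shells": [an_shells.r_min1, an_shells.r_min2],
        "bulk_f_mean": table.attrs.get("bulk_f_mean"),
        "bulk_f_sigma": table.attrs.get("bulk_f_sigma"),
        "hydration": result.to_dict(),
    }
    (outdir / "results.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return result


def run_drs(
    spectra: list[DielectricSpectrum],
    reference: DielectricSpectrum,
    eps_inf: float = 3.52,
    eps_inf_reference: float | None = None,
    output_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Per-concentration double-Debye fits and DRS hydration numbers.

    ``reference`` is the pure-water spectrum; each solution spectrum must
    carry its conductivity, solute concentration (mol/kg) and water
    concentration (mol/L).  Returns a DataFrame with one row per solution.
    """
    if reference is None:
        raise ValueError("a pure-water reference spectrum is required")
    ref_inf = eps_inf_reference if eps_inf_reference is not None else eps_inf
    fit0 = fit_double_debye(remove_conductivity(reference), eps_inf=ref_inf)
    rows = []
    for spec in spectra:
        if spec.concentration <= 0:
            raise ValueError("solution spectrum lacks a positive concentration")
        fit_c = fit_double_debye(remove_conductivity(spec), eps_inf=eps_inf)
        dep = static_depolarization(fit_c, fit0, sigma_c=spec.conductivity)
        dep = drs_hydration_number(
            dep,
            c=spec.concentration,
            cH2O_c=spec.water_concentration,
            cH2O_0=reference.water_concentration,
            S0=fit0.strength,
        )
        rows.append(
            {
                "c_mol_per_kg": spec.concentration,
                "S1": fit_c.S1, "S2": fit_c.S2,
                "tau1_ps": fit_c.tau1, "tau2_ps": fit_c.tau2,
                "dS_total": dep.dS_total, "dS_kinetic": dep.dS_kinetic,
                "dS_static": dep.dS_static, "N_hyd": dep.N_hyd,
                "negative_N_flagged": dep.negative_N_flagged,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["reference_fit"] = fit0
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "drs_hydration.csv", index=False)
    return df
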