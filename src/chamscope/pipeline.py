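"""End-to-end analysis workflows behind the command-line interface.

Two workflows are provided. The chameleonicity workflow takes (or
generates) one ensemble in a polar and one in an apolar solvent, computes
per-conformer descriptors, clusters each ensemble, assigns Boltzmann
populations, extracts the >1% population subset and the MEC, builds
property landscapes and renders a congruence verdict. The NAMFIS workflow
fits conformer populations to an NOE restraint table, runs a
leave-one-restraint-out jackknife and summarizes fold-class populations.

Every numeric default left open by convention (temperature, cutoffs,
thresholds) is echoed into the JSON report, and all randomness funnels
through the single ``seed`` field, so identical configurations yield
identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as cio
from .core import Ensemble
from .descriptors import FoldThresholds, PolarScheme, conformer_properties, fold_class
from .ensemble_analysis import (
    CongruenceConfig,
    boltzmann_populations,
    cluster_ensemble,
    cluster_populations,
    compare_solvent_ensembles,
    identify_mec,
    low_energy_subset,
    property_landscape,
)
from .namfis import NamfisOptions, build_distance_matrix, jackknife_restraints, namfis_fit, summarize_fold_populations
from .synthetic_data import (
    CHLOROFORM_PROFILE,
    WATER_PROFILE,
    MimicSpec,
    build_protac_mimic,
    sample_conformers,
    simulate_noes,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_chameleonicity_analysis", "run_namfis_analysis"]


@dataclass
class RunConfig:
    """Flat configuration for the pipeline workflows.

    Structure inputs may be file paths (``polar_ensemble``/``apolar_ensemble``
    /``ensemble``/``noe_table``); when absent, the synthetic generator is used
    with the ``mimic`` settings. All defaults are serialized into the report.
    """

    # generator
    linker_type: str = "alkyl"
    n_linker_atoms: int = 12
    ligand_size: int = 16
    n_conformers: int = 150
    # inputs (override the generator when set)
    polar_ensemble: Optional[str] = None
    apolar_ensemble: Optional[str] = None
    ensemble: Optional[str] = None
    noe_table: Optional[str] = None
    structure_format: Optional[str] = None
    # descriptors
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    polar_elements: tuple[str, ...] = ("N", "O")
    include_attached_hydrogens: bool = True
    include_sulfur: bool = False
    folded_max: float = 7.0
    extended_min: float = 9.5
    # ensemble analysis
    rmsd_cutoff: float = 1.0
    temperature: float = 300.0
    population_threshold: float = 0.01
    landscape_bins: int = 12
    max_delta_r_gyr: float = 1.0
    min_overlap: float = 0.25
    #: "uniform" treats the conformer set as an already-Boltzmann-distributed
    #: sample (correct for Metropolis/MD output); "population" reweights by
    #: the per-conformer Boltzmann weights (for enumerated conformer pools).
    landscape_weighting: str = "uniform"
    # namfis
    noe_exponent: float = 6.0
    namfis_starts: int = 10
    reporting_floor: float = 0.005
    n_restraints: int = 20
    noise_sd: float = 0.0
    # run control
    seed: int = 0
    out_dir: str = "chamscope_out"
    output_format: str = "sdf"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "polar_elements" in data:
            data["polar_elements"] = tuple(data["polar_elements"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["polar_elements"] = list(self.polar_elements)
        return d

    def scheme(self) -> PolarScheme:
        return PolarScheme(
            polar_elements=frozenset(self.polar_elements),
            include_attached_hydrogens=self.include_attached_hydrogens,
            include_sulfur=self.include_sulfur,
        )

    def thresholds(self) -> FoldThresholds:
        return FoldThresholds(self.folded_max, self.extended_min)

    def congruence(self) -> CongruenceConfig:
        return CongruenceConfig(
            bins=self.landscape_bins,
            max_delta_r_gyr=self.max_delta_r_gyr,
            min_overlap=self.min_overlap,
        )

    def namfis_options(self) -> NamfisOptions:
        return NamfisOptions(
            exponent=self.noe_exponent,
            n_starts=self.namfis_starts,
            reporting_floor=self.reporting_floor,
            seed=self.seed,
        )


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def _obtain_ensembles(config: RunConfig) -> tuple[Ensemble, Ensemble]:
    if config.polar_ensemble and config.apolar_ensemble:
        polar = cio.read_ensemble(config.polar_ensemble, config.structure_format)
        apolar = cio.read_ensemble(config.apolar_ensemble, config.structure_format)
        return polar, apolar
    spec = MimicSpec(
        linker_type=config.linker_type,
        n_linker_atoms=config.n_linker_atoms,
        ligand_size=config.ligand_size,
        seed=config.seed,
    )
    topo = build_protac_mimic(spec)
    polar = sample_conformers(topo, config.n_conformers, WATER_PROFILE, seed=config.seed)
    apolar = sample_conformers(
        topo, config.n_conformers, CHLOROFORM_PROFILE, seed=config.seed + 1
    )
    return polar, apolar


def _analyze_one(ensemble: Ensemble, config: RunConfig, tag: str, out: Path) -> dict:
    props = conformer_properties(
        ensemble,
        scheme=config.scheme(),
        thresholds=config.thresholds(),
        probe_radius=config.probe_radius,
        n_sphere_points=config.n_sphere_points,
    )
    energies = ensemble.energies
    if energies is None:
        raise ValueError(
            f"{tag} ensemble carries no per-conformer energies; Boltzmann "
            "population analysis requires them"
        )
    populations = boltzmann_populations(energies, config.temperature)
    props["population"] = populations
    clusters = cluster_ensemble(ensemble, config.rmsd_cutoff)
    cpops = cluster_populations(clusters, populations)
    keep_clusters = low_energy_subset(cpops, config.population_threshold)
    mec = identify_mec(clusters, populations, energies)
    cio.write_property_table(
        props,
        out / f"properties_{tag}.tsv",
        metadata={
            "scheme": config.scheme().to_dict(),
            "fold_thresholds": config.thresholds().to_dict(),
            "probe_radius": config.probe_radius,
            "n_sphere_points": config.n_sphere_points,
            "temperature": config.temperature,
        },
    )
    landscape_w = (
        populations
        if config.landscape_weighting == "population"
        else np.full(len(props), 1.0 / len(props))
    )
    grid = property_landscape(props, bins=config.landscape_bins, weights=landscape_w)
    np.savetxt(out / f"landscape_{tag}.tsv", grid.density, delimiter="\t")
    mec_file = out / f"mec_{tag}.{config.output_format}"
    cio.write_ensemble(ensemble.subset([mec]), mec_file, config.output_format)
    mec_row = props.iloc[mec]
    return {
        "n_conformers": ensemble.n_conformers,
        "solvent": {"label": ensemble.solvent.label, "dielectric": ensemble.solvent.dielectric},
        "n_clusters": clusters.n_clusters,
        "clusters_above_threshold": int(len(keep_clusters)),
        "mec": {
            "conformer_id": ensemble.conformers[mec].conformer_id,
            "r_gyr": float(mec_row["r_gyr"]),
            "sa3d_psa": float(mec_row["sa3d_psa"]),
            "sa3d_npsa": float(mec_row["sa3d_npsa"]),
            "fold_class": str(mec_row["fold_class"]),
            "energy": float(energies[mec]),
        },
        "mean_r_gyr": float(props["r_gyr"].mean()),
        "mean_sa3d_psa": float(props["sa3d_psa"].mean()),
        "boltzmann_mean_r_gyr": float((props["r_gyr"] * populations).sum()),
        "property_table": str(out / f"properties_{tag}.tsv"),
        "_props": props,
    }


def run_chameleonicity_analysis(config: RunConfig) -> dict:
    """Full descriptor → clustering → populations → landscape → congruence
    workflow over a polar/apolar ensemble pair. Returns the report dict and
    writes it (plus tables and MEC structures) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _stage("load or generate ensembles")
    polar, apolar = _obtain_ensembles(config)
    report: dict = {"workflow": "chameleonicity", "config": config.to_dict()}
    _stage("per-solvent analysis")
    res_polar = _analyze_one(polar, config, "polar", out)
    res_apolar = _analyze_one(apolar, config, "apolar", out)
    props_polar = res_polar.pop("_props")
    props_apolar = res_apolar.pop("_props")
    _stage("cross-solvent comparison")
    if config.landscape_weighting == "uniform":
        props_polar = props_polar.drop(columns=["population"])
        props_apolar = props_apolar.drop(columns=["population"])
    comparison = compare_solvent_ensembles(props_polar, props_apolar, config.congruence())
    report["polar"] = res_polar
    report["apolar"] = res_apolar
    report["comparison"] = comparison.to_dict()
    report["elapsed_s"] = round(time.perf_counter() - t0, 3)
    (out / "chameleonicity_report.json").write_text(
        json.dumps(_strip_volatile(report), indent=2, sort_keys=True) + "\n"
    )
    return report


def run_namfis_analysis(config: RunConfig) -> dict:
    """NOE deconvolution workflow: distance matrix → population fit →
    jackknife → fold-class summary. Returns and writes the JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _stage("load or generate ensemble and restraints")
    truth = None
    if config.ensemble:
        ensemble = cio.read_ensemble(config.ensemble, config.structure_format)
        if not config.noe_table:
            raise FileNotFoundError(
                "a NOE restraint table is required when an ensemble file is given"
            )
        restraints = cio.read_noe_table(config.noe_table)
    else:
        spec = MimicSpec(
            linker_type=config.linker_type,
            n_linker_atoms=config.n_linker_atoms,
            ligand_size=config.ligand_size,
            seed=config.seed,
        )
        topo = build_protac_mimic(spec)
        ensemble = sample_conformers(topo, config.n_conformers, WATER_PROFILE, seed=config.seed)
        rng = np.random.default_rng(config.seed)
        true_pop = np.zeros(ensemble.n_conformers)
        chosen = rng.choice(ensemble.n_conformers, size=min(3, ensemble.n_conformers), replace=False)
        true_pop[chosen] = rng.dirichlet(np.ones(len(chosen)) * 5.0)
        restraints, truth = simulate_noes(
            ensemble,
            true_pop,
            n_restraints=config.n_restraints,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        if not restraints:
            raise RuntimeError("the synthetic mixture produced no observable NOEs")
    _stage("distance matrix and fit")
    matrix = build_distance_matrix(ensemble, restraints, exponent=config.noe_exponent)
    result = namfis_fit(matrix, restraints, config.namfis_options())
    _stage("jackknife and fold summary")
    jack = (
        jackknife_restraints(matrix, restraints, config.namfis_options())
        if matrix.n_restraints >= 2
        else None
    )
    masses = ensemble.topology.masses
    from .descriptors import radius_of_gyration

    classes = [
        fold_class(
            radius_of_gyration(c.coordinates, masses), config.thresholds()
        )
        for c in ensemble.conformers
    ]
    fold_pops = summarize_fold_populations(result, classes)
    result.fold_class_populations = fold_pops
    report = {
        "workflow": "namfis",
        "config": config.to_dict(),
        "fit": result.to_dict(),
        "jackknife": jack,
        "fold_class_percent": fold_pops,
        "n_restraints": matrix.n_restraints,
        "n_conformers": matrix.n_conformers,
    }
    if truth is not None:
        report["ground_truth"] = truth
        err = np.abs(result.populations - np.asarray(truth["true_populations"]))
        report["max_population_error_vs_truth"] = float(err.max())
    report["elapsed_s"] = round(time.perf_counter() - t0, 3)
    pop_table = out / "populations.tsv"
    with open(pop_table, "w") as fh:
        fh.write("conformer_id\tpopulation\tfold_class\n")
        for cid, pop, cls in zip(result.conformer_ids, result.populations, classes):
            fh.write(f"{cid}\t{pop:.6f}\t{cls}\n")
    (out / "namfis_report.json").write_text(
        json.dumps(_strip_volatile(report), indent=2, sort_keys=True) + "\n"
    )
    return report


def _strip_volatile(report: dict) -> dict:
    """Drop wall-clock fields so identical runs yield identical files."""
    out = dict(report)
    out.pop("elapsed_s", None)
    return out
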