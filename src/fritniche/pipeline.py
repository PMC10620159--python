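"""End-to-end orchestration of the synthetic niche study.

``run_pipeline`` executes the full chain on generated data — environmental
stack, virtual species, occurrence thinning, variable selection, ensemble
fitting and evaluation, suitability projection (current plus any labelled
scenario stacks), habitat grading and areas, niche breadth/overlap and
overlapping degree, metabolite clustering and plant trees, TN93 distances,
and the overlap-vs-dissimilarity correlation report — writing every stage's
output and a seed log into a run directory. One master seed fans out to
per-stage seeds by stable hashing of stage names, so any stage is
reproducible in isolation; the same config and seed reproduce every output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chem, niche, phylo, synth
from .correlate import correlate_overlap
from .occurrences import OccurrenceSet, extract_env, select_variables, thin_occurrences
from .raster import RasterStack, write_ascii
from .sdm import EnsembleSDM, area_stats, classify_habitat, fit_sre, sample_pseudo_absences

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the stage and the input digest."""


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    h = hashlib.blake2b(f"{master}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2 ** 31)


@dataclass
class SpeciesConfig:
    optima: list[float]
    widths: list[float]
    weights: list[float]
    n_records: int = 150
    duplicate_rate: float = 0.2
    chem_clusters: list[int] = field(default_factory=list)
    branch_length: float = 0.05


@dataclass
class RunConfig:
    """Serializable study configuration with the conventional defaults:
    Spearman cutoff 0.8, Tanimoto threshold 0.85, suitability threshold
    0.5, grade bins 0.25/0.5/0.75, member AUC cutoff 0.9, 15 runs per
    algorithm."""

    seed: int = 0
    n_rows: int = 60
    n_cols: int = 60
    layer_names: list[str] = field(default_factory=lambda: ["bio01", "bio12", "bio03", "elev"])
    layer_means: list[float] = field(default_factory=lambda: [12.0, 800.0, 45.0, 3000.0])
    layer_sds: list[float] = field(default_factory=lambda: [4.0, 250.0, 8.0, 900.0])
    corr_length: float = 4.0
    west: float = 95.0
    north: float = 35.0
    cellsize: float = 0.1
    algorithms: list[str] = field(default_factory=lambda: ["sre", "glm"])
    split: float = 0.8
    splits_available: list[float] = field(default_factory=lambda: [0.85, 0.80, 0.75])
    n_runs: int = 15
    auc_cutoff: float = 0.9
    sre_q: float = 0.025
    max_iter: int = 500
    spearman_threshold: float = 0.8
    thin_cell_km: float = 20.0
    tanimoto_threshold: float = 0.85
    suitability_threshold: float = 0.5
    chem_k_clusters: int = 6
    chem_per_cluster: int = 6
    chem_flip_bits: int = 4
    chem_n_boot: int = 200
    phylo_n_sites: int = 5000
    scenarios: dict = field(default_factory=dict)  # label -> per-layer mean shifts
    species: dict = field(default_factory=dict)  # name -> SpeciesConfig fields

    def __post_init__(self) -> None:
        if not self.species:
            self.species = {
                "species_A": {"optima": [14.0, 900.0, 45.0, 3000.0],
                              "widths": [2.0, 120.0, 8.0, 900.0],
                              "weights": [1.0, 1.0, 0.0, 0.0],
                              "chem_clusters": [0, 1, 2], "branch_length": 0.04},
                "species_B": {"optima": [13.0, 870.0, 45.0, 3000.0],
                              "widths": [2.0, 130.0, 8.0, 900.0],
                              "weights": [1.0, 1.0, 0.0, 0.0],
                              "chem_clusters": [0, 1, 3], "branch_length": 0.06},
                "species_C": {"optima": [8.0, 600.0, 45.0, 3000.0],
                              "widths": [2.0, 120.0, 8.0, 900.0],
                              "weights": [1.0, 1.0, 0.0, 0.0],
                              "chem_clusters": [3, 4, 5], "branch_length": 0.12},
            }
        self.species = {name: cfg if isinstance(cfg, SpeciesConfig)
                        else SpeciesConfig(**cfg)
                        for name, cfg in self.species.items()}

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seeds: dict[str, int] = {}

    def seed_for(stage: str) -> int:
        seeds[stage] = stage_seed(config.seed, stage)
        return seeds[stage]

    # --- simulate environment -------------------------------------------
    @_stage("simulate_env")
    def simulate_env() -> RasterStack:
        stack = synth.gen_env_stack(
            config.n_rows, config.n_cols, len(config.layer_names),
            config.corr_length, config.layer_means, config.layer_sds,
            seed=seed_for("env"), west=config.west, north=config.north,
            cellsize=config.cellsize, names=config.layer_names)
        for name in stack.names:
            write_ascii(stack.layer(name), out / f"env_{name}.asc")
        return stack

    stack = simulate_env()

    # --- species: sample, thin, extract, model ---------------------------
    @_stage("species_modelling")
    def model_species():
        suitability, grades, occ_thinned, tables = {}, {}, {}, {}
        score_frames, area_frames, range_frames = [], [], []
        for name, sp in config.species.items():
            truth = synth.gen_virtual_species(stack, sp.optima, sp.widths, sp.weights)
            occ = synth.sample_occurrences(truth, sp.n_records, sp.duplicate_rate,
                                           seed=seed_for(f"occ:{name}"), species=name)
            thinned, n_removed = thin_occurrences(occ, config.thin_cell_km)
            logger.info("%s: thinned %d -> %d records", name, len(occ), len(thinned))
            presence_env = extract_env(stack, thinned)
            sre0 = fit_sre(presence_env, q=config.sre_q)
            absences = sample_pseudo_absences(
                stack, sre0, n=len(thinned), seed=seed_for(f"pa:{name}"),
                species=name, exclude=thinned)
            env = extract_env(stack, OccurrenceSet.concat([thinned, absences]))
            retained, removed = select_variables(env, threshold=config.spearman_threshold)
            keep_cols = ["species", "lon", "lat", "kind"] + retained + ["label"]
            env_sel = env[keep_cols]
            model = EnsembleSDM(env_sel, algorithms=config.algorithms,
                                split=config.split, n_runs=config.n_runs,
                                auc_cutoff=config.auc_cutoff,
                                seed=seed_for(f"fit:{name}"),
                                sre_q=config.sre_q, max_iter=config.max_iter)
            res = model.fit()
            suit = res.predict_raster(stack)
            grade = classify_habitat(suit)
            suitability[name], grades[name] = suit, grade
            occ_thinned[name], tables[name] = thinned, env_sel
            write_ascii(suit, out / f"suitability_{name}.asc")
            write_ascii(grade, out / f"grades_{name}.asc")
            occ.to_csv(out / f"occurrences_raw_{name}.csv")
            thinned.to_csv(out / f"occurrences_thinned_{name}.csv")
            env_sel.to_csv(out / f"env_table_{name}.csv", index=False)
            sc = res.scores.assign(species=name)
            score_frames.append(sc)
            ar = area_stats(grade).assign(species=name, scenario="current")
            area_frames.append(ar)
            rng_tab = res.suitable_range_table(config.suitability_threshold)
            range_frames.append(rng_tab.assign(species=name))
            for label, shifts in config.scenarios.items():
                shifted = RasterStack(
                    list(stack.names),
                    stack.data + np.asarray(shifts, dtype=float)[:, None, None],
                    stack.west, stack.north, stack.dx, stack.dy)
                g2 = classify_habitat(res.predict_raster(shifted))
                area_frames.append(area_stats(g2).assign(species=name, scenario=label))
        pd.concat(score_frames, ignore_index=True).to_csv(out / "scores.csv", index=False)
        pd.concat(area_frames, ignore_index=True).to_csv(out / "areas.csv", index=False)
        pd.concat(range_frames, ignore_index=True).to_csv(out / "suitable_ranges.csv", index=False)
        return suitability, grades, occ_thinned

    suitability, grades, occ_thinned = model_species()

    # --- niche statistics -------------------------------------------------
    @_stage("niche_stats")
    def niche_stats():
        breadth, pairs = niche.compute_niche_stats(suitability, grades, occ_thinned)
        breadth.to_csv(out / "niche_breadth.csv", index=False)
        pairs.to_csv(out / "niche_overlap.csv", index=False)
        return breadth, pairs

    _breadth, pairs = niche_stats()

    # --- chemistry ---------------------------------------------------------
    @_stage("chemistry")
    def chemistry():
        fps, truth = synth.gen_fingerprint_clusters(
            config.chem_k_clusters, config.chem_per_cluster,
            config.chem_flip_bits, seed=seed_for("fingerprints"))
        profiles = synth.gen_plant_profiles(
            fps, truth,
            {name: set(sp.chem_clusters) for name, sp in config.species.items()},
            seed=seed_for("plant_profiles"))
        profiles.to_csv(out / "fingerprints.csv", out / "plant_metabolites.csv")
        g = chem.build_network(profiles, threshold=config.tanimoto_threshold)
        groups = chem.cluster_metabolites(g)
        pd.DataFrame([(gid, m) for gid, mets in groups.items() for m in sorted(mets)],
                     columns=["group", "metabolite"]).to_csv(
            out / "metabolite_groups.csv", index=False)
        pgm = chem.plant_group_matrix(groups, profiles.plants)
        pgm.to_csv(out / "plant_group_matrix.csv", index_label="plant")
        dmat = chem.dissimilarity_matrix(pgm, index="jaccard")
        dmat.to_csv(out / "jaccard_dissimilarity.csv", index_label="plant")
        tree = chem.cluster_plants(dmat, n_boot=config.chem_n_boot,
                                   seed=seed_for("chem_boot"), matrix=pgm)
        tree.write(out / "plant_tree_jaccard.nwk")
        return dmat

    chem_dmat = chemistry()

    # --- phylogenetic distances -------------------------------------------
    @_stage("phylo")
    def phylo_stage():
        aln = synth.gen_star_alignment(
            config.phylo_n_sites,
            {name: sp.branch_length for name, sp in config.species.items()},
            seed=seed_for("alignment"))
        phylo.write_fasta_alignment(aln, out / "alignment.fasta")
        dmat = phylo.distance_matrix(aln)
        dmat.to_csv(out / "tn93_distances.csv", index_label="taxon")
        return dmat

    tn93_dmat = phylo_stage()

    # --- correlation -------------------------------------------------------
    @_stage("correlation")
    def correlation():
        idx = [f"{row.species_a}|{row.species_b}" for row in pairs.itertuples()]
        overlaps = pd.DataFrame({"D": pairs["D"].to_numpy(),
                                 "I": pairs["I"].to_numpy()}, index=idx)
        features = pd.DataFrame({
            "chemical": [chem_dmat.loc[a, b] for a, b in
                         zip(pairs["species_a"], pairs["species_b"])],
            "genetic": [tn93_dmat.loc[a, b] for a, b in
                        zip(pairs["species_a"], pairs["species_b"])],
        }, index=idx)
        report = correlate_overlap(overlaps, features)
        report.to_csv(out / "correlation_report.csv", index=False)
        return report

    correlation()

    with open(out / "seeds.json", "w") as fh:
        json.dump({"master": config.seed, "stages": seeds}, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished: %s", out)
    return out
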