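"""End-to-end orchestration of the pipeline stages from one config.

Stage order: ``qc -> pseudoabsence -> select -> fit -> project -> community``.
Requesting a subset runs that subset plus whatever upstream stages it needs;
every run writes a ``manifest.json`` recording, for each artifact, the stage
that produced it, the seed in force and a SHA-256 checksum, so reruns of the
deterministic pipeline can be compared bit-for-bit.

Per-stage seeds are derived from the master seed by stable hashing of the
stage name (and species id where sampling is per-species), so a stage rerun
is independent of how many random draws earlier stages consumed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import community as comm
from . import ensemble as ens
from . import io, projection as proj, qc as qcmod
from .config import PipelineConfig
from .grids import EnvStack
from .predictors import select_predictors
from .pseudoabsence import PseudoAbsenceSet, sample_pseudoabsences

log = logging.getLogger("shaderange")

STAGES = ["qc", "pseudoabsence", "select", "fit", "project", "community"]


def derive_seed(master: int, *names: str) -> int:
    """Stable sub-seed < 2^31 from the master seed and a label path."""
    h = hashlib.sha256(("/".join([str(master), *names])).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def extract_training_set(species_id: str, pres_lon, pres_lat,
                         pa: PseudoAbsenceSet, env: EnvStack,
                         predictors: list[str], k: int = 4,
                         seed: int = 0) -> ens.TrainingSet:
    """Build the labelled predictor matrix for one species."""
    lon = np.concatenate([np.asarray(pres_lon, float), pa.lon])
    lat = np.concatenate([np.asarray(pres_lat, float), pa.lat])
    y = np.concatenate([np.ones(len(pres_lon), int), np.zeros(len(pa.lon), int)])
    X = env.extract(lon, lat, predictors)
    if X.isna().any().any():
        raise ValueError(f"{species_id}: NaN predictor values at training points")
    folds = ens.assign_folds(y, k=k, seed=seed)
    return ens.TrainingSet(species_id=species_id, X=X, y=y, folds=folds,
                           lon=lon, lat=lat)


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.paths.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.env = io.read_stack(config.paths.env_dir)
        self.landcover = (io.read_landcover(config.paths.landcover_dir)
                          if config.paths.landcover_dir else None)
        self.occurrences = io.read_occurrences(config.paths.occurrences)
        self.artifacts: list[dict] = []
        # populated by stages
        self.qc_table: pd.DataFrame | None = None
        self.kept_species: list[str] = []
        self.pa_sets: dict[str, PseudoAbsenceSet] = {}
        self.selected: list[str] = []
        self.models: dict[str, ens.EnsembleModel] = {}
        self.importances: dict[str, ens.VariableImportance] = {}
        self.current_binaries: dict[str, proj.BinaryMap] = {}
        self.future_binaries: dict[str, dict[str, proj.BinaryMap]] = {}
        self.current_maps: dict[str, proj.SuitabilityMap] = {}
        self.future_maps: dict[str, dict[str, proj.SuitabilityMap]] = {}

    def record(self, stage: str, path: Path, seed: int | None = None) -> None:
        self.artifacts.append({
            "name": path.name, "path": str(path.relative_to(self.out)),
            "stage": stage, "sha256": _sha256(path), "seed": seed,
        })

    # ----- stages -------------------------------------------------------

    def stage_qc(self) -> None:
        cfg = self.config.qc
        table, kept, report = qcmod.run_qc(
            self.occurrences, self.env,
            baseline_year=cfg.baseline_year, tail_fraction=cfg.tail_fraction,
            source_blacklist=set(cfg.source_blacklist), min_n=cfg.min_n)
        self.qc_table = table
        self.kept_species = sorted(kept)
        p1 = self.out / "occurrences_qc.csv"
        table.to_csv(p1, index=False)
        p2 = self.out / "qc_report.csv"
        report.to_csv(p2, index=False)
        self.record("qc", p1)
        self.record("qc", p2)
        for _, row in report.iterrows():
            log.info("qc %s: %d in, %d retained", row["species"],
                     row["n_input"], row["n_retained"])

    def _presences(self, species: str) -> pd.DataFrame:
        assert self.qc_table is not None
        tab = self.qc_table
        return tab[(tab["species"] == species) & qcmod.retained_mask(tab)]

    def stage_pseudoabsence(self) -> None:
        cfg = self.config.pseudoabsence
        rows = []
        for sp in self.kept_species:
            pres = self._presences(sp)
            seed = derive_seed(self.config.seed, "pseudoabsence", sp)
            pa = sample_pseudoabsences(pres["lon"].to_numpy(float),
                                       pres["lat"].to_numpy(float),
                                       self.env, n=cfg.n, buffer_km=cfg.buffer_km,
                                       seed=seed, species_id=sp)
            self.pa_sets[sp] = pa
            rows.append(pd.DataFrame({"species": sp, "lon": pres["lon"],
                                      "lat": pres["lat"], "label": "presence"}))
            rows.append(pd.DataFrame({"species": sp, "lon": pa.lon,
                                      "lat": pa.lat, "label": "pseudoabsence"}))
        path = self.out / "pseudoabsences.csv"
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
        self.record("pseudoabsence", path,
                    seed=derive_seed(self.config.seed, "pseudoabsence"))

    def stage_select(self) -> None:
        cfg = self.config.selection
        lon, lat = [], []
        for sp in self.kept_species:
            pres = self._presences(sp)
            lon += [pres["lon"].to_numpy(float), self.pa_sets[sp].lon]
            lat += [pres["lat"].to_numpy(float), self.pa_sets[sp].lat]
        matrix = self.env.extract(np.concatenate(lon), np.concatenate(lat))
        matrix = matrix.dropna()
        priority = ({name: i for i, name in enumerate(cfg.priority)}
                    if cfg.priority else None)
        result = select_predictors(matrix, vif_threshold=cfg.vif_threshold,
                                   r_max=cfg.r_max, priority=priority)
        self.selected = result.kept
        path = self.out / "predictor_selection.csv"
        result.to_frame().to_csv(path, index=False)
        self.record("select", path)
        log.info("selected predictors: %s", self.selected)

    def stage_fit(self) -> None:
        cfg = self.config.model
        metrics, summary, imp_rows = [], [], []
        for sp in self.kept_species:
            pres = self._presences(sp)
            seed = derive_seed(self.config.seed, "fit", sp)
            ts = extract_training_set(sp, pres["lon"].to_numpy(float),
                                      pres["lat"].to_numpy(float),
                                      self.pa_sets[sp], self.env, self.selected,
                                      k=cfg.k, seed=seed)
            model = ens.fit_ensemble(ts, algorithms=tuple(cfg.algorithms),
                                     seed=seed, hyperparams=cfg.hyperparams,
                                     weight_mode=cfg.weight_mode)
            vi = ens.variable_importance(model, ts,
                                         n_permutations=cfg.n_permutations,
                                         seed=seed,
                                         variable_class=self.env.variable_class)
            self.models[sp] = model
            self.importances[sp] = vi
            cv = model.cv_metrics.copy()
            cv.insert(0, "species", sp)
            metrics.append(cv)
            summary.append({"species": sp, "threshold": model.threshold,
                            "ensemble_auc": model.ensemble_auc,
                            "ensemble_tss": model.ensemble_tss,
                            "best_algorithm": model.best_algorithm,
                            **{f"w_{a}": w for a, w in model.weights.items()}})
            imp_rows.append(pd.DataFrame({"species": sp,
                                          "variable": vi.importance.index,
                                          "importance_pct": vi.importance.values}))
        p1 = self.out / "cv_metrics.csv"
        pd.concat(metrics, ignore_index=True).to_csv(p1, index=False)
        p2 = self.out / "ensemble_summary.csv"
        pd.DataFrame(summary).to_csv(p2, index=False)
        p3 = self.out / "variable_importance.csv"
        pd.concat(imp_rows, ignore_index=True).to_csv(p3, index=False)
        for p in (p1, p2, p3):
            self.record("fit", p, seed=derive_seed(self.config.seed, "fit"))

    def _scenario_groups(self) -> dict[str, list]:
        groups: dict[str, list] = {}
        for sc in self.config.scenarios:
            groups.setdefault(f"{sc.ssp}_{sc.period}", []).append(sc)
        return groups

    def stage_project(self) -> None:
        cfg = self.config.projection
        summaries = []
        scenario_stacks = {sc.label: io.read_stack(sc.env_dir)
                           for sc in self.config.scenarios}
        for sp in self.kept_species:
            model = self.models[sp]
            cur_map = proj.predict_map(model, self.env, scenario="current")
            cur_bin = proj.binarize(cur_map, model.threshold)
            self.current_maps[sp] = cur_map
            self.current_binaries[sp] = cur_bin
            io.write_ascii_grid(self.out / f"suitability_{sp}_current.asc",
                                cur_map.values, cur_map.grid)
            self.record("project", self.out / f"suitability_{sp}_current.asc")
            self.future_binaries[sp] = {}
            self.future_maps[sp] = {}
            for label, members in self._scenario_groups().items():
                maps = [proj.predict_map(model, scenario_stacks[sc.label],
                                         scenario=sc.label) for sc in members]
                agg = proj.aggregate_gcms(maps, scenario=label)
                fut_bin = proj.binarize(agg, model.threshold)
                self.future_maps[sp][label] = agg
                self.future_binaries[sp][label] = fut_bin
                io.write_ascii_grid(self.out / f"suitability_{sp}_{label}.asc",
                                    agg.values, agg.grid)
                self.record("project", self.out / f"suitability_{sp}_{label}.asc")
                summaries.append(proj.area_change(
                    cur_bin, fut_bin, landcover=self.landcover,
                    allowed_classes=cfg.allowed_classes,
                    study_area_mask=self.env.land_mask, mode=cfg.area_mode))
        if summaries:
            path = self.out / "area_change.csv"
            proj.summaries_to_frame(summaries).to_csv(path, index=False)
            self.record("project", path)

    def stage_community(self) -> None:
        cfg = self.config.community
        focal = cfg.focal_species
        shade = [sp for sp in self.kept_species if sp != focal]
        if not shade:
            log.warning("community stage: no shade species retained")
            return
        rich_cur = comm.richness([self.current_binaries[sp] for sp in shade],
                                 scenario="current")
        io.write_ascii_grid(self.out / "richness_current.asc",
                            rich_cur.counts.astype(float), rich_cur.grid)
        self.record("community", self.out / "richness_current.asc")
        hot = comm.hotspots(rich_cur, min_richness=cfg.min_richness)
        io.write_ascii_grid(self.out / "hotspots_current.asc",
                            hot.astype(float), rich_cur.grid)
        self.record("community", self.out / "hotspots_current.asc")
        for label in self._scenario_groups():
            rich = comm.richness([self.future_binaries[sp][label] for sp in shade],
                                 scenario=label)
            io.write_ascii_grid(self.out / f"richness_{label}.asc",
                                rich.counts.astype(float), rich.grid)
            self.record("community", self.out / f"richness_{label}.asc")
        # importance roll-up over all modelled species
        per_species, pooled = comm.importance_rollup(
            list(self.importances.values()), self.env.variable_class)
        p = self.out / "importance_rollup.csv"
        per_species.to_csv(p, index=False)
        self.record("community", p)
        p = self.out / "importance_pooled.csv"
        pooled.to_csv(p, index=False)
        self.record("community", p)
        # focal-crop overlap summary
        if focal and focal in self.models:
            layer_name = cfg.overlap_layer or self._default_overlap_layer()
            cur = comm.overlap_summary(
                {sp: self.current_binaries[sp] for sp in shade},
                self.current_maps[focal], self.env.layers[layer_name],
                layer_name=layer_name)
            cur.insert(1, "scenario", "current")
            frames = [cur]
            for label in self._scenario_groups():
                fut = comm.overlap_summary(
                    {sp: self.future_binaries[sp][label] for sp in shade},
                    self.future_maps[focal][label], self.env.layers[layer_name],
                    layer_name=layer_name)
                fut.insert(1, "scenario", label)
                frames.append(fut)
            p = self.out / "overlap_summary.csv"
            pd.concat(frames, ignore_index=True).to_csv(p, index=False)
            self.record("community", p)

    def _default_overlap_layer(self) -> str:
        """Layer with the highest pooled median importance across species."""
        imp = pd.concat([vi.importance for vi in self.importances.values()], axis=1)
        return str(imp.median(axis=1).idxmax())


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run requested stages (plus upstream dependencies) and write the
    manifest. Returns the manifest dict; the PipelineRun is attached under
    the ``_run`` key for programmatic use."""
    requested = stages or STAGES
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    last = max(STAGES.index(s) for s in requested)
    to_run = STAGES[: last + 1]
    run = PipelineRun(config)
    for stage in to_run:
        log.info("stage %s", stage)
        try:
            getattr(run, f"stage_{stage}")()
        except Exception as exc:
            raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    manifest = {
        "seed": config.seed,
        "stages": to_run,
        "inputs": {
            "occurrences": _sha256(Path(config.paths.occurrences)),
        },
        "artifacts": run.artifacts,
    }
    with open(run.out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["_run"] = run
    return manifest
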