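"""One-command orchestration of the full analysis.

A YAML (or dict) configuration names the input genotype file, optional
coordinates and region map, the stages to run, and per-stage parameters.
Stages run in dependency order (diversity -> structure -> bottleneck -> sgs
-> abc); each writes its own CSV/JSON outputs and contributes to a combined
machine-readable report.  Per-stage random seeds are derived from the global
seed with a fixed per-stage spawn key, so toggling one stage never shifts
another stage's random stream.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from msatpop import __version__, core, demography, distance, io, sgs
from msatpop import bottleneck as bnk
from msatpop import diversity as div

__all__ = ["run_pipeline", "PipelineConfigError", "STAGES"]

STAGES = ("diversity", "structure", "bottleneck", "sgs", "abc")


class PipelineConfigError(ValueError):
    """Raised for inconsistent pipeline configurations."""


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _stage_seed(global_seed: int | None, stage: str) -> int:
    """Deterministic per-stage seed: fixed spawn key per stage name."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the configured stages; returns the combined report dict.

    `config` is a mapping or a path to a YAML file.  Recognised keys:
    ``genotypes`` (path, required), ``dialect``, ``coordinates`` (path),
    ``region_map`` (pop -> group), ``seed``, ``output_dir``, ``stages``
    (subset of diversity/structure/bottleneck/sgs/abc), and one mapping of
    parameters per stage name.  Any stage failure raises a stage-tagged
    error after logging.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    out_dir = Path(cfg.get("output_dir", "msatpop_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("msatpop.pipeline")
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        stages = list(cfg.get("stages", STAGES))
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stages: {sorted(unknown)}")
        if "genotypes" not in cfg:
            raise PipelineConfigError("config needs a 'genotypes' path")
        seed = cfg.get("seed")
        log.info("msatpop %s; seed=%s; stages=%s", __version__, seed, stages)

        table = io.read_genotypes(cfg["genotypes"],
                                  dialect=cfg.get("dialect", "genalex_csv"))
        if cfg.get("region_map"):
            table.regions = {str(k): str(v) for k, v in cfg["region_map"].items()}
            table.validate()
        coords = None
        if cfg.get("coordinates"):
            coords = io.read_coordinates(cfg["coordinates"])
        if "abc" in stages and not table.regions:
            raise PipelineConfigError("stage 'abc' needs a region_map")

        flagged = table.flag_high_missing()
        if flagged:
            log.warning("individuals with >50%% missing loci: %s", flagged)
            if cfg.get("exclude_high_missing", False):
                keep = [i for i, ind in enumerate(table.ids) if ind not in flagged]
                table = table.subset_individuals(keep)
                log.info("excluded %d high-missingness individuals", len(flagged))

        report: dict[str, Any] = {"version": __version__, "seed": seed,
                                  "stages": stages, "config_echo": _jsonable(cfg)}

        for stage in STAGES:
            if stage not in stages:
                continue
            s_seed = _stage_seed(seed, stage)
            log.info("stage %s: seed=%d", stage, s_seed)
            try:
                report[stage] = _run_stage(stage, table, coords,
                                           cfg.get(stage) or {}, s_seed,
                                           out_dir, log)
            except Exception as e:  # noqa: BLE001 - tag and re-raise
                log.error("stage %s failed: %s", stage, e)
                raise StageError(stage, e) from e

        with open(out_dir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        log.info("report written to %s", out_dir / "report.json")
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stage(stage: str, table, coords, params: dict, seed: int,
               out_dir: Path, log) -> dict:
    if stage == "diversity":
        loc = div.locus_summaries(table)
        pop = div.population_summaries(table)
        loc.round(3).to_csv(out_dir / "locus_summaries.csv")
        pop.round(3).to_csv(out_dir / "population_summaries.csv")
        nulls = div.null_allele_screen(
            table, hwe_iterations=int(params.get("hwe_iterations", 2000)),
            seed=seed)
        nulls.to_csv(out_dir / "null_alleles.csv", index=False)
        return {"locus_means": loc.loc["Mean"].to_dict(),
                "n_flagged_null": int(nulls["flagged"].sum())}

    if stage == "structure":
        perms = int(params.get("permutations", 1000))
        freqs = core.allele_frequencies(table)
        nei = distance.nei_distance(freqs)
        nei.to_frame().to_csv(out_dir / "nei_distances.csv")
        newick = distance.nj_tree(nei)
        (out_dir / "nj_tree.nwk").write_text(newick + "\n")
        pc = distance.pcoa(nei)
        pc.to_frame().to_csv(out_dir / "pcoa_coordinates.csv")
        am = distance.amova(table, permutations=perms, seed=seed)
        am.to_frame().round(3).to_csv(out_dir / "amova.csv", index=False)
        out = {"amova_percent": am.percentages, "amova_p": am.p_values,
               "phi": am.phi}
        if coords is not None and coords.mode == "geodetic":
            geo = distance.geographic_distances(coords)
            shared = [p for p in nei.labels if p in geo.labels]
            sub_nei = distance.DistanceMatrix(
                labels=shared,
                values=nei.to_frame().loc[shared, shared].to_numpy(),
                metric=nei.metric)
            sub_geo = distance.DistanceMatrix(
                labels=shared,
                values=geo.to_frame().loc[shared, shared].to_numpy(),
                metric=geo.metric)
            mr = distance.mantel(sub_nei, sub_geo, permutations=perms, seed=seed)
            out["mantel"] = {"r": mr.r, "p": mr.p, "slope": mr.slope,
                             "intercept": mr.intercept}
        return out

    if stage == "bottleneck":
        p = bnk.TPMParams(
            p_single=float(params.get("p_single", 0.7)),
            sigma2_geom=float(params.get("sigma2_geom", 30.0)),
            replicates=int(params.get("replicates", 1000)),
            seed=seed,
        )
        groups = params.get("groups")
        if groups is None:
            groups = (sorted(set(table.regions.values()))
                      if table.regions else [None])
        cache: dict = {}
        out = {}
        rows = []
        for g in groups:
            res = bnk.heterozygosity_excess_test(table, group=g, params=p,
                                                 heq_cache=cache)
            out[res.group] = {"wilcoxon_p": res.wilcoxon_p,
                              "mode_shift": res.mode_shift_verdict,
                              "n_loci": res.n_loci_tested}
            pl = res.per_locus.copy()
            pl.insert(0, "group", res.group)
            rows.append(pl)
        import pandas as pd

        pd.concat(rows).to_csv(out_dir / "bottleneck_per_locus.csv", index=False)
        return out

    if stage == "sgs":
        if coords is None or coords.mode != "planar":
            raise PipelineConfigError("stage 'sgs' needs planar coordinates")
        min_n = int(params.get("min_n", 20))
        pops = params.get("populations") or [
            p for p, n in table.population_sizes().items() if n > min_n
        ]
        perms = int(params.get("permutations", 1000))
        out = {}
        for k, pop in enumerate(pops):
            res = sgs.sgs_analysis(table, pop, coords,
                                   scheme=params.get("scheme"),
                                   n_perm=perms, seed=seed + k)
            res.per_class.round(5).to_csv(
                out_dir / f"sgs_correlogram_{pop}.csv", index=False)
            out[pop] = {"b": res.b, "b_p": res.b_p, "F_d1": res.f_d1,
                        "Sp": res.sp, "k": res.curvature_k,
                        "verdict": res.verdict}
        return out

    if stage == "abc":
        scen_cfg = params.get("scenarios", "divergence")
        if scen_cfg == "divergence":
            scenarios = demography.divergence_scenarios(params.get("priors"))
        elif scen_cfg == "migration":
            scenarios = demography.migration_scenarios(params.get("priors"))
        else:
            raise PipelineConfigError(
                f"unknown scenario set {scen_cfg!r} (use divergence|migration)")
        group_sizes: dict[str, int] = {}
        for pop, n in table.population_sizes().items():
            g = table.regions[pop]
            group_sizes[g] = group_sizes.get(g, 0) + n
        cap = int(params.get("max_sample_per_group", 25))
        n_samples = {g: min(n, cap) for g, n in group_sizes.items()}
        observed = demography.compute_summaries(table)
        res = demography.abc_scenario_choice(
            observed, scenarios, n_samples=n_samples,
            n_loci=table.n_loci,
            n_sims=int(params.get("n_sims", 50_000)),
            retain_frac=float(params.get("retain_frac", 0.01)),
            seed=seed,
        )
        payload = {"best_scenario": res.best_scenario,
                   "posterior": {k: v[0] for k, v in res.scenario_pp.items()},
                   "rejection": res.rejection_pp,
                   "parameters": res.param_posterior,
                   "n_retained": res.n_retained}
        if "t1" in res.param_posterior:
            gt = float(params.get("generation_time", 5.0))
            payload["t1_years"] = demography.generations_to_years(
                res.param_posterior["t1"][0], gt)
        with open(out_dir / "abc_result.json", "w") as fh:
            json.dump(_jsonable(payload), fh, indent=2)
        return payload

    raise PipelineConfigError(f"unknown stage {stage!r}")
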