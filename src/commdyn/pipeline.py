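"""End-to-end orchestration: simulate/ingest -> rarefy -> STR + island +
determinism + community statistics, per station, with seeded reproducibility.

Every stage writes machine-readable outputs (JSON for structured results,
TSV for matrices; floats at 12 significant digits) plus a manifest that
fully determines the run: inputs, seeds, parameters and package version.
Stage failures are recorded in the manifest and independent stages continue.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_io import (
    CommunityMatrix,
    EnvironmentSeries,
    binarize,
    read_asv_table,
    read_metadata,
    repeat_rarefy,
    write_asv_table,
    write_metadata,
)
from .island import fit_ce, fit_ce_env
from .process_model import determinism_from_fit, fit_crn
from .stats import DistanceMatrix, bray_curtis, cv_slrt, hellinger, mantel, sorensen
from .str_analysis import str_curve, str_permutation_test
from .synthetic import StationDesign, default_design, simulate_dataset

__all__ = ["RunConfig", "run_all", "load_config"]

log = logging.getLogger("commdyn")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``asv_table``/``metadata`` paths or a synthetic ``design`` must
    be present (the default is the built-in synthetic design).  ``depth``
    ``None`` means the minimum sample sum; presence-absence analyses use
    the unrarefied table by default (``rarefied_presence`` switches that).
    """

    asv_table: str | None = None
    metadata: str | None = None
    design: StationDesign | None = None
    group: str = "community"
    depth: int | None = None
    sim_depth: int = 12000
    n_rarefactions: int = 100
    n_perm: int = 1000
    seed: int = 0
    stations: list[str] | None = None
    covariate: str = "salinity"
    top_k: int = 50
    rarefied_presence: bool = False
    outdir: str = "commdyn_out"

    def __post_init__(self):
        for name in ("n_rarefactions", "n_perm", "sim_depth", "top_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.depth is not None and self.depth < 1:
            raise ValueError("depth must be positive")


def load_config(path) -> RunConfig:
    """Read a TOML config file into a :class:`RunConfig`.

    Recognized keys mirror the dataclass fields; a ``[design]`` table (with
    StationDesign fields) selects a custom synthetic design.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    design_tbl = raw.pop("design", None)
    cfg = RunConfig(**raw)
    if design_tbl is not None:
        for key in ("station_ids", "months", "salinity_mean", "salinity_sd"):
            if key in design_tbl:
                design_tbl[key] = tuple(design_tbl[key])
        cfg.design = StationDesign(**design_tbl)
    return cfg


# ---------------------------------------------------------------------------
# Serialization helpers (stable, 12 significant digits)
# ---------------------------------------------------------------------------


def _round12(obj):
    if isinstance(obj, float):
        return float(f"{obj:.12g}") if np.isfinite(obj) else (None if np.isnan(obj) else str(obj))
    if isinstance(obj, (np.floating,)):
        return _round12(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_round12(x) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(x) for x in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _round12(dataclasses.asdict(obj))
    return obj


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_round12(obj), indent=1, sort_keys=True) + "\n")


def _write_matrix_tsv(values: np.ndarray, index, columns, path: Path) -> None:
    df = pd.DataFrame(np.asarray(values), index=index, columns=columns)
    df = df.map(lambda x: float(f"{x:.12g}") if isinstance(x, float) else x)
    df.to_csv(path, sep="\t")


def _derive_seed(master: int, *tags: str) -> int:
    crcs = [zlib.crc32(t.encode()) % (2**31) for t in tags]
    h = np.random.SeedSequence([int(master)] + crcs)
    return int(h.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_str(pm_station, cfg: RunConfig, outdir: Path, station: str) -> dict:
    curve = str_curve(pm_station)
    fit = str_permutation_test(
        pm_station, n_perm=cfg.n_perm, seed=_derive_seed(cfg.seed, "str", station)
    )
    pd.DataFrame({"T": curve.T, "S_geo": curve.S_geo}).to_csv(
        outdir / f"str_curve_{station}.tsv", sep="\t", index=False
    )
    result = dataclasses.asdict(fit)
    _write_json(result, outdir / f"str_fit_{station}.json")
    return result


def _stage_island(pm_station, env_station, cfg: RunConfig, outdir: Path, station: str) -> dict:
    ce = fit_ce(pm_station)
    result = {"constant": dataclasses.asdict(ce)}
    try:
        ce_env = fit_ce_env(pm_station, env_station, covariate=cfg.covariate)
        result["covariate"] = dataclasses.asdict(ce_env)
    except ValueError as exc:
        result["covariate_error"] = str(exc)
    _write_json(result, outdir / f"island_{station}.json")
    return result


def _stage_determinism(cm_station, env_station, cfg: RunConfig, outdir: Path, station: str) -> dict:
    fit = fit_crn(cm_station, env_station, top_k=cfg.top_k)
    det = determinism_from_fit(fit)
    _write_matrix_tsv(
        det.D, det.taxon_ids, [f"{t:.6g}" for t in det.times], outdir / f"determinism_D_{station}.tsv"
    )
    result = {
        "D_mean_unweighted": det.D_mean_unweighted,
        "D_mean_weighted": det.D_mean_weighted,
        "D_unweighted": det.D_unweighted,
        "D_weighted": det.D_weighted,
        "times": det.times,
        "skipped_taxa": fit.skipped,
    }
    _write_json(result, outdir / f"determinism_{station}.json")
    return result


def _stage_stats(cm_station, pm_station, env_station, cfg: RunConfig, outdir: Path, station: str) -> dict:
    depth = cfg.depth if cfg.depth is not None else int(cm_station.sample_sums().min())
    reps = repeat_rarefy(
        cm_station, depth, n_rep=cfg.n_rarefactions,
        seed=_derive_seed(cfg.seed, "rarefy", station),
    )
    acc = np.zeros((cm_station.n_samples, cm_station.n_samples))
    for rep in reps:
        acc += bray_curtis(hellinger(rep)).values
    bc_mean = DistanceMatrix(acc / len(reps), cm_station.sample_ids)
    _write_matrix_tsv(
        bc_mean.values, cm_station.sample_ids, cm_station.sample_ids,
        outdir / f"braycurtis_hellinger_{station}.tsv",
    )
    sor = sorensen(pm_station)
    _write_matrix_tsv(
        sor.values, cm_station.sample_ids, cm_station.sample_ids,
        outdir / f"sorensen_{station}.tsv",
    )
    sal = env_station.covariate(cfg.covariate)
    d_env = DistanceMatrix(np.abs(sal[:, None] - sal[None, :]), cm_station.sample_ids)
    mr = mantel(
        bc_mean, d_env, n_perm=min(cfg.n_perm, 999),
        seed=_derive_seed(cfg.seed, "mantel", station),
    )
    result = {
        "depth": depth,
        "n_rarefactions": len(reps),
        "mantel_community_vs_covariate": dataclasses.asdict(mr),
    }
    _write_json(result, outdir / f"stats_{station}.json")
    return result


def run_all(cfg: RunConfig) -> dict:
    """Run the full per-station analysis; return the result bundle.

    Reads the configured ASV table + metadata, or simulates the synthetic
    design (default) and writes the simulated inputs alongside the
    results.  Per station: STR fit with permutation significance,
    constant and covariate-modulated colonization/extinction fits,
    process-model determinism, repeated-rarefaction Bray-Curtis (after
    Hellinger) and Sorensen matrices with a Mantel test against the
    covariate; across stations, the CV-equality SLRT on salinity and
    temperature.  All outputs land in ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

    truth = None
    if cfg.asv_table is not None:
        meta, env = read_metadata(cfg.metadata)
        cm = read_asv_table(cfg.asv_table, metadata=meta)
    else:
        ds = simulate_dataset(
            design=cfg.design or default_design(),
            depth=cfg.sim_depth,
            seed=_derive_seed(cfg.seed, "simulate"),
        )
        cm, env, truth = ds.counts, ds.env, ds.truth
        write_asv_table(cm, outdir / "simulated_asv_table.tsv")
        write_metadata(ds.meta, outdir / "simulated_metadata.tsv")
        _write_json(truth, outdir / "simulated_truth.json")

    stations = cfg.stations or cm.stations
    pm = binarize(cm)
    bundle: dict = {"stations": {}, "errors": {}}
    for st in stations:
        cm_st = cm.subset_station(st)
        env_st = env.align(cm_st.sample_ids)
        if cfg.rarefied_presence:
            depth = cfg.depth if cfg.depth is not None else int(cm_st.sample_sums().min())
            from .data_io import rarefy

            pm_st = binarize(rarefy(cm_st, depth, _derive_seed(cfg.seed, "pa-rarefy", st)))
        else:
            pm_st = pm.subset_station(st)
        log.info("station %s: %d samples", st, cm_st.n_samples)
        st_res: dict = {}
        stages = {
            "str": lambda: _stage_str(pm_st, cfg, outdir, st),
            "island": lambda: _stage_island(pm_st, env_st, cfg, outdir, st),
            "determinism": lambda: _stage_determinism(cm_st, env_st, cfg, outdir, st),
            "stats": lambda: _stage_stats(cm_st, pm_st, env_st, cfg, outdir, st),
        }
        for name, fn in stages.items():
            try:
                st_res[name] = fn()
            except Exception as exc:  # stage isolation: record and continue
                log.warning("station %s stage %s failed: %s", st, name, exc)
                bundle["errors"][f"{st}/{name}"] = f"{type(exc).__name__}: {exc}"
        bundle["stations"][st] = st_res

    # across-station variability of the environment
    try:
        groups = [env.align(cm.subset_station(st).sample_ids) for st in stations]
        slrt_sal = cv_slrt(
            [g.salinity for g in groups], n_sim=1000, seed=_derive_seed(cfg.seed, "slrt-sal")
        )
        env_cmp = {"salinity_cv_slrt": dataclasses.asdict(slrt_sal)}
        if all(np.all(np.isfinite(g.temperature)) for g in groups):
            slrt_tmp = cv_slrt(
                [g.temperature for g in groups], n_sim=1000, seed=_derive_seed(cfg.seed, "slrt-tmp")
            )
            env_cmp["temperature_cv_slrt"] = dataclasses.asdict(slrt_tmp)
        _write_json(env_cmp, outdir / "environment_cv.json")
        bundle["environment"] = env_cmp
    except Exception as exc:
        bundle["errors"]["environment/cv_slrt"] = f"{type(exc).__name__}: {exc}"

    manifest = {
        "version": __version__,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(cfg).items()
            if k != "outdir"  # run location does not determine results
        },
        "stations": list(stations),
        "n_taxa": cm.n_taxa,
        "n_samples": cm.n_samples,
        "truth": truth,
        "errors": bundle["errors"],
    }
    _write_json(manifest, outdir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
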