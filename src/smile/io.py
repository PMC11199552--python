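"""Tab-separated readers/writers, run configuration, and the pipeline runner.

All tables are plain UTF-8 TSV with headers; missing values are empty
fields.  Formats:

pedigree:    individual_id family_id role sex birth_year months_enrolled location_id
phenotypes:  individual_id phenotype_id status        (status 0/1)
adjacency:   location_a location_b                    (undirected, one per line)
exposures:   location_id pm25 no2 wind_speed wind_dir [psum]
location covariates: location_id <covariate columns>
"""

from __future__ import annotations

import json
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import causal as causal_mod
from .pedigree import Cohort, Family, Individual, PedigreeError, ROLES
from .spatial import LocationGraph, build_location_graph
from .vc_model import (
    ModelSpec,
    blup_spatial,
    correlate_blup_covariates,
    fit_smile,
    observed_to_liability,
    select_model,
)


class ConfigError(ValueError):
    pass


# --------------------------------------------------------------------------
# readers


def read_pedigree(path) -> Cohort:
    """Load a pedigree TSV into a canonically ordered cohort.

    Schema violations are reported with the offending line number.
    """
    path = Path(path)
    expected = ["individual_id", "family_id", "role", "sex", "birth_year",
                "months_enrolled", "location_id"]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != expected:
            raise PedigreeError(
                f"{path}:1: bad header {header}; expected {expected}")
        rows = []
        seen = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(expected):
                raise PedigreeError(
                    f"{path}:{lineno}: expected {len(expected)} fields, got {len(parts)}")
            iid, fid, role, sex, by, me, loc = parts
            if role not in ROLES:
                raise PedigreeError(
                    f"{path}:{lineno}: unknown role {role!r}; expected one of {ROLES}")
            if iid in seen:
                raise PedigreeError(f"{path}:{lineno}: duplicate individual_id {iid!r}")
            seen.add(iid)
            try:
                rows.append(Individual(iid, fid, role, sex, int(by), int(me), loc))
            except ValueError as exc:
                raise PedigreeError(f"{path}:{lineno}: {exc}") from exc
    fams: dict[str, list[Individual]] = {}
    for ind in rows:
        fams.setdefault(ind.family_id, []).append(ind)
    return Cohort([Family(fid, members) for fid, members in fams.items()])


def read_adjacency(path, extra_locations=()) -> LocationGraph:
    """Load an undirected edge list; extra locations become isolates."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["location_a", "location_b"]:
        raise ConfigError(
            f"{path}: bad header {list(df.columns)}; expected location_a/location_b")
    edges = list(df.itertuples(index=False, name=None))
    locations = sorted({a for a, b in edges} | {b for a, b in edges}
                       | set(extra_locations))
    return build_location_graph(edges, locations)


def read_phenotypes(path, cohort: Cohort) -> pd.DataFrame:
    """Long phenotype TSV -> individuals x phenotypes 0/1 matrix in cohort
    order (individuals without a record for a phenotype default to 0)."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str,
                                            "phenotype_id": str})
    expected = ["individual_id", "phenotype_id", "status"]
    if list(df.columns) != expected:
        raise ConfigError(f"{path}: bad header; expected {expected}")
    unknown = set(df["individual_id"]) - set(cohort.individual_ids)
    if unknown:
        raise ConfigError(
            f"{path}: {len(unknown)} individuals not in pedigree, e.g. "
            f"{sorted(unknown)[:3]}")
    wide = df.pivot_table(index="individual_id", columns="phenotype_id",
                          values="status", aggfunc="max", fill_value=0)
    out = wide.reindex(cohort.individual_ids, fill_value=0)
    out.columns.name = None
    return out.astype(float)


def read_exposures(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure/instrument TSV keyed by location_id -> (exposures, instruments)."""
    df = pd.read_csv(path, sep="\t", dtype={"location_id": str}).set_index("location_id")
    needed = {"pm25", "no2", "wind_speed", "wind_dir"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    exposures = df[["pm25", "no2"]].copy()
    if "psum" in df.columns:
        exposures["psum"] = df["psum"]
    else:
        from scipy.stats import zscore
        exposures["psum"] = zscore(df["pm25"]) + zscore(df["no2"])
    return exposures, df[["wind_speed", "wind_dir"]].copy()


def read_location_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"location_id": str}).set_index("location_id")


def load_cohort(pedigree_path, phenotype_path, adjacency_path):
    """Load and cross-validate the three core inputs.

    Returns (cohort, graph, phenotype matrix).  Locations present in the
    pedigree but absent from the adjacency file are reported and kept as
    isolated graph nodes.
    """
    cohort = read_pedigree(pedigree_path)
    ped_locs = set(cohort.location_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # isolate warning re-raised with context
        graph = read_adjacency(adjacency_path, extra_locations=sorted(ped_locs))
    connected = {loc for loc, n in zip(graph.locations, graph.neighbor_counts)
                 if n > 0}
    orphan = sorted(ped_locs - connected)
    if orphan:
        warnings.warn(
            f"{len(orphan)} pedigree location(s) missing from adjacency "
            f"(kept as isolates): {orphan[:5]}", stacklevel=2)
    phenotypes = read_phenotypes(phenotype_path, cohort)
    return cohort, graph, phenotypes


# --------------------------------------------------------------------------
# writers


def write_pedigree(cohort: Cohort, path) -> None:
    rows = [
        (m.individual_id, m.family_id, m.role, m.sex, m.birth_year,
         m.months_enrolled, m.location_id)
        for m in cohort.iter_members()
    ]
    pd.DataFrame(rows, columns=[
        "individual_id", "family_id", "role", "sex", "birth_year",
        "months_enrolled", "location_id",
    ]).to_csv(path, sep="\t", index=False)


def write_adjacency(graph: LocationGraph, path) -> None:
    coo = graph.W.tocoo()
    rows = [(graph.locations[i], graph.locations[j])
            for i, j in zip(coo.row, coo.col) if i < j]
    pd.DataFrame(rows, columns=["location_a", "location_b"]).to_csv(
        path, sep="\t", index=False)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    """Individuals x phenotypes matrix -> long TSV (case rows only are
    sufficient, but all rows are written for lossless round-trips)."""
    long = phenotypes.stack().rename("status").reset_index()
    long.columns = ["individual_id", "phenotype_id", "status"]
    long["status"] = long["status"].astype(int)
    long.to_csv(path, sep="\t", index=False)


def write_exposures(exposures: pd.DataFrame, instruments: pd.DataFrame, path) -> None:
    merged = exposures.join(instruments)
    merged.index.name = "location_id"
    merged.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-backed)."""

    pedigree: Path
    phenotypes: Path
    adjacency: Path
    output_dir: Path
    exposures: Path | None = None
    location_covariates: Path | None = None
    models: list = field(default_factory=lambda: ["GPC+S", "GPC"])
    spatial_structures: list = field(default_factory=lambda: ["CAR"])
    covariates: list = field(default_factory=lambda: ["age", "sex", "months_enrolled"])
    liability_method: str = "tetrachoric"
    causal_exposures: list = field(default_factory=lambda: ["pm25", "no2", "psum"])
    causal_min_prevalence: float = 0.001
    blup_min_prevalence: float = 0.02
    blup_min_spatial_var: float = 0.02
    n_starts: int = 3
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known - {"version"}
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.pop("version", None)
        cfg = cls(**{k: v for k, v in raw.items()})
        cfg.pedigree = Path(cfg.pedigree)
        cfg.phenotypes = Path(cfg.phenotypes)
        cfg.adjacency = Path(cfg.adjacency)
        cfg.output_dir = Path(cfg.output_dir)
        for p in [cfg.pedigree, cfg.phenotypes, cfg.adjacency]:
            if not Path(p).exists():
                raise ConfigError(f"input file does not exist: {p}")
        for opt in ["exposures", "location_covariates"]:
            val = getattr(cfg, opt)
            if val is not None:
                setattr(cfg, opt, Path(val))
                if not Path(val).exists():
                    raise ConfigError(f"input file does not exist: {val}")
        for s in cfg.spatial_structures:
            if s not in ("IND", "CAR", "SAR"):
                raise ConfigError(f"unknown spatial structure {s!r}")
        for m in cfg.models:
            ModelSpec.from_name(m)  # raises on bad token
        for thr in [cfg.causal_min_prevalence, cfg.blup_min_prevalence,
                    cfg.blup_min_spatial_var]:
            if not 0.0 < thr < 1.0:
                raise ConfigError(f"threshold {thr} outside (0, 1)")
        return cfg


# --------------------------------------------------------------------------
# pipeline


def _fit_row(phen: str, fit, K: float, liability_method: str) -> dict:
    vc = fit.vc
    row = {
        "phenotype": phen, "model": fit.spec.name,
        "sigma_g2": vc.sigma_g2, "sigma_par2": vc.sigma_par2,
        "sigma_child2": vc.sigma_child2, "sigma_s2": vc.sigma_s2,
        "sigma_eps2": vc.sigma_eps2, "rho": vc.rho,
        "gower_sigma_s2": vc.gower_sigma_s2,
        "h2_obs": vc.h2, "prevalence": K,
        "loglik": fit.loglik, "bic": fit.bic, "n_params": fit.n_params,
        "converged": fit.converged,
    }
    try:
        liab = observed_to_liability(vc, K, method=liability_method)
        row.update({"h2_liab": liab.sigma_g2, "par_liab": liab.sigma_par2,
                    "child_liab": liab.sigma_child2, "s_liab": liab.sigma_s2})
    except Exception:
        row.update({"h2_liab": np.nan, "par_liab": np.nan,
                    "child_liab": np.nan, "s_liab": np.nan})
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Fit every configured model to every phenotype, select by BIC, convert
    to liability scale, compute spatial BLUPs and their covariate
    correlations, and (if exposures are provided) run the causal screen.

    Per-phenotype failures are logged and skipped; the phenome loop never
    aborts.  Returns the machine-readable run log (also written to
    run_log.json in the output directory).
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, graph, phenotypes = load_cohort(
        config.pedigree, config.phenotypes, config.adjacency)
    from .vc_model import CohortStructure, design_matrix
    structure = CohortStructure(cohort, graph)
    X = design_matrix(cohort, config.covariates)

    specs = []
    for m in config.models:
        if "S" in m:
            for s in config.spatial_structures:
                specs.append(ModelSpec.from_name(m, spatial=s))
        else:
            specs.append(ModelSpec.from_name(m))

    fit_rows, blup_rows, status = [], [], {}
    selected_fits = {}
    for phen in phenotypes.columns:
        Y = phenotypes[phen].to_numpy()
        K = float(Y.mean())
        if not 0.0 < K < 1.0:
            status[phen] = f"skipped: prevalence {K}"
            continue
        fits = []
        try:
            rows_by_model = {}
            for spec in specs:
                fit = fit_smile(cohort, Y, X, spec, graph=graph,
                                n_starts=config.n_starts, compute_se=False,
                                structure=structure)
                fits.append(fit)
                row = _fit_row(phen, fit, K, config.liability_method)
                rows_by_model[fit.spec.name] = row
                fit_rows.append(row)
            best = select_model(fits)
            rows_by_model[best.spec.name]["selected"] = True
            selected_fits[phen] = best
            if best.spec.has_spatial:
                blups = blup_spatial(best)
                for loc, b in zip(graph.locations, blups):
                    blup_rows.append({"phenotype": phen, "location_id": loc,
                                      "blup": b})
            status[phen] = "ok"
        except Exception as exc:  # phenome loop must not abort
            status[phen] = f"failed: {exc}"

    fits_df = pd.DataFrame(fit_rows)
    if "selected" in fits_df.columns:
        fits_df["selected"] = (fits_df["selected"] == True)  # noqa: E712
    elif len(fits_df):
        fits_df["selected"] = False
    fits_df.to_csv(outdir / "fit_results.tsv", sep="\t", index=False,
                   float_format="%.10g")
    blups_df = pd.DataFrame(blup_rows)
    blups_df.to_csv(outdir / "blups.tsv", sep="\t", index=False,
                    float_format="%.10g")

    if config.location_covariates is not None and len(blups_df):
        covs = read_location_covariates(config.location_covariates)
        wide = blups_df.pivot(index="phenotype", columns="location_id",
                              values="blup")
        info = pd.DataFrame({
            "prevalence": {p: float(phenotypes[p].mean()) for p in wide.index},
            "spatial_var": {
                p: (selected_fits[p].vc.gower_sigma_s2 or 0.0)
                / selected_fits[p].vc.total() for p in wide.index},
        })
        corr = correlate_blup_covariates(
            wide, covs, info, min_prevalence=config.blup_min_prevalence,
            min_spatial_var=config.blup_min_spatial_var)
        corr.to_csv(outdir / "blup_correlations.tsv", sep="\t", index=False,
                    float_format="%.10g")

    if config.exposures is not None:
        exposures, instruments = read_exposures(config.exposures)
        causal_rows = []
        for phen in phenotypes.columns:
            Y = phenotypes[phen].to_numpy()
            K = float(Y.mean())
            for exp_name in config.causal_exposures:
                try:
                    fs = causal_mod.first_stage_predict(
                        exposures[exp_name], instruments)
                    est = causal_mod.fit_smile2(
                        cohort, Y, fs.fitted, X, first_stage=fs,
                        n_starts=1)
                    causal_rows.append({
                        "trait": phen, "exposure": exp_name, "beta": est.beta,
                        "se": est.se, "p_value": est.p_value,
                        "odds_ratio": est.odds_ratio,
                        "first_stage_r2": est.first_stage_r2,
                        "prevalence": K,
                    })
                except Exception as exc:
                    status[f"{phen}:{exp_name}"] = f"causal failed: {exc}"
        if causal_rows:
            screen = causal_mod.phenome_screen(
                pd.DataFrame(causal_rows),
                n_exposures=len(config.causal_exposures),
                min_prevalence=config.causal_min_prevalence)
            screen.to_csv(outdir / "causal_screen.tsv", sep="\t", index=False,
                          float_format="%.10g")

    log = {
        "seed": config.seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "wall_time_s": round(time.time() - t0, 3),
        "n_individuals": cohort.n_individuals,
        "n_families": cohort.n_families,
        "n_locations": graph.L,
        "phenotype_status": status,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return log
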