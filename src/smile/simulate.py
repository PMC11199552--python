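"""Synthetic cohort generator: spatial nuclear-family cohorts, liability
threshold phenotypes, confounded pollution exposures with wind instruments,
and robustness perturbations.

The generator emulates the statistical structure of a large insurance-claims
family cohort: nuclear families (default: two parents, two children) placed
on a location graph (default: a 2-D lattice standing in for the county/MSA
border graph) with a heavy-tailed families-per-location distribution;
spatially autocorrelated community random effects (CAR by default); binary
disease outcomes from a liability threshold model; and location-level
pollution exposures driven partly by wind instruments and partly by a
spatially correlated confounder that also raises disease liability
(endogeneity), with the wind instruments exogenous by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, solve_triangular

from .pedigree import Cohort, Family, Individual, kinship_matrix
from .spatial import LocationGraph, SpatialSpec, build_location_graph, unit_precision
from .vc_model import VarianceComponents


class SimulationError(ValueError):
    pass


def default_variance_components() -> VarianceComponents:
    """Liability-scale generating values for a moderately heritable disease
    with family- and community-level environment (components sum to 1)."""
    return VarianceComponents(
        sigma_g2=0.30, sigma_par2=0.10, sigma_child2=0.10,
        sigma_s2=0.05, sigma_eps2=0.45, rho=0.6, scale="liability",
    )


@dataclass
class SimulationScenario:
    """All knobs of one simulation condition.

    Liability-scale variance components must sum to 1 (the threshold is set
    against the unit-variance baseline liability).  ``rr`` is the causal
    effect of one standard deviation of pollutant exposure expressed as a
    relative risk at prevalence ``prevalence``.
    """

    n_families: int = 2000
    lattice: tuple[int, int] = (10, 10)
    n_children_probs: dict = field(default_factory=lambda: {2: 1.0})
    vc: VarianceComponents = field(default_factory=default_variance_components)
    spatial_structure: str = "CAR"
    prevalence: float = 0.05
    rr: float = 1.0
    pollutant: str = "pm25"
    confounder_effect: float = 0.15
    instrument_strength: float = 0.8
    confounder_weight: float = 0.5
    exposure_noise_sd: float = 0.6
    allocation: str = "lognormal"  # or "even"
    allocation_sigma: float = 1.25
    sex_effect: float = 0.0
    first_year_range: tuple[int, int] = (2005, 2011)
    binary: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise SimulationError("prevalence must be in (0, 1)")
        if self.rr * self.prevalence >= 1.0:
            raise SimulationError("rr * prevalence must be < 1")
        tot = (self.vc.sigma_g2 + self.vc.sigma_par2 + self.vc.sigma_child2
               + self.vc.sigma_s2 + self.vc.sigma_eps2)
        if abs(tot - 1.0) > 1e-8:
            raise SimulationError(
                f"liability variance components must sum to 1, got {tot}")
        if abs(sum(self.n_children_probs.values()) - 1.0) > 1e-8:
            raise SimulationError("family-size probabilities must sum to 1")


@dataclass
class TruthTable:
    """Generating values aligned to an emitted cohort."""

    vc: VarianceComponents
    u_s: np.ndarray
    liabilities: np.ndarray
    threshold: float
    beta_liab: float
    prevalence: float
    kinship_overrides: dict = field(default_factory=dict)
    mislabeled: pd.DataFrame | None = None


def rr_to_liability_shift(rr: float, K: float) -> float:
    """Liability shift per +1 SD exposure giving relative risk ``rr`` at
    baseline prevalence ``K`` under the liability threshold model."""
    if rr * K >= 1.0:
        raise SimulationError("rr * K must be < 1")
    t = stats.norm.ppf(1.0 - K)
    return t - stats.norm.ppf(1.0 - rr * K)


def lattice_graph(rows: int, cols: int) -> LocationGraph:
    """Rectangular 4-neighbor lattice of rows x cols locations."""
    locations = [f"loc_{r}_{c}" for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((f"loc_{r}_{c}", f"loc_{r}_{c + 1}"))
            if r + 1 < rows:
                edges.append((f"loc_{r}_{c}", f"loc_{r + 1}_{c}"))
    return build_location_graph(edges, locations)


def simulate_cohort(
    scenario: SimulationScenario, rng: np.random.Generator
) -> tuple[Cohort, LocationGraph]:
    """Place nuclear families on the location graph.

    Under ``allocation="lognormal"`` each location receives a log-normal
    weight, giving the heavy-tailed families-per-location profile seen in
    claims data; ``allocation="even"`` spreads families as evenly as
    possible (useful for calibration studies with minimal clustering).
    """
    graph = lattice_graph(*scenario.lattice)
    L = graph.L
    if scenario.allocation == "lognormal":
        weights = rng.lognormal(mean=0.0, sigma=scenario.allocation_sigma, size=L)
        fam_loc = rng.choice(L, size=scenario.n_families, p=weights / weights.sum())
    elif scenario.allocation == "even":
        fam_loc = np.arange(scenario.n_families) % L
        rng.shuffle(fam_loc)
    else:
        raise SimulationError(f"unknown allocation {scenario.allocation!r}")

    sizes = np.array(sorted(scenario.n_children_probs))
    probs = np.array([scenario.n_children_probs[s] for s in sizes])
    n_children = rng.choice(sizes, size=scenario.n_families, p=probs)
    y0, y1 = scenario.first_year_range
    first_year = rng.integers(y0, y1 + 1, size=scenario.n_families)

    families = []
    for f in range(scenario.n_families):
        fid = f"fam{f}"
        loc = graph.locations[fam_loc[f]]
        fy = int(first_year[f])
        members = []
        father_by = fy - 47 + int(np.round(rng.normal(0, 4)))
        mother_by = fy - 45 + int(np.round(rng.normal(0, 4)))
        months = int(np.clip(72 + rng.exponential(17.0), 72, 156))
        members.append(Individual(f"{fid}_f", fid, "father", "M", father_by, months, loc))
        members.append(Individual(f"{fid}_m", fid, "mother", "F", mother_by, months, loc))
        child_years = fy - rng.integers(11, 19, size=int(n_children[f]))
        for c, by in enumerate(sorted(child_years)):
            sex = "M" if rng.random() < 0.5 else "F"
            members.append(Individual(f"{fid}_c{c}", fid, "child", sex, int(by), months, loc))
        families.append(Family(fid, members))
    return Cohort(families), graph


def simulate_spatial_effects(
    graph: LocationGraph,
    spec: SpatialSpec,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n_reps vectors from MVN(0, Sigma_structure) over locations."""
    P0 = unit_precision(graph, spec.structure, spec.rho).toarray()
    # x = chol(P0)^-T z  has covariance P0^-1
    c, low = cho_factor(P0, lower=True)
    z = rng.standard_normal((graph.L, n_reps))
    x = solve_triangular(c, z, lower=True, trans="T")
    return np.sqrt(spec.sigma_s2) * x.T


def _family_component_draws(
    cohort: Cohort, var_shared_parents: float, var_shared_children: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual draws of the parental- and child-shared environment."""
    n_f = cohort.n_families
    par = np.empty(cohort.n_individuals)
    child = np.empty(cohort.n_individuals)
    shared_par = rng.normal(0, 1, n_f)
    shared_child = rng.normal(0, 1, n_f)
    is_child = cohort.roles == "child"
    fam = cohort.family_index
    own_par = rng.normal(0, 1, cohort.n_individuals)
    own_child = rng.normal(0, 1, cohort.n_individuals)
    par[:] = np.sqrt(var_shared_parents) * np.where(
        is_child, own_par, shared_par[fam])
    child[:] = np.sqrt(var_shared_children) * np.where(
        is_child, shared_child[fam], own_child)
    return par, child


def simulate_phenotype(
    cohort: Cohort,
    graph: LocationGraph,
    scenario: SimulationScenario,
    rng: np.random.Generator,
    *,
    exposure_z: np.ndarray | None = None,
    confounder: np.ndarray | None = None,
    kinship_overrides: dict | None = None,
) -> tuple[np.ndarray, TruthTable]:
    """Simulate liabilities and (by default) threshold them into 0/1 disease.

    liability = genetic + parental + children + spatial + causal exposure
    term + confounder term + residual; the disease indicator is 1 where
    liability exceeds the (1 - K) quantile of the baseline (unit-variance)
    liability distribution.  ``exposure_z`` and ``confounder`` are
    per-location vectors; ``kinship_overrides`` maps family index to the
    true relationship matrix (used by the relationship-error injector).
    """
    vc = scenario.vc
    kinship_overrides = kinship_overrides or {}
    N = cohort.n_individuals
    liab = np.zeros(N)

    # genetic effects: per-family MVN with (possibly perturbed) kinship
    if vc.sigma_g2 > 0:
        chol_cache: dict[tuple[int, int], np.ndarray] = {}
        g_eff = np.empty(N)
        offset = 0
        for fi, fam in enumerate(cohort.families):
            k = fam.size
            if fi in kinship_overrides:
                cmat = np.linalg.cholesky(
                    kinship_overrides[fi] + 1e-10 * np.eye(k))
            else:
                sig = fam.signature
                if sig not in chol_cache:
                    chol_cache[sig] = np.linalg.cholesky(
                        kinship_matrix(fam) + 1e-10 * np.eye(k))
                cmat = chol_cache[sig]
            g_eff[offset:offset + k] = cmat @ rng.standard_normal(k)
            offset += k
        liab += np.sqrt(vc.sigma_g2) * g_eff

    par_eff, child_eff = _family_component_draws(
        cohort, vc.sigma_par2, vc.sigma_child2, rng)
    liab += par_eff + child_eff

    ind_loc = cohort.family_location_index(graph.locations)[cohort.family_index]
    u_s = np.zeros(graph.L)
    if vc.sigma_s2 > 0:
        # vc.sigma_s2 is the average per-individual (Gower-standardized)
        # spatial variance; rescale the structure so the realized cohort-level
        # Gower factor of the generating covariance equals it exactly.
        from .spatial import gower_factor_from_counts, spatial_covariance
        counts = np.bincount(ind_loc, minlength=graph.L).astype(float)
        Sigma0 = spatial_covariance(
            graph, SpatialSpec(scenario.spatial_structure, 1.0, vc.rho))
        g0 = gower_factor_from_counts(counts, Sigma0)
        u_s = simulate_spatial_effects(
            graph,
            SpatialSpec(scenario.spatial_structure, vc.sigma_s2 / g0, vc.rho),
            1, rng)[0]
        # the cohort-wide mean of community effects is absorbed by the
        # intercept and not identifiable; draw effects centred so the
        # per-individual spatial variance equals the Gower target exactly
        u_s = u_s - np.average(u_s, weights=np.maximum(counts, 1e-12))
        liab += u_s[ind_loc]

    beta_liab = 0.0
    if exposure_z is not None and scenario.rr != 1.0:
        beta_liab = rr_to_liability_shift(scenario.rr, scenario.prevalence)
        liab += beta_liab * np.asarray(exposure_z)[ind_loc]
    if confounder is not None and scenario.confounder_effect != 0.0:
        liab += scenario.confounder_effect * np.asarray(confounder)[ind_loc]
    if scenario.sex_effect != 0.0:
        liab += scenario.sex_effect * (cohort.sex == "M")

    liab += np.sqrt(vc.sigma_eps2) * rng.standard_normal(N)

    threshold = stats.norm.ppf(1.0 - scenario.prevalence)
    Y = (liab > threshold).astype(float) if scenario.binary else liab
    truth = TruthTable(
        vc=vc, u_s=u_s, liabilities=liab, threshold=threshold,
        beta_liab=beta_liab, prevalence=float((liab > threshold).mean()),
        kinship_overrides=kinship_overrides,
    )
    return Y, truth


def encode_wind(instruments: pd.DataFrame) -> pd.DataFrame:
    """Circular-safe instrument encoding: (sin, cos, speed, speed*sin,
    speed*cos) of the long-term wind direction/speed."""
    theta = np.deg2rad(instruments["wind_dir"].to_numpy(dtype=float))
    v = instruments["wind_speed"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "sin_dir": np.sin(theta),
            "cos_dir": np.cos(theta),
            "speed": v,
            "speed_sin": v * np.sin(theta),
            "speed_cos": v * np.cos(theta),
        },
        index=instruments.index,
    )


def _smooth_field(graph: LocationGraph, rng: np.random.Generator,
                  rho: float = 0.9) -> np.ndarray:
    """Unit-variance spatially smooth field via a CAR draw."""
    f = simulate_spatial_effects(graph, SpatialSpec("CAR", 1.0, rho), 1, rng)[0]
    return (f - f.mean()) / f.std()


def simulate_exposure_instruments(
    graph: LocationGraph,
    scenario: SimulationScenario,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Location-level exposures, wind instruments, and the hidden confounder.

    exposure = instrument component + spatially correlated confounder +
    noise.  The confounder also raises disease liability (endogeneity); the
    wind field is drawn independently of the confounder, so instrument
    exogeneity holds by construction.
    """
    idx = pd.Index(graph.locations, name="location_id")
    speed = np.clip(4.0 + 1.5 * _smooth_field(graph, rng), 0.1, None)
    direction = np.mod(225.0 + 60.0 * _smooth_field(graph, rng), 360.0)
    instruments = pd.DataFrame(
        {"wind_speed": speed, "wind_dir": direction}, index=idx)

    E = encode_wind(instruments).to_numpy()
    E = (E - E.mean(axis=0)) / np.where(E.std(axis=0) < 1e-12, 1.0, E.std(axis=0))
    confounder = _smooth_field(graph, rng, rho=0.6)

    def one_exposure(loc_mean: float, loc_sd: float) -> np.ndarray:
        gamma = rng.normal(size=E.shape[1])
        signal = E @ gamma
        signal = (signal - signal.mean()) / signal.std()
        x = (scenario.instrument_strength * signal
             + scenario.confounder_weight * confounder
             + scenario.exposure_noise_sd * rng.standard_normal(graph.L))
        return loc_mean + loc_sd * (x - x.mean()) / x.std()

    pm25 = one_exposure(8.0, 3.0)
    no2 = one_exposure(10.0, 4.0)
    exposures = pd.DataFrame({"pm25": pm25, "no2": no2}, index=idx)
    exposures["psum"] = (
        stats.zscore(exposures["pm25"]) + stats.zscore(exposures["no2"]))
    return exposures, instruments, confounder


def inject_relationship_errors(
    cohort: Cohort, error_rate: float, rng: np.random.Generator
) -> tuple[Cohort, dict, pd.DataFrame]:
    """Relabel a fraction of children as biological when they are not.

    Each selected child becomes, with equal probability, "adopted" (no
    genetic sharing with either parent or any sibling) or a "stepchild"
    (shares one parent: 0.5 with that parent, 0 with the other, 0.25 with
    full siblings).  Labels in the cohort are unchanged — exactly the
    miscoding being emulated; the returned kinship overrides carry the true
    relationship matrices for the simulator, and the table records who was
    mislabeled.
    """
    if not 0.0 <= error_rate <= 0.5:
        raise SimulationError("error_rate must be in [0, 0.5]")
    overrides: dict[int, np.ndarray] = {}
    records = []
    if error_rate == 0.0:
        return cohort, overrides, pd.DataFrame(
            columns=["individual_id", "family_id", "error_type"])
    for fi, fam in enumerate(cohort.families):
        n_p, n_c = fam.signature
        if n_c == 0:
            continue
        hit = rng.random(n_c) < error_rate
        if not hit.any():
            continue
        G = kinship_matrix(fam).copy()
        kinds = []
        for ci in np.flatnonzero(hit):
            row = n_p + ci
            kind = "adopted" if rng.random() < 0.5 else "stepchild"
            kinds.append((ci, kind))
            records.append({
                "individual_id": fam.children[ci].individual_id,
                "family_id": fam.family_id,
                "error_type": kind,
            })
        for ci, kind in kinds:
            row = n_p + ci
            if kind == "adopted":
                G[row, :] = 0.0
                G[:, row] = 0.0
            else:
                if n_p > 0:
                    off = rng.integers(n_p)  # parent the child is unrelated to
                    G[row, off] = G[off, row] = 0.0
                for sib in range(n_p, n_p + n_c):
                    if sib != row and G[row, sib] == 0.5:
                        G[row, sib] = G[sib, row] = 0.25
            G[row, row] = 1.0
        # adopted/step pairs among mislabeled sibs: conservative zero/quarter
        for i, (ci, ki) in enumerate(kinds):
            for cj, kj in kinds[i + 1:]:
                ri, rj = n_p + ci, n_p + cj
                if "adopted" in (ki, kj):
                    G[ri, rj] = G[rj, ri] = 0.0
        overrides[fi] = G
    return cohort, overrides, pd.DataFrame(records)


def add_measurement_noise(
    exposures: pd.DataFrame,
    instruments: pd.DataFrame,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add independent Gaussian measurement noise.

    ``noise_sd`` is relative: each pollution/speed column receives noise
    with standard deviation noise_sd times that column's spread; wind
    direction receives noise_sd * 45 degrees, wrapped to [0, 360).
    """
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    exp2 = exposures.copy()
    inst2 = instruments.copy()
    if noise_sd == 0.0:
        return exp2, inst2
    for col in ["pm25", "no2"]:
        exp2[col] = exp2[col] + rng.normal(
            0, noise_sd * exp2[col].std(), len(exp2))
    exp2["psum"] = stats.zscore(exp2["pm25"]) + stats.zscore(exp2["no2"])
    inst2["wind_speed"] = np.clip(
        inst2["wind_speed"] + rng.normal(
            0, noise_sd * inst2["wind_speed"].std(), len(inst2)), 0.0, None)
    inst2["wind_dir"] = np.mod(
        inst2["wind_dir"] + rng.normal(0, noise_sd * 45.0, len(inst2)), 360.0)
    return exp2, inst2


def scenario_grid(
    base: SimulationScenario,
    rr_values: tuple = (1.0, 1.01, 1.05, 1.1, 1.2),
    prevalence_values: tuple | None = None,
    pollutants: tuple = ("pm25",),
) -> list[SimulationScenario]:
    """Cartesian grid of causal-simulation scenarios over relative risk,
    prevalence, and pollutant (the replicate-grid protocol of the causal
    power study)."""
    prevs = prevalence_values if prevalence_values is not None else (base.prevalence,)
    out = []
    for rr in rr_values:
        for K in prevs:
            for pol in pollutants:
                out.append(replace(base, rr=rr, prevalence=K, pollutant=pol))
    return out
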