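"""Synthetic landscape generator mirroring the model's simulation study.

A 900-cell study area is split into three contiguous regions with
contrasting covariates: region 1 (360 cells) has high V1 / low V2, region 2
(180 cells) high V2 / low V1, region 3 (360 cells) intermediate values of
both.  Each cell holds one location (a cluster of villages) with a number of
households drawn around region-specific means (40 / 100 / 65), a mean of 5
adult-male equivalents (AME) per household, and a two-level categorical
covariate V3 per household (levels 30% / 70%).

Three generative processes, with region-varying intercepts and slopes,
define the ground truth:

* consumption probability: logit-linear in V1 and V3 plus a latent spatial
  Gaussian process over the inter-location distance matrix, plus a
  recall-duration increment;
* frequency of consumption: logit-linear in V2 and V3;
* per-AME daily quantity (kg): log-linear in V2 and household AME, with
  Gamma observation noise.

``observe`` then emulates a field campaign: a coverage fraction of
locations is surveyed; 80% of surveyed locations report frequency and 50%
report quantities; 20% of households lack AME information; observed
frequencies carry logit-normal noise whose standard deviation scales with
the number of unmonitored days (sigma * (365 - mdays), vanishing for a
household monitored every day of the year).

The generative coefficient values are package defaults chosen so that about
16% of recall events register consumption, matching the preponderance of
non-consumption records in real recall surveys; they are freely
overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survey import build_distance_matrix

__all__ = [
    "LandscapeSpec",
    "GenerativeParams",
    "ObservationSpec",
    "Landscape",
    "GroundTruth",
    "generate_landscape",
    "simulate_truth",
    "observe",
    "prediction_cells",
]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class LandscapeSpec:
    """Geometry and population structure of the simulated study area."""

    n_side: int = 30
    region_rows: tuple = (12, 6, 12)  # -> 360 / 180 / 360 cells
    cell_side_deg: float = 0.63  # ~70 km at the equator
    origin_lon: float = 10.0
    origin_lat: float = -9.0
    v1_means: tuple = (1.0, -1.0, 0.0)
    v2_means: tuple = (-1.0, 1.0, 0.0)
    covariate_sd: float = 0.4
    household_count_means: tuple = (40.0, 100.0, 65.0)
    ame_mean: float = 5.0
    v3_level_probs: tuple = (0.30, 0.70)

    def __post_init__(self):
        if sum(self.region_rows) != self.n_side:
            raise ValueError("region_rows must sum to the number of grid rows")
        if abs(sum(self.v3_level_probs) - 1.0) > 1e-9:
            raise ValueError("v3_level_probs must sum to 1")
        if min(self.household_count_means) <= 0 or self.ame_mean <= 0:
            raise ValueError("household and AME means must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_side * self.n_side

    @property
    def region_sizes(self) -> tuple:
        return tuple(r * self.n_side for r in self.region_rows)


@dataclass(frozen=True)
class GenerativeParams:
    """True coefficients of the three generative processes.

    Arrays of length 3 are region-varying (intercepts, continuous slopes);
    scalars are shared.  V3 uses reference coding: the coefficient is the
    effect of the common (70%) level relative to the rare (30%) one.
    """

    # consumption: logit pi = a0[r] + a1[r] V1 + a_v3 V3 + eps + a_days days
    a0: tuple = (-2.2, -2.6, -2.4)
    a1: tuple = (0.8, 0.5, 0.6)
    a_v3: float = 0.4
    a_days: float = 0.05
    zeta: float = 0.5  # GP marginal sd
    rho: float = 0.006  # GP inverse length scale, 1/km
    # frequency: logit phibar = b0[r] + b1[r] V2 + b_v3 V3
    b0: tuple = (-1.7, -2.1, -1.9)
    b1: tuple = (0.5, 0.3, 0.4)
    b_v3: float = 0.3
    sigma: float = 0.004  # logit-sd per unmonitored day
    # quantity: log mu = c0[r] + c1[r] V2 + c_ame AME ; Gamma(mu*theta, theta)
    c0: tuple = (-1.0, -1.3, -1.15)
    c1: tuple = (0.35, 0.2, 0.3)
    c_ame: float = -0.03
    theta: float = 2.0

    def coefficient_dict(self) -> dict:
        """Named scalar regression coefficients (for recovery checks)."""
        out = {}
        for name in ("a0", "a1", "b0", "b1", "c0", "c1"):
            for r, v in enumerate(getattr(self, name), start=1):
                out[f"{name}[{r}]"] = float(v)
        for name in ("a_v3", "a_days", "b_v3", "c_ame"):
            out[name] = float(getattr(self, name))
        return out


@dataclass(frozen=True)
class ObservationSpec:
    """How much of the landscape a simulated survey campaign observes."""

    coverage: float = 0.10
    frac_frequency_locations: float = 0.80
    frac_quantity_locations: float = 0.50
    frac_missing_ame: float = 0.20
    household_sampling_fraction: float = 0.10
    recalls_per_household_mean: float = 3.0
    locations_per_study: int = 10

    def __post_init__(self):
        for name in (
            "coverage",
            "frac_frequency_locations",
            "frac_quantity_locations",
            "household_sampling_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not 0.0 <= self.frac_missing_ame < 1.0:
            raise ValueError("frac_missing_ame must lie in [0, 1)")


@dataclass
class Landscape:
    """Generated landscape: cells, households, inter-location distances."""

    spec: LandscapeSpec
    cells: pd.DataFrame
    households: pd.DataFrame
    distance_km: np.ndarray


@dataclass
class GroundTruth:
    """True per-household and aggregate quantities of a simulated landscape."""

    params: GenerativeParams
    landscape: Landscape
    eps: np.ndarray  # latent spatial effect per cell
    households: pd.DataFrame  # with true pi (days=1), phi, mu, rate, ame

    @property
    def total_tonnes(self) -> float:
        """Annual tonnes via the cell-sum route: sum over cells of the
        AME-weighted mean rate times the cell's AME and 365 days."""
        hh = self.households
        by_cell = hh.groupby("cell_id").apply(
            lambda g: (g["rate"] * g["ame"]).sum(), include_groups=False
        )
        return float(by_cell.sum() * 365.0 / 1000.0)

    @property
    def total_tonnes_household_sum(self) -> float:
        """Annual tonnes via the household-sum route (must agree)."""
        hh = self.households
        return float((hh["rate"] * hh["ame"]).sum() * 365.0 / 1000.0)

    def summary(self) -> dict:
        hh = self.households
        return {
            "mean_consumption_probability": float(hh["pi"].mean()),
            "mean_frequency": float(hh["phi"].mean()),
            "mean_quantity_kg_per_ame": float(hh["mu"].mean()),
            "mean_rate_kg_per_ame_day": float(hh["rate"].mean()),
            "total_tonnes_per_year": self.total_tonnes,
            "n_households": int(len(hh)),
            "total_ame": float(hh["ame"].sum()),
        }


def generate_landscape(
    spec: LandscapeSpec = LandscapeSpec(), seed: int = 0
) -> Landscape:
    """Draw the landscape: covariates, household counts, AMEs, V3 labels.

    Household counts are Poisson around the region means; AMEs are Poisson
    around the global mean, truncated at 1 (a household has at least one
    member).  Regions are contiguous row blocks of the grid.  Output is
    deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_side
    rows, cols = np.divmod(np.arange(spec.n_cells), n)
    region = np.empty(spec.n_cells, dtype=int)
    boundaries = np.cumsum(spec.region_rows)
    region[:] = np.searchsorted(boundaries, rows, side="right")

    v1 = rng.normal(np.asarray(spec.v1_means)[region], spec.covariate_sd)
    v2 = rng.normal(np.asarray(spec.v2_means)[region], spec.covariate_sd)
    n_households = rng.poisson(np.asarray(spec.household_count_means)[region])
    n_households = np.maximum(n_households, 1)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(spec.n_cells),
            "region": region + 1,
            "row": rows,
            "col": cols,
            "lon": spec.origin_lon + (cols + 0.5) * spec.cell_side_deg,
            "lat": spec.origin_lat + (rows + 0.5) * spec.cell_side_deg,
            "v1": v1,
            "v2": v2,
            "n_households": n_households,
        }
    )

    total_h = int(n_households.sum())
    cell_of_h = np.repeat(np.arange(spec.n_cells), n_households)
    ame = np.maximum(rng.poisson(spec.ame_mean, size=total_h), 1).astype(float)
    v3 = rng.choice([0, 1], size=total_h, p=spec.v3_level_probs)
    households = pd.DataFrame(
        {
            "household_id": [f"h{i:06d}" for i in range(total_h)],
            "cell_id": cell_of_h,
            "region": region[cell_of_h] + 1,
            "v1": v1[cell_of_h],
            "v2": v2[cell_of_h],
            "v3": v3,
            "ame": ame,
        }
    )
    distance_km = build_distance_matrix(cells)
    return Landscape(spec, cells, households, distance_km)


def simulate_truth(
    landscape: Landscape,
    params: GenerativeParams = GenerativeParams(),
    seed: int = 1,
) -> GroundTruth:
    """Draw the latent spatial effect and compute true household quantities.

    ``pi`` is the daily (1-day recall) consumption probability, ``phi`` the
    true frequency of consumption, ``mu`` the expected per-AME daily
    quantity, and ``rate = pi * phi * mu`` the true consumption rate in
    kg/AME/day.
    """
    rng = np.random.default_rng(seed)
    D = landscape.distance_km
    if params.zeta > 0.0:
        cov = params.zeta**2 * np.exp(-(params.rho**2) * D**2)
        cov[np.diag_indices_from(cov)] += 1e-9
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "GP covariance not positive definite after jitter"
            ) from err
        eps = L @ rng.standard_normal(len(D))
    else:
        eps = np.zeros(len(D))

    hh = landscape.households.copy()
    r = hh["region"].to_numpy() - 1
    a0 = np.asarray(params.a0)[r]
    a1 = np.asarray(params.a1)[r]
    b0 = np.asarray(params.b0)[r]
    b1 = np.asarray(params.b1)[r]
    c0 = np.asarray(params.c0)[r]
    c1 = np.asarray(params.c1)[r]
    v1 = hh["v1"].to_numpy()
    v2 = hh["v2"].to_numpy()
    v3 = hh["v3"].to_numpy()
    ame = hh["ame"].to_numpy()
    eps_h = eps[hh["cell_id"].to_numpy()]

    hh["logit_pi1"] = a0 + a1 * v1 + params.a_v3 * v3 + eps_h + params.a_days * 1.0
    hh["pi"] = _sigmoid(hh["logit_pi1"])
    hh["logit_phibar"] = b0 + b1 * v2 + params.b_v3 * v3
    hh["phi"] = _sigmoid(hh["logit_phibar"])
    hh["mu"] = np.exp(c0 + c1 * v2 + params.c_ame * ame)
    hh["rate"] = hh["pi"] * hh["phi"] * hh["mu"]
    return GroundTruth(params, landscape, eps, hh)


def prediction_cells(landscape: Landscape) -> pd.DataFrame:
    """Prediction-grid frame for the simulated landscape.

    Columns follow :func:`wildmeat.predict.sim_cell_design`: region
    one-hots, region-specific covariate columns, the cell's household share
    in the common V3 level, a unit recall-duration column (daily rates),
    the mean household AME (entering the quantity predictor) and the total
    AME (scaling rates into biomass).
    """
    hh = landscape.households
    by_cell = hh.groupby("cell_id").agg(
        v3_prop=("v3", "mean"), ame_bar=("ame", "mean"), ame=("ame", "sum")
    )
    cells = landscape.cells.set_index("cell_id").join(by_cell)
    out = pd.DataFrame(index=cells.index)
    for r in (1, 2, 3):
        out[f"r{r}"] = (cells["region"] == r).astype(float)
        out[f"v1_r{r}"] = np.where(cells["region"] == r, cells["v1"], 0.0)
        out[f"v2_r{r}"] = np.where(cells["region"] == r, cells["v2"], 0.0)
    out["v3_prop"] = cells["v3_prop"]
    out["days_one"] = 1.0
    out["ame_bar"] = cells["ame_bar"]
    out["ame"] = cells["ame"]
    return out


def _log_uniform_days(rng, size, low=1, high=365):
    return np.floor(
        np.exp(rng.uniform(np.log(low), np.log(high + 1), size=size))
    ).astype(int).clip(low, high)


def observe(
    truth: GroundTruth,
    obs_spec: ObservationSpec = ObservationSpec(),
    seed: int = 2,
) -> dict:
    """Simulate a survey campaign over the ground truth.

    Returns the four survey tables (``studies``, ``locations``,
    ``households``, ``recalls``) in the ingestion schema, plus
    ``sampled_cells`` bookkeeping.  Locations carry the cell covariates V1
    and V2; households carry V3 and (where not masked) the AME.
    """
    rng = np.random.default_rng(seed)
    landscape = truth.landscape
    params = truth.params
    n_cells = landscape.spec.n_cells

    n_sampled = int(round(obs_spec.coverage * n_cells))
    if n_sampled < 1:
        raise ValueError(
            f"coverage {obs_spec.coverage} yields zero surveyed locations"
        )
    sampled_cells = np.sort(rng.choice(n_cells, size=n_sampled, replace=False))

    # Exact fractions of surveyed locations report frequency / quantity.
    perm = rng.permutation(n_sampled)
    n_freq = int(round(obs_spec.frac_frequency_locations * n_sampled))
    n_qty = int(round(obs_spec.frac_quantity_locations * n_sampled))
    freq_flag = np.zeros(n_sampled, dtype=bool)
    freq_flag[perm[:n_freq]] = True
    qty_flag = np.zeros(n_sampled, dtype=bool)
    qty_flag[rng.permutation(n_sampled)[:n_qty]] = True

    cells = landscape.cells.set_index("cell_id")
    loc_ids = [f"loc{c:04d}" for c in sampled_cells]
    locations = pd.DataFrame(
        {
            "location_id": loc_ids,
            "lon": cells.loc[sampled_cells, "lon"].to_numpy(),
            "lat": cells.loc[sampled_cells, "lat"].to_numpy(),
            "location_type": "village",
            "region": cells.loc[sampled_cells, "region"].to_numpy(),
            "v1": cells.loc[sampled_cells, "v1"].to_numpy(),
            "v2": cells.loc[sampled_cells, "v2"].to_numpy(),
        }
    )

    # Studies group locations sharing a reporting profile.
    profile = freq_flag.astype(int) * 2 + qty_flag.astype(int)
    study_rows, study_of_loc = [], {}
    sid = 0
    for prof in np.unique(profile):
        members = np.flatnonzero(profile == prof)
        for start in range(0, len(members), obs_spec.locations_per_study):
            chunk = members[start : start + obs_spec.locations_per_study]
            study_id = f"study{sid:03d}"
            # Quantity studies are short-recall (ST 1); others long-recall (ST 2).
            st = 1 if bool(prof & 1) else 2
            study_rows.append({"study_id": study_id, "study_type": st, "period": 2})
            for m in chunk:
                study_of_loc[loc_ids[m]] = study_id
            sid += 1
    studies = pd.DataFrame(study_rows)
    locations["study_id"] = locations["location_id"].map(study_of_loc)

    hh_all = truth.households
    hh_rows, recall_rows = [], []
    rid = 0
    for i, cell in enumerate(sampled_cells):
        members = hh_all.loc[hh_all["cell_id"] == cell]
        m = max(1, int(round(obs_spec.household_sampling_fraction * len(members))))
        chosen = members.iloc[
            rng.choice(len(members), size=min(m, len(members)), replace=False)
        ]
        for _, h in chosen.iterrows():
            mdays = int(_log_uniform_days(rng, 1)[0])
            if freq_flag[i]:
                mdays = max(mdays, 2)
            n_rec = int(min(mdays, 1 + rng.poisson(
                max(obs_spec.recalls_per_household_mean - 1.0, 0.0))))
            base, extra = divmod(mdays, n_rec)
            days = np.full(n_rec, base, dtype=int)
            days[:extra] += 1

            freq_obs = np.nan
            if freq_flag[i]:
                noise = params.sigma * (365 - mdays) * rng.standard_normal()
                freq_obs = float(_sigmoid(h["logit_phibar"] + noise))

            hh_rows.append(
                {
                    "household_id": h["household_id"],
                    "location_id": loc_ids[i],
                    "mdays": mdays,
                    "frequency": freq_obs,
                    "education": "unknown",
                    "v3": int(h["v3"]),
                    "ame": float(h["ame"]),
                }
            )
            logit_pi = (
                h["logit_pi1"] - params.a_days * 1.0 + params.a_days * days
            )
            consumed = rng.random(n_rec) < _sigmoid(logit_pi)
            for d, c in zip(days, consumed):
                q = np.nan
                if qty_flag[i] and c:
                    per_ame = rng.gamma(
                        shape=h["mu"] * params.theta, scale=1.0 / params.theta
                    )
                    q = float(per_ame * h["ame"])
                elif qty_flag[i]:
                    q = 0.0
                recall_rows.append(
                    {
                        "recall_id": f"r{rid:07d}",
                        "household_id": h["household_id"],
                        "days": float(d),
                        "consumed": int(c),
                        "quantity_kg": q,
                        "ame": float(h["ame"]),
                    }
                )
                rid += 1

    households = pd.DataFrame(hh_rows)
    recalls = pd.DataFrame(recall_rows)

    # Mask AME for the stated fraction of surveyed households.
    n_missing = int(round(obs_spec.frac_missing_ame * len(households)))
    if n_missing:
        miss_idx = rng.choice(len(households), size=n_missing, replace=False)
        miss_ids = set(households.iloc[miss_idx]["household_id"])
        households.loc[households["household_id"].isin(miss_ids), "ame"] = np.nan
        recalls.loc[recalls["household_id"].isin(miss_ids), "ame"] = np.nan

    return {
        "studies": studies,
        "locations": locations,
        "households": households,
        "recalls": recalls,
        "sampled_cells": sampled_cells,
    }
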