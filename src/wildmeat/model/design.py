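"""Model-ready data assembly: design matrices, groupings, distances.

Two builders are provided.  ``sim_design`` matches the synthetic-landscape
generative structure (region-varying intercepts and slopes on V1/V2, the
two-level V3 factor, the recall-duration term, a GP on the consumption
process) and is used for parameter-recovery work.  ``survey_design`` builds
the full survey structure: population density with location-type-specific
slopes, development, remoteness and forest-condition covariates, an
education factor, period-varying intercepts, study and household random
intercepts, and GPs on both the consumption and frequency processes.

Observed frequencies exactly at the Beta boundary (0 or 1) are clamped to
``[clamp, 1 - clamp]``; the count of clamped records is carried in the
output for the diagnostics report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..survey import SurveyTables, build_distance_matrix

DEFAULT_CLAMP = 1e-4


@dataclass
class REBlock:
    """A random-intercept grouping: per-row level index into n_levels."""

    name: str
    idx: np.ndarray
    n_levels: int


@dataclass
class ModelData:
    """Arrays consumed by :class:`~wildmeat.model.joint.JointPosterior`."""

    # consumption (recall level)
    y_c: np.ndarray
    X_c: np.ndarray
    names_c: list
    loc_c: np.ndarray | None  # row index into D, or None for no GP
    re_c: list = field(default_factory=list)
    # frequency (household level)
    f: np.ndarray = None
    X_f: np.ndarray = None
    names_f: list = field(default_factory=list)
    mdays: np.ndarray = None
    loc_f: np.ndarray | None = None
    # quantity (recall level, consumed > 0 only)
    q: np.ndarray = None
    X_q: np.ndarray = None
    names_q: list = field(default_factory=list)
    ame: np.ndarray = None  # NaN where missing
    imp_idx: np.ndarray = None  # imputation parameter index per row, -1 observed
    n_imp: int = 0
    ame_name: str = "gamma_ame"
    re_q: list = field(default_factory=list)
    # spatial
    D: np.ndarray | None = None
    ame_prior_mean: float = 5.0
    n_clamped: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def has_frequency(self) -> bool:
        return self.f is not None and len(self.f) > 0

    @property
    def has_quantity(self) -> bool:
        return self.q is not None and len(self.q) > 0


def _clamp_frequency(f: np.ndarray, clamp: float) -> tuple[np.ndarray, int]:
    clamped = (f < clamp) | (f > 1.0 - clamp)
    return np.clip(f, clamp, 1.0 - clamp), int(clamped.sum())


def _imputation_index(household_ids, ame_values):
    """Per-row imputation index: one parameter per household lacking AME."""
    miss_households = sorted(
        {h for h, a in zip(household_ids, ame_values) if np.isnan(a)}
    )
    imp_of = {h: i for i, h in enumerate(miss_households)}
    idx = np.array(
        [imp_of.get(h, -1) if np.isnan(a) else -1
         for h, a in zip(household_ids, ame_values)],
        dtype=int,
    )
    return idx, len(miss_households)


def sim_design(tables: SurveyTables, clamp: float = DEFAULT_CLAMP) -> ModelData:
    """Design matrices mirroring the synthetic landscape's generative model.

    Coefficient names match :meth:`GenerativeParams.coefficient_dict` so
    recovery checks can compare by name.
    """
    locs = tables.locations.reset_index(drop=True)
    loc_index = {lid: i for i, lid in enumerate(locs["location_id"])}
    D = build_distance_matrix(locs)

    hh = tables.households.merge(
        locs[["location_id", "region", "v1", "v2"]], on="location_id"
    )
    ready = tables.model_ready()

    def region_design(frame, cont_col, prefix_int, prefix_slope):
        X_cols, names = [], []
        reg = frame["region"].to_numpy()
        cont = frame[cont_col].to_numpy(dtype=float)
        for r in (1, 2, 3):
            X_cols.append((reg == r).astype(float))
            names.append(f"{prefix_int}[{r}]")
        for r in (1, 2, 3):
            X_cols.append(np.where(reg == r, cont, 0.0))
            names.append(f"{prefix_slope}[{r}]")
        return X_cols, names

    # consumption: all recalls
    rec = ready["consumption"].merge(
        hh[["household_id", "region", "v1", "v2", "v3"]], on="household_id"
    )
    X_cols, names_c = region_design(rec, "v1", "a0", "a1")
    X_cols.append(rec["v3"].to_numpy(dtype=float))
    names_c.append("a_v3")
    X_cols.append(rec["days"].to_numpy(dtype=float))
    names_c.append("a_days")
    X_c = np.column_stack(X_cols)
    loc_c = rec["location_id"].map(loc_index).to_numpy()

    # frequency: households reporting it
    fr = ready["frequency"].merge(
        hh[["household_id", "region", "v2", "v3"]], on="household_id"
    )
    Xf_cols, names_f = region_design(fr, "v2", "b0", "b1")
    Xf_cols.append(fr["v3"].to_numpy(dtype=float))
    names_f.append("b_v3")
    f_clamped, n_clamped = _clamp_frequency(
        fr["frequency"].to_numpy(dtype=float), clamp
    )

    # quantity: consumed recalls with a recorded positive quantity
    qt = ready["quantity"]
    qt = qt.loc[qt["quantity_kg"] > 0].merge(
        hh[["household_id", "region", "v2", "v3"]], on="household_id"
    )
    Xq_cols, names_q = region_design(qt, "v2", "c0", "c1")
    imp_idx, n_imp = _imputation_index(
        qt["household_id"].to_numpy(), qt["ame"].to_numpy(dtype=float)
    )
    observed_ame = tables.households["ame"].dropna()
    ame_prior_mean = float(observed_ame.mean()) if len(observed_ame) else 5.0

    return ModelData(
        y_c=rec["consumed"].to_numpy(dtype=float),
        X_c=X_c,
        names_c=names_c,
        loc_c=loc_c,
        f=f_clamped,
        X_f=np.column_stack(Xf_cols),
        names_f=names_f,
        mdays=fr["mdays"].to_numpy(dtype=float),
        loc_f=None,
        q=qt["quantity_kg"].to_numpy(dtype=float),
        X_q=np.column_stack(Xq_cols),
        names_q=names_q,
        ame=qt["ame"].to_numpy(dtype=float),
        imp_idx=imp_idx,
        n_imp=n_imp,
        ame_name="c_ame",
        D=D,
        ame_prior_mean=ame_prior_mean,
        n_clamped=n_clamped,
        meta={"location_ids": list(locs["location_id"])},
    )


def survey_design(
    tables: SurveyTables,
    clamp: float = DEFAULT_CLAMP,
    gp_consumption: bool = True,
    gp_frequency: bool = True,
) -> ModelData:
    """Full survey-schema design matrices.

    Continuous covariates (HPD, HDI, REM, FCI) are z-scored; the scaler is
    stored in ``meta["scalers"]`` for use at prediction time.  The
    population-density slope varies by location type; education enters as a
    three-level main-effect factor (reference: primary-or-none); intercepts
    vary by survey period (reference: period 1); study and household random
    intercepts absorb design and repeated-measurement structure.
    """
    locs = tables.locations.reset_index(drop=True)
    loc_index = {lid: i for i, lid in enumerate(locs["location_id"])}
    D = build_distance_matrix(locs)

    scalers = {}
    loc_cov = locs.copy()
    for col in ("hpd", "rem", "hdi", "fci"):
        mean, sd = float(loc_cov[col].mean()), float(loc_cov[col].std(ddof=0))
        sd = sd if sd > 0 else 1.0
        scalers[col] = (mean, sd)
        loc_cov[col + "_z"] = (loc_cov[col] - mean) / sd

    period_of_study = tables.studies.set_index("study_id")["period"]
    loc_cov["period"] = loc_cov["study_id"].map(period_of_study)

    hh = tables.households.merge(
        loc_cov[
            ["location_id", "location_type", "period",
             "hpd_z", "rem_z", "hdi_z", "fci_z", "study_id"]
        ],
        on="location_id",
    )
    st_of_study = tables.studies.set_index("study_id")["study_type"]
    hh["study_type"] = hh["study_id"].map(st_of_study)
    ready = tables.model_ready()

    def shared_columns(frame, prefix):
        cols, names = [np.ones(len(frame))], [f"{prefix}0"]
        cols.append((frame["period"] == 2).to_numpy(dtype=float))
        names.append(f"{prefix}_period2")
        for lt in ("village", "town", "city"):
            cols.append(
                np.where(frame["location_type"] == lt, frame["hpd_z"], 0.0)
            )
            names.append(f"{prefix}_hpd[{lt}]")
        for cov in ("hdi", "rem", "fci"):
            cols.append(frame[cov + "_z"].to_numpy(dtype=float))
            names.append(f"{prefix}_{cov}")
        for ed in ("secondary_or_higher", "unknown"):
            cols.append((frame["education"] == ed).to_numpy(dtype=float))
            names.append(f"{prefix}_ed[{ed}]")
        return cols, names

    def re_blocks(frame, which):
        blocks = []
        for col, name in which:
            levels = sorted(frame[col].unique())
            level_of = {v: i for i, v in enumerate(levels)}
            blocks.append(
                REBlock(name, frame[col].map(level_of).to_numpy(), len(levels))
            )
        return blocks

    hh_cols = [
        "household_id", "location_id", "education", "location_type",
        "period", "hpd_z", "rem_z", "hdi_z", "fci_z", "study_id", "study_type",
    ]
    rec = ready["consumption"].drop(columns=["location_id"]).merge(
        hh[hh_cols], on="household_id"
    )
    X_cols, names_c = shared_columns(rec, "alpha")
    X_cols.append(rec["days"].to_numpy(dtype=float))
    names_c.append("alpha_days")

    fr = ready["frequency"].drop(columns=["location_id"]).merge(
        hh[hh_cols], on="household_id"
    )
    Xf_cols, names_f = shared_columns(fr, "beta")
    f_clamped, n_clamped = _clamp_frequency(
        fr["frequency"].to_numpy(dtype=float), clamp
    )

    qt = ready["quantity"].drop(columns=["location_id"]).merge(
        hh[hh_cols], on="household_id"
    )
    qt = qt.loc[qt["quantity_kg"] > 0].reset_index(drop=True)
    Xq_cols, names_q = [np.ones(len(qt))], ["gamma0"]
    Xq_cols.append((qt["period"] == 2).to_numpy(dtype=float))
    names_q.append("gamma_period2")
    for lt in ("town", "city"):
        Xq_cols.append((qt["location_type"] == lt).to_numpy(dtype=float))
        names_q.append(f"gamma_lt[{lt}]")
    for ed in ("secondary_or_higher", "unknown"):
        Xq_cols.append((qt["education"] == ed).to_numpy(dtype=float))
        names_q.append(f"gamma_ed[{ed}]")
    for st in (2, 3):
        Xq_cols.append((qt["study_type"] == st).to_numpy(dtype=float))
        names_q.append(f"gamma_st[{st}]")

    imp_idx, n_imp = _imputation_index(
        qt["household_id"].to_numpy(), qt["ame"].to_numpy(dtype=float)
    )
    observed_ame = tables.households["ame"].dropna()
    ame_prior_mean = float(observed_ame.mean()) if len(observed_ame) else 5.0

    return ModelData(
        y_c=rec["consumed"].to_numpy(dtype=float),
        X_c=np.column_stack(X_cols),
        names_c=names_c,
        loc_c=(
            rec["location_id"].map(loc_index).to_numpy() if gp_consumption else None
        ),
        re_c=re_blocks(rec, [("study_id", "study"), ("household_id", "household")]),
        f=f_clamped,
        X_f=np.column_stack(Xf_cols),
        names_f=names_f,
        mdays=fr["mdays"].to_numpy(dtype=float),
        loc_f=(
            fr["location_id"].map(loc_index).to_numpy() if gp_frequency else None
        ),
        q=qt["quantity_kg"].to_numpy(dtype=float),
        X_q=np.column_stack(Xq_cols),
        names_q=names_q,
        ame=qt["ame"].to_numpy(dtype=float),
        imp_idx=imp_idx,
        n_imp=n_imp,
        ame_name="gamma_ame",
        re_q=re_blocks(qt, [("study_id", "study"), ("household_id", "household")]),
        D=D,
        ame_prior_mean=ame_prior_mean,
        n_clamped=n_clamped,
        meta={"location_ids": list(locs["location_id"]), "scalers": scalers},
    )
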