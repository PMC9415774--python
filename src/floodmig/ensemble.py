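"""Monte Carlo ensemble driver and headline analyses.

Each ensemble run draws an emissions scenario, a perceived-normal flooding
multiplier m ~ U(0.5, 1.5), a credit multiplier ~ U(0, 2) and the remaining
decision parameters from their design ranges, runs the simulation, and
records one outcome row. The analyses over the resulting table are the
study's headline diagnostics: per-district net migration, the largest
flows, moored-population shares and covariates, coastal-vs-interior rank
correlation of in-migration with mooring, and random-forest permutation
importance of the drawn parameters.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .calibration import CalibrationPoint, apply_calibration_point
from .config import ExperimentDesign, WorldConfig
from .engine import FlowMatrix, LifeHistories, run_simulation
from .hazard import default_scenario
from .world import World

PARAMETER_COLUMNS = [
    "normal_multiplier",
    "credit_multiplier",
    "k_locations",
    "rho_scale",
    "info_share_prob",
    "p_reconsider_mean",
    "scenario_rise",
]


def run_experiment(design: ExperimentDesign, world: World,
                   collect_details: bool = False):
    """Execute the ensemble; returns the OutcomeTable (one row per run).

    Deterministic given (design, world): run i uses seed seed_base + i for
    both its parameter draws and its simulation.
    """
    design.validate()
    rows = []
    details = []
    for i in range(design.n_runs):
        if design.paired:
            seed = design.seed_base + i // 2
            arm = i % 2  # 0 = low stratum, 1 = high stratum
        else:
            seed = design.seed_base + i
            arm = None
        rng = np.random.default_rng([seed, 11])
        scenario_name = design.scenarios[int(rng.integers(len(design.scenarios)))]
        m = float(rng.uniform(*design.normal_multiplier_range))
        credit = float(rng.uniform(*design.credit_multiplier_range))
        if design.paired == "m":
            lo, hi = design.normal_multiplier_range
            mid = 0.5 * (lo + hi)
            u = float(rng.uniform())
            m = lo + u * (mid - lo) if arm == 0 else mid + u * (hi - mid)
        elif design.paired == "credit":
            lo, hi = design.credit_multiplier_range
            mid = 0.5 * (lo + hi)
            u = float(rng.uniform())
            credit = lo + u * (mid - lo) if arm == 0 else mid + u * (hi - mid)
        point = CalibrationPoint(
            credit_multiplier=credit,
            k_locations=int(rng.integers(design.k_locations_range[0],
                                         design.k_locations_range[1] + 1)),
            rho_scale=float(rng.uniform(*design.rho_scale_range)),
            info_share_prob=float(rng.uniform(*design.info_share_prob_range)),
            p_reconsider_mean=float(rng.uniform(*design.p_reconsider_mean_range)),
        )
        config = apply_calibration_point(world.config or WorldConfig(), point)
        scenario = default_scenario(scenario_name, normal_multiplier=m,
                                    noise_scale=config.flood_noise_scale)
        histories, flows, summary = run_simulation(
            world,
            scenario,
            start_year=design.start_year,
            end_year=design.end_year,
            seed=seed,
            n_agents=design.n_agents,
            config=config,
        )
        coastal = np.array([d.coastal for d in world.districts])
        net = summary.net_migration_by_district
        row = {
            "run": i,
            "pair": (i // 2) if design.paired else i,
            "seed": seed,
            "scenario": scenario_name,
            "scenario_rise": scenario.slr(design.end_year),
            "normal_multiplier": m,
            "credit_multiplier": point.credit_multiplier,
            "k_locations": point.k_locations,
            "rho_scale": point.rho_scale,
            "info_share_prob": point.info_share_prob,
            "p_reconsider_mean": point.p_reconsider_mean,
            "net_coastal_migration": float(net[coastal].sum()),
            "total_moves": summary.total_moves,
            "total_migrations": summary.total_migrations,
            "mean_final_wealth": summary.mean_final_wealth,
            "mean_final_net_worth": summary.mean_final_net_worth,
            "moored_share": summary.moored_share_overall,
            "moored_mean_wealth": summary.moored_mean_wealth,
            "moored_mean_crra": summary.moored_mean_crra,
            "moored_mean_prior_moves": summary.moored_mean_prior_moves,
            "final_population": summary.final_population,
        }
        rows.append(row)
        if collect_details:
            details.append((histories, flows, summary))
    table = pd.DataFrame(rows)
    if collect_details:
        return table, details
    return table


def net_migration_by_district(flows: FlowMatrix, total_population: int) -> np.ndarray:
    """(in-flow - out-flow) per district, normalized by total population."""
    if total_population <= 0:
        raise ValueError("total population must be positive")
    inflow = flows.counts.sum(axis=0).astype(float)
    outflow = flows.counts.sum(axis=1).astype(float)
    return (inflow - outflow) / total_population


def top_flows(flows: FlowMatrix, fraction: float) -> list[tuple[int, int, int]]:
    """The ceil(fraction * D * (D-1)) largest off-diagonal flows, descending.

    Ties break by (origin, destination) id order. Zero flows are returned
    too; the caller filters if it wants strictly positive corridors.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    D = flows.counts.shape[0]
    n = math.ceil(fraction * D * (D - 1))
    cells = [
        (int(flows.counts[o, d]), o, d)
        for o in range(D)
        for d in range(D)
        if o != d
    ]
    cells.sort(key=lambda c: (-c[0], c[1], c[2]))
    return [(o, d, c) for c, o, d in cells[:n]]


def moored_analysis(
    histories: LifeHistories,
    world: World | None = None,
    agents=None,
) -> dict:
    """Final moored shares and moored-cohort covariates.

    Moored share is the fraction of adult agents whose final moored flag is
    true, per district and overall. Cohort covariates (mean wealth, CRRA,
    and moves made strictly before the first moored event) are computed over
    the moored agents when the engine's agent list is supplied; otherwise
    wealth comes from the histories and the rest are NaN-flagged.
    """
    q = np.array(histories.quarter)
    if len(q) == 0:
        return {
            "share_overall": 0.0,
            "share_by_district": np.zeros(world.n_districts if world else 0),
            "mean_wealth": float("nan"),
            "mean_crra": float("nan"),
            "mean_prior_moves": float("nan"),
            "n_moored": 0,
        }
    last_q = q.max()
    final = q == last_q
    adult = np.array(histories.adult)[final]
    moored = np.array(histories.moored)[final]
    district = np.array(histories.district)[final]
    wealth = np.array(histories.wealth)[final]
    agent_ids = np.array(histories.agent)[final]
    D = world.n_districts if world else int(district.max()) + 1
    share_by_d = np.zeros(D)
    for d in range(D):
        sel = adult & (district == d)
        share_by_d[d] = moored[sel].mean() if sel.any() else 0.0
    n_adults = int(adult.sum())
    n_moored = int((moored & adult).sum())
    share = n_moored / n_adults if n_adults else 0.0
    out = {
        "share_overall": share,
        "share_by_district": share_by_d,
        "n_moored": n_moored,
        "mean_wealth": float(wealth[moored & adult].mean()) if n_moored else float("nan"),
        "mean_crra": float("nan"),
        "mean_prior_moves": float("nan"),
    }
    if agents is not None and n_moored:
        moored_ids = set(agent_ids[moored & adult].tolist())
        cohort = [a for a in agents if a.id in moored_ids]
        out["mean_crra"] = float(np.mean([a.rho for a in cohort]))
        ever = [a for a in agents if a.ever_moored]
        if ever:
            out["mean_prior_moves"] = float(
                np.mean([a.moves_before_moored for a in ever])
            )
    return out


def coastal_interior_correlation(
    net_mig: np.ndarray, moored_share: np.ndarray, coastal_flags: np.ndarray
) -> dict:
    """Spearman rank correlation of net in-migration with moored share,
    separately for coastal and interior districts."""
    coastal_flags = np.asarray(coastal_flags, dtype=bool)
    out = {}
    for label, mask in (("coastal", coastal_flags), ("interior", ~coastal_flags)):
        n = int(mask.sum())
        if n < 3:
            out[label] = {"rho": float("nan"), "n": n, "ok": False}
            continue
        rho, p = spearmanr(net_mig[mask], moored_share[mask])
        out[label] = {"rho": float(rho), "p": float(p), "n": n, "ok": True}
    return out


def parameter_importance(
    outcomes: pd.DataFrame,
    target: str,
    parameter_columns: list[str] | None = None,
    seed: int = 0,
    n_repeats: int = 20,
) -> list[tuple[str, float]]:
    """Permutation importance of the drawn parameters for one outcome.

    Fits a random-forest regressor of the target on the parameter columns
    and scores each parameter by the mean decrease in held-out R^2 over
    ``n_repeats`` permutations. Returns (parameter, importance) pairs,
    descending.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.inspection import permutation_importance
    from sklearn.model_selection import train_test_split

    if len(outcomes) < 30:
        raise ValueError("need at least 30 ensemble rows for importance")
    if target not in outcomes.columns:
        raise ValueError(f"target column {target!r} missing")
    cols = parameter_columns or [
        c for c in PARAMETER_COLUMNS if c in outcomes.columns
    ]
    X = outcomes[cols].to_numpy(dtype=float)
    y = outcomes[target].to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.33, random_state=seed
    )
    model = RandomForestRegressor(n_estimators=300, random_state=seed)
    model.fit(X_tr, y_tr)
    result = permutation_importance(
        model, X_te, y_te, n_repeats=n_repeats, random_state=seed
    )
    pairs = sorted(
        zip(cols, result.importances_mean.tolist()), key=lambda kv: -kv[1]
    )
    return pairs
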