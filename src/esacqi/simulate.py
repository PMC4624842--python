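"""Synthetic physician cohort with known ground-truth attitude effects.

The generator emulates a three-year regional primary-care cohort:
~1400 physicians with log-normal patient panels (median 1329), one-off
0-10 VAS questionnaire responses whose per-item distributions are Beta
laws discretized to the 0.5-step VAS grid, and monthly J01 prescription
volumes in DDDs with a winter excess and physician-level overdispersion
(negative-binomial monthly totals).

The attitude -> prescribing link acts on a latent quality propensity

    q_i = sum_k effect_k * (score_ik - mean_k) + u_i,   u_i ~ N(0, sigma_u^2),

never on the AQPA label directly: higher q_i lowers a physician's total
volume and shifts the class mix from broad- toward narrow-spectrum
agents, so the binary outcome emerges from the full indicator pipeline.
Monthly totals have equal base means across months (month length is not
modelled), so a winter multiplier w implies an expected seasonal
variation of exactly (w - 1) x 100 percent.

Everything is reproducible: one integer seed drives a single PCG64
generator and identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import beta as beta_dist

__all__ = [
    "CohortConfig",
    "SimulatedCohort",
    "generate_cohort",
    "tune_to_study",
    "fit_beta_to_quartiles",
    "simulate_model_data",
    "ITEM_QUARTILE_TARGETS",
    "DEFAULT_ITEM_EFFECTS",
]

#: Target VAS quartiles (q25, q50, q75) of the 11 analysis items.
ITEM_QUARTILE_TARGETS: dict[int, tuple[float, float, float]] = {
    1: (7.5, 9.5, 9.5),
    2: (1.5, 3.0, 5.5),
    3: (1.0, 1.5, 4.0),
    4: (2.5, 5.0, 6.5),
    5: (2.5, 5.0, 7.5),
    6: (4.5, 6.5, 8.5),
    7: (1.0, 3.0, 5.5),
    8: (1.5, 3.5, 5.5),
    9: (0.5, 1.0, 2.5),
    10: (2.5, 5.5, 8.0),
    11: (5.0, 7.5, 9.5),
}

#: True log-odds-per-VAS-unit contributions to the latent quality scale.
#: Signs follow the observed associations (agreement with fear/complacency
#: items lowers quality; knowledge items 2, 6, 11 raise it); magnitudes
#: are generator conventions.  Items 12-16 are the unreliable items that
#: the ICC screen drops; they carry no effect.
DEFAULT_ITEM_EFFECTS: dict[int, float] = {
    1: -0.01, 2: 0.05, 3: -0.10, 4: -0.08, 5: -0.20, 6: 0.10,
    7: -0.15, 8: -0.12, 9: -0.08, 10: -0.02, 11: 0.15,
    12: 0.0, 13: 0.0, 14: 0.0, 15: 0.0, 16: 0.0,
}

#: Retest noise SD on the latent VAS scale: reliable items reproduce
#: (ICC ~ 0.8-0.9), the five dropped items do not (ICC well under 0.5).
DEFAULT_RETEST_NOISE: dict[int, float] = {
    **{k: 1.0 for k in range(1, 12)},
    **{k: 4.5 for k in range(12, 17)},
}

# Prescribing class mix: (class, codes, baseline share of J01 DDDs,
# quality direction: +1 broad-spectrum-like (share falls as quality
# rises), -1 narrow-spectrum-like (share rises), 0 neutral).
# Shares approximate a Spanish primary-care profile: penicillin/
# beta-lactamase-inhibitor combinations dominate, narrow-spectrum
# penicillins are nearly extinct.
_CLASS_MIX: tuple[tuple[str, tuple[str, ...], float, int], ...] = (
    ("J01CR", ("J01CR02", "J01CR05"), 0.419, +1),
    ("J01CE", ("J01CE02", "J01CE10"), 0.005, -1),
    ("J01CA", ("J01CA01", "J01CA04", "J01CF02"), 0.125, 0),
    ("J01DB", ("J01DB01", "J01DB05"), 0.002, -1),
    ("J01DC", ("J01DC02", "J01DC04"), 0.076, +1),
    ("J01DD", ("J01DD04", "J01DD08", "J01DD14"), 0.042, +1),
    ("J01DE", ("J01DE01",), 0.002, +1),
    ("J01FA01", ("J01FA01",), 0.003, -1),
    ("J01F_other", ("J01FA02", "J01FA06", "J01FA09", "J01FA10", "J01FA15", "J01FF01"), 0.105, +1),
    ("J01MA", ("J01MA01", "J01MA02", "J01MA06", "J01MA12", "J01MA14"), 0.129, +1),
    ("J01M_other", ("J01MB04",), 0.008, 0),
    ("J01_other", ("J01AA02", "J01AA08", "J01EA01", "J01EE01", "J01GB03", "J01XE01", "J01XX01"), 0.084, 0),
)

_WINTER_MONTHS = frozenset({1, 2, 3, 10, 11, 12})


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic study, with study-like defaults."""

    n_physicians: int = 1428
    years: tuple[int, ...] = (2008, 2009, 2010)
    seed: int = 20080101
    panel_median: float = 1329.0
    panel_log_sd: float = 0.35
    baseline_did: float = 15.65  # cohort mean J01 DID target
    winter_multiplier: float = 1.25
    # NB size parameter of the monthly physician-level J01 total; 25 gives
    # a monthly coefficient of variation near 0.2, a realistic level of
    # physician-month overdispersion
    nb_dispersion: float = 25.0
    sigma_u: float = 1.0  # physician heterogeneity on the latent quality scale
    volume_gradient: float = -0.12  # log volume per SD of latent quality
    mix_gradient: float = 0.25  # broad->narrow share shift per SD of quality
    effect_sizes: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_EFFECTS)
    )
    vas_item_params: Optional[Mapping[int, tuple[float, float]]] = None
    retest_noise_sd: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RETEST_NOISE)
    )
    class_shares: Optional[Mapping[str, float]] = None  # override baseline shares

    def __post_init__(self) -> None:
        if self.n_physicians < 2:
            raise ValueError("need at least 2 physicians")
        if self.baseline_did <= 0:
            raise ValueError("baseline_did must be > 0")
        if self.winter_multiplier < 1:
            raise ValueError("winter_multiplier must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        shares = self.resolved_shares()
        if abs(sum(shares.values()) - 1.0) > 1e-6:
            raise ValueError(
                f"class shares must sum to 1, got {sum(shares.values()):.6f}"
            )
        if any(s < 0 for s in shares.values()):
            raise ValueError("class shares must be non-negative")

    def resolved_shares(self) -> dict[str, float]:
        base = {name: share for name, _, share, _ in _CLASS_MIX}
        if self.class_shares is not None:
            unknown = set(self.class_shares) - set(base)
            if unknown:
                raise ValueError(f"unknown prescribing classes: {sorted(unknown)}")
            base.update(self.class_shares)
        return base

    def resolved_vas_params(self) -> dict[int, tuple[float, float]]:
        if self.vas_item_params is not None:
            return dict(self.vas_item_params)
        params = dict(_default_vas_params())
        for item in self.effect_sizes:
            params.setdefault(item, (2.0, 2.0))
        return params


@dataclass
class SimulatedCohort:
    """Generated tables plus the ground truth that produced them."""

    attitudes: pd.DataFrame  # physician_id, item_id, score, retest_score, on_call, night_shifts
    panels: pd.DataFrame  # physician_id, year, persons
    prescriptions: pd.DataFrame  # physician_id, year, month, atc, ddd_total
    ground_truth: dict


@lru_cache(maxsize=1)
def _default_vas_params() -> tuple[tuple[int, tuple[float, float]], ...]:
    return tuple(
        (item, fit_beta_to_quartiles(*targets))
        for item, targets in ITEM_QUARTILE_TARGETS.items()
    )


def _discretized_quantiles(
    a: float, b: float, probs: Sequence[float] = (0.25, 0.5, 0.75)
) -> np.ndarray:
    """Quantiles of a Beta(a,b)*10 score rounded to the 0.5 grid."""
    grid = np.arange(0.0, 10.01, 0.5)
    upper = np.clip((grid + 0.25) / 10.0, 0.0, 1.0)
    cdf = beta_dist.cdf(upper, a, b)
    out = [grid[np.searchsorted(cdf, p, side="left")] for p in probs]
    return np.asarray(out)


def fit_beta_to_quartiles(
    q25: float, q50: float, q75: float, tol: float = 0.5
) -> tuple[float, float]:
    """Beta shape parameters whose discretized VAS quartiles hit the targets.

    Raises with a diagnostic when the targets are degenerate
    (q25 == q75) or unattainable within *tol* on every quartile.
    """
    if not (0 <= q25 <= q50 <= q75 <= 10):
        raise ValueError(f"quartile targets must be ordered in [0,10]: {(q25, q50, q75)}")
    if q25 == q75:
        raise ValueError(
            f"degenerate quartile targets q25 == q75 == {q25}: "
            "no continuous score distribution can match them"
        )
    targets = np.array([q25, q50, q75])
    # squeeze targets off the boundary for the continuous objective
    t = np.clip(targets / 10.0, 0.02, 0.98)

    def objective(log_ab: np.ndarray) -> float:
        a, b = np.exp(np.clip(log_ab, -3, 5))
        q = beta_dist.ppf([0.25, 0.5, 0.75], a, b)
        return float(((q - t) ** 2).sum())

    best, best_val = None, np.inf
    for start in ((0.0, 0.0), (0.7, -0.7), (-0.7, 0.7), (-1.2, 0.5)):
        res = minimize(objective, np.asarray(start), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 600})
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    a, b = np.exp(np.clip(best, -3, 5))
    achieved = _discretized_quantiles(a, b)
    if np.max(np.abs(achieved - targets)) > tol:
        raise ValueError(
            f"cannot match quartile targets {tuple(targets)} within {tol} "
            f"VAS units; best discretized fit {tuple(achieved)} with "
            f"Beta({a:.3f}, {b:.3f})"
        )
    return float(a), float(b)


def _discretize_vas(values: np.ndarray) -> np.ndarray:
    return np.clip(np.round(values * 2.0) / 2.0, 0.0, 10.0)


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """Draw a full synthetic study from a config (seed overrides config.seed)."""
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_physicians
    years = tuple(config.years)
    physician_ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    # --- panels (constant across follow-up years) ------------------------
    persons = np.maximum(
        np.round(
            np.exp(rng.normal(np.log(config.panel_median), config.panel_log_sd, n))
        ).astype(int),
        100,
    )
    panels = pd.DataFrame(
        {
            "physician_id": np.repeat(physician_ids, len(years)),
            "year": np.tile(years, n),
            "persons": np.repeat(persons, len(years)),
        }
    )

    # --- questionnaire ----------------------------------------------------
    vas_params = config.resolved_vas_params()
    items = sorted(vas_params)
    scores = np.empty((n, len(items)))
    retests = np.empty((n, len(items)))
    for j, item in enumerate(items):
        a, b = vas_params[item]
        latent = 10.0 * rng.beta(a, b, n)
        scores[:, j] = _discretize_vas(latent)
        tau = config.retest_noise_sd.get(item, 1.0)
        retests[:, j] = _discretize_vas(latent + rng.normal(0.0, tau, n))
    on_call = rng.binomial(1, 0.5, n)
    night_shifts = rng.binomial(1, 0.35, n)
    attitudes = pd.DataFrame(
        {
            "physician_id": np.repeat(physician_ids, len(items)),
            "item_id": np.tile(items, n),
            "score": scores.ravel(),
            "retest_score": retests.ravel(),
            "on_call": np.repeat(on_call, len(items)),
            "night_shifts": np.repeat(night_shifts, len(items)),
        }
    )

    # --- latent quality propensity ---------------------------------------
    effects = np.array([config.effect_sizes.get(item, 0.0) for item in items])
    u = rng.normal(0.0, config.sigma_u, n) if config.sigma_u > 0 else np.zeros(n)
    q = (scores - scores.mean(axis=0)) @ effects + u
    q_sd = q.std()
    qz = (q - q.mean()) / q_sd if q_sd > 0 else np.zeros(n)

    # --- monthly prescription volumes -------------------------------------
    shares = config.resolved_shares()
    class_names = [name for name, _, _, _ in _CLASS_MIX]
    class_codes = {name: codes for name, codes, _, _ in _CLASS_MIX}
    badness = np.array([bad for _, _, _, bad in _CLASS_MIX], dtype=float)
    base_share = np.array([shares[name] for name in class_names])

    # physician class mix: broad shares shrink, narrow grow, with quality
    tilt = np.exp(-config.mix_gradient * qz[:, None] * badness[None, :])
    mix = base_share[None, :] * tilt
    mix /= mix.sum(axis=1, keepdims=True)  # (n, n_classes)

    # physician volume factor, normalized to cohort mean 1 so that the
    # realized cohort mean DID tracks baseline_did
    vol = np.exp(config.volume_gradient * qz)
    vol /= vol.mean()

    from .indicators import days_in_year

    w = config.winter_multiplier
    month_factor = np.array([w if m in _WINTER_MONTHS else 1.0 for m in range(1, 13)])
    month_factor /= month_factor.sum()  # annual total is split across months

    # flatten the class mix to per-code allocation probabilities (uniform
    # within class): (n, n_codes)
    all_codes: list[str] = []
    code_probs_cols: list[np.ndarray] = []
    for ci, cname in enumerate(class_names):
        codes = class_codes[cname]
        for code in codes:
            all_codes.append(code)
            code_probs_cols.append(mix[:, ci] / len(codes))
    code_probs = np.column_stack(code_probs_cols)  # (n, K)
    code_labels = np.asarray(all_codes, dtype=object)

    frames = []
    theta = config.nb_dispersion
    for year in years:
        annual = (
            config.baseline_did / 1000.0 * persons * days_in_year(year) * vol
        )  # (n,)
        # monthly physician-level J01 totals: NB around the monthly mean
        mu = annual[:, None] * month_factor[None, :]  # (n, 12)
        totals = rng.negative_binomial(theta, theta / (theta + mu))
        # split each monthly total across substances by the physician mix
        counts = rng.multinomial(totals, code_probs[:, None, :])  # (n, 12, K)
        doc_idx, month_idx, code_idx = np.nonzero(counts)
        frames.append(
            pd.DataFrame(
                {
                    "physician_id": physician_ids[doc_idx],
                    "year": year,
                    "month": month_idx + 1,
                    "atc": code_labels[code_idx],
                    "ddd_total": counts[doc_idx, month_idx, code_idx].astype(float),
                }
            )
        )
    prescriptions = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["physician_id", "year", "month", "atc"])
        .reset_index(drop=True)
    )

    ground_truth = {
        "seed": int(config.seed if seed is None else seed),
        "n_physicians": n,
        "years": list(years),
        "sigma_u": config.sigma_u,
        "effect_sizes": {int(k): float(v) for k, v in config.effect_sizes.items()},
        "volume_gradient": config.volume_gradient,
        "mix_gradient": config.mix_gradient,
        "winter_multiplier": config.winter_multiplier,
        "baseline_did": config.baseline_did,
        "latent_quality": dict(zip(physician_ids.tolist(), q.tolist())),
    }
    return SimulatedCohort(attitudes, panels, prescriptions, ground_truth)


def tune_to_study(
    config: CohortConfig,
    item_targets: Mapping[int, tuple[float, float, float]] | None = None,
    target_mean_did: float | None = None,
) -> CohortConfig:
    """Adjust VAS shapes and baseline volume toward study targets.

    Fits each item's Beta parameters to the requested quartiles (default:
    the published 11-item quartile table) and sets ``baseline_did`` to the
    target cohort mean.  Unattainable quartile targets raise with a
    diagnostic naming the item.
    """
    targets = dict(item_targets if item_targets is not None else ITEM_QUARTILE_TARGETS)
    params = dict(config.resolved_vas_params())
    for item, tq in targets.items():
        try:
            params[item] = fit_beta_to_quartiles(*tq)
        except ValueError as exc:
            raise ValueError(f"item {item}: {exc}") from exc
    updates: dict = {"vas_item_params": params}
    if target_mean_did is not None:
        if target_mean_did <= 0:
            raise ValueError("target mean DID must be > 0")
        updates["baseline_did"] = float(target_mean_did)
    return replace(config, **updates)


def simulate_model_data(
    n_physicians: int,
    n_years: int = 3,
    beta0: float = 1.25,
    beta_exposure: float = -0.25,
    sigma_u: float = 1.0,
    seed: int = 0,
    covariate_effects: Mapping[str, float] | None = None,
    score_shape: tuple[float, float] = (2.0, 2.0),
) -> pd.DataFrame:
    """Draw physician-year outcome data directly from the logistic model.

    A fast generator for parameter-recovery and calibration studies: the
    exposure is a discretized Beta VAS score constant within physician,
    and the outcome is Bernoulli with
    logit p = beta0 + beta_exposure * score (+ covariates) + u_i.
    """
    rng = np.random.default_rng(seed)
    ids = np.array([f"P{i:05d}" for i in range(1, n_physicians + 1)])
    score = _discretize_vas(10.0 * rng.beta(*score_shape, n_physicians))
    on_call = rng.binomial(1, 0.5, n_physicians)
    night = rng.binomial(1, 0.35, n_physicians)
    panel_k = np.exp(rng.normal(np.log(1.329), 0.35, n_physicians))
    u = rng.normal(0.0, sigma_u, n_physicians) if sigma_u > 0 else np.zeros(n_physicians)
    eta_doc = beta0 + beta_exposure * score + u
    cov_eff = dict(covariate_effects or {})
    eta_doc = (
        eta_doc
        + cov_eff.get("on_call", 0.0) * on_call
        + cov_eff.get("night_shifts", 0.0) * night
        + cov_eff.get("mean_panel_k", 0.0) * panel_k
    )
    rows = {
        "physician_id": np.repeat(ids, n_years),
        "year": np.tile(np.arange(n_years), n_physicians),
        "score": np.repeat(score, n_years),
        "on_call": np.repeat(on_call, n_years).astype(float),
        "night_shifts": np.repeat(night, n_years).astype(float),
        "mean_panel_k": np.repeat(panel_k, n_years),
    }
    p = expit(np.repeat(eta_doc, n_years))
    rows["aqpa"] = rng.binomial(1, p)
    return pd.DataFrame(rows)
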