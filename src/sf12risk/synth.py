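"""Seeded synthetic-cohort generator with a two-latent-factor structure.

The generator draws a correlated (mental, physical) latent factor pair per
patient, maps the factors to 8 latent domain scores through configurable
loadings plus noise, discretizes the latent domain scores into SF-12v2 item
codes, and draws clinical covariates through logistic links on the latent
factors (so that heart failure and high NYHA class are more likely at low
physical/mental health).  Depression-risk labels are whatever the scoring
pipeline produces on the generated items — the generator never writes
labels directly.

``calibrate_prevalence`` shifts the mental-factor location by bisection
until the large-n simulated prevalence of MCS<42 matches a target.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss

from sf12risk import scoring
from sf12risk.scoring import DOMAINS, ITEM_SPECS, ScoringCoefficients

__all__ = [
    "DomainModel",
    "CovariateLink",
    "SyntheticConfig",
    "ConfigError",
    "CalibrationError",
    "generate_cohort",
    "calibrate_prevalence",
    "marginal_report",
    "default_config",
]


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


class CalibrationError(RuntimeError):
    """Prevalence calibration failed to converge / bracket the target."""


@dataclass
class DomainModel:
    """Linear map from the latent factors to one latent domain score.

    latent_domain = base + load_mental·m + load_physical·p + N(0, noise_sd²),
    clipped to [0, 100].
    """

    base: float
    load_mental: float
    load_physical: float
    noise_sd: float


@dataclass
class CovariateLink:
    """Bernoulli covariate with a logistic link on the latent factors.

    P(X=1 | m, p) = sigmoid(intercept + coef_mental·m + coef_physical·p).
    The intercept is solved (Gauss–Hermite quadrature + bisection) so the
    population marginal equals ``rate`` under the configured latent
    distribution.
    """

    rate: float
    coef_mental: float = 0.0
    coef_physical: float = 0.0


# Emulation targets for the cohort's marginal structure (published cohort
# summary statistics used as configuration defaults, not ground truth).
_DEFAULT_DOMAINS: dict[str, DomainModel] = {
    "PF": DomainModel(base=50.0, load_mental=4.0, load_physical=24.0, noise_sd=13.0),
    "RP": DomainModel(base=49.0, load_mental=4.0, load_physical=17.0, noise_sd=11.0),
    "BP": DomainModel(base=60.0, load_mental=4.0, load_physical=20.0, noise_sd=13.0),
    "GH": DomainModel(base=48.0, load_mental=5.0, load_physical=15.0, noise_sd=10.0),
    "VT": DomainModel(base=49.0, load_mental=26.0, load_physical=5.0, noise_sd=4.0),
    "SF": DomainModel(base=64.0, load_mental=19.0, load_physical=5.0, noise_sd=13.0),
    "RE": DomainModel(base=65.0, load_mental=13.0, load_physical=4.0, noise_sd=15.0),
    "MH": DomainModel(base=65.0, load_mental=15.0, load_physical=3.0, noise_sd=9.0),
}

_DEFAULT_COVARIATES: dict[str, CovariateLink] = {
    "heart_failure": CovariateLink(rate=0.272, coef_mental=-0.3, coef_physical=-0.9),
    "nyha_high": CovariateLink(rate=0.719, coef_mental=-0.4, coef_physical=-1.0),
    "ccs_high": CovariateLink(rate=0.797, coef_mental=-0.2, coef_physical=-0.6),
    "male": CovariateLink(rate=0.654),
}


@dataclass
class SyntheticConfig:
    """Full configuration of the synthetic cohort generator."""

    n: int = 217
    target_prevalence: float = 0.2903
    seed: int = 0
    mental_loc: float = 0.0
    physical_loc: float = 0.0
    factor_corr: float = 0.4
    domains: dict[str, DomainModel] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_DOMAINS)
    )
    covariates: dict[str, CovariateLink] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_COVARIATES)
    )
    item_noise_sd: float = 6.0
    age_mean: float = 65.14
    age_sd: float = 9.47
    euroscore_mean: float = 1.86
    euroscore_sd: float = 1.31
    surgery_probs: tuple[float, float, float] = (0.567, 0.203, 0.230)
    coefficients: ScoringCoefficients | None = None
    calibration: dict | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n < 2:
            raise ConfigError(f"n must be ≥ 2, got {self.n}")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ConfigError(
                f"target_prevalence must be in (0, 1), got {self.target_prevalence}"
            )
        if not (-1.0 < self.factor_corr < 1.0):
            raise ConfigError(f"factor_corr must be in (-1, 1), got {self.factor_corr}")
        if set(self.domains) != set(DOMAINS):
            raise ConfigError(f"domains must cover exactly {DOMAINS}")
        for name, dm in self.domains.items():
            if not all(
                np.isfinite([dm.base, dm.load_mental, dm.load_physical, dm.noise_sd])
            ):
                raise ConfigError(f"domain {name}: non-finite parameters")
            if dm.noise_sd < 0:
                raise ConfigError(f"domain {name}: negative noise_sd")
        for name, cov in self.covariates.items():
            if not (0.0 < cov.rate < 1.0):
                raise ConfigError(f"covariate {name}: rate must be in (0, 1)")
        if self.item_noise_sd < 0:
            raise ConfigError("item_noise_sd must be ≥ 0")
        probs = np.asarray(self.surgery_probs, float)
        if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-6:
            raise ConfigError("surgery_probs must be 3 non-negative values summing to 1")

    def replace(self, **kwargs) -> "SyntheticConfig":
        cfg = copy.deepcopy(self)
        for key, value in kwargs.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config field {key!r}")
            setattr(cfg, key, value)
        cfg.validate()
        return cfg

    def scoring_coefficients(self) -> ScoringCoefficients:
        return self.coefficients or scoring.default_coefficients()


def default_config(**kwargs) -> SyntheticConfig:
    return SyntheticConfig(**kwargs)


# ---------------------------------------------------------------------------
# Item discretization
# ---------------------------------------------------------------------------


def _item_cuts(levels: int) -> np.ndarray:
    """Midpoint cut-points on [0, 100] so that latent = level midpoint maps back."""
    return (np.arange(1, levels) - 0.5) * 100.0 / (levels - 1)


def _discretize_item(latent: np.ndarray, spec) -> np.ndarray:
    """Map latent 0–100 values to raw item codes, honoring reverse coding."""
    cuts = _item_cuts(spec.levels)
    if np.any(np.diff(cuts) <= 0):  # degenerate thresholds guard
        raise ConfigError(f"non-monotone cut-points for item {spec.name}")
    recoded = np.searchsorted(cuts, latent) + 1  # 1..levels, higher = better
    return spec.levels + 1 - recoded if spec.reverse else recoded


# ---------------------------------------------------------------------------
# Covariate intercept calibration (population marginal -> logistic intercept)
# ---------------------------------------------------------------------------


def _logistic_intercept(link: CovariateLink, cfg: SyntheticConfig) -> float:
    """Solve sigmoid intercept so E[sigmoid(a + s)] = rate, s Gaussian.

    s = coef_mental·m + coef_physical·p is normal with moments implied by the
    configured latent locations and correlation; the expectation is computed
    with 64-point Gauss–Hermite quadrature and the intercept bisected.
    """
    bm, bp = link.coef_mental, link.coef_physical
    mu = bm * cfg.mental_loc + bp * cfg.physical_loc
    var = bm**2 + bp**2 + 2.0 * cfg.factor_corr * bm * bp
    if var <= 1e-12:
        return float(np.log(link.rate / (1.0 - link.rate)) - mu)
    sd = np.sqrt(var)
    nodes, weights = hermegauss(64)
    weights = weights / weights.sum()

    def expected(a: float) -> float:
        s = mu + sd * nodes
        return float(weights @ (1.0 / (1.0 + np.exp(-(a + s)))))

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) < link.rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_cohort(
    cfg: SyntheticConfig,
    seed: int | None = None,
    *,
    include_latent: bool = True,
    scored: bool = True,
) -> pd.DataFrame:
    """Generate one synthetic cohort.

    Returns a frame with the 12 ``sf12_q*`` item columns, clinical
    covariates, latent ground-truth factors (unless suppressed), and — when
    ``scored`` — the derived domain scores, PCS/MCS and ``depression_risk``
    label produced by running the scoring pipeline on the generated items.

    The draw is bit-for-bit reproducible from ``(cfg, seed)``; the root seed
    fans out into named child streams (latents, items, covariates).
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    s_latent, s_items, s_cov = root.spawn(3)
    rng_latent = np.random.default_rng(s_latent)
    rng_items = np.random.default_rng(s_items)
    rng_cov = np.random.default_rng(s_cov)
    n = cfg.n

    # Latent factors: correlated bivariate normal, unit variances.
    cov = np.array([[1.0, cfg.factor_corr], [cfg.factor_corr, 1.0]])
    factors = rng_latent.multivariate_normal(
        [cfg.mental_loc, cfg.physical_loc], cov, size=n, method="cholesky"
    )
    mental, physical = factors[:, 0], factors[:, 1]

    # Latent domain scores.
    domain_latent: dict[str, np.ndarray] = {}
    for d in DOMAINS:
        dm = cfg.domains[d]
        vals = (
            dm.base
            + dm.load_mental * mental
            + dm.load_physical * physical
            + rng_latent.normal(0.0, dm.noise_sd, size=n)
        )
        domain_latent[d] = np.clip(vals, 0.0, 100.0)

    # Item responses: per-item jitter on the domain latent, then threshold.
    data: dict[str, np.ndarray] = {}
    for name, spec in ITEM_SPECS.items():
        latent = domain_latent[spec.domain] + rng_items.normal(
            0.0, cfg.item_noise_sd, size=n
        )
        data[name] = _discretize_item(np.clip(latent, 0.0, 100.0), spec).astype(int)

    # Covariates (stable iteration order: insertion order of the dict).
    for cname, link in cfg.covariates.items():
        a0 = _logistic_intercept(link, cfg)
        eta = a0 + link.coef_mental * mental + link.coef_physical * physical
        p1 = 1.0 / (1.0 + np.exp(-eta))
        data[cname] = (rng_cov.uniform(size=n) < p1).astype(int)
    data["age"] = np.round(
        np.clip(rng_cov.normal(cfg.age_mean, cfg.age_sd, size=n), 25, 95), 1
    )
    # EUROscore: lognormal with moments matched to the configured mean/SD.
    sigma2 = np.log1p((cfg.euroscore_sd / cfg.euroscore_mean) ** 2)
    mu_ln = np.log(cfg.euroscore_mean) - 0.5 * sigma2
    data["euroscore"] = np.round(
        rng_cov.lognormal(mu_ln, np.sqrt(sigma2), size=n), 2
    )
    data["surgery_type"] = rng_cov.choice(3, size=n, p=np.asarray(cfg.surgery_probs))

    if include_latent:
        data["latent_mental"] = mental
        data["latent_physical"] = physical

    cohort = pd.DataFrame(data)
    if scored:
        cohort = scoring.score_cohort(cohort, cfg.scoring_coefficients())
    return cohort


# ---------------------------------------------------------------------------
# Prevalence calibration
# ---------------------------------------------------------------------------


def _simulated_prevalence(
    cfg: SyntheticConfig, n_sim: int, seed: int, n_rep: int = 3
) -> float:
    """Mean prevalence over ``n_rep`` fixed-seed simulations of size ``n_sim``.

    Averaging over a few independent streams keeps the Monte-Carlo error of
    the (deterministic, seed-frozen) bisection objective well below the
    calibration tolerance.
    """
    sim_cfg = cfg.replace(n=n_sim)
    prevs = [
        generate_cohort(sim_cfg, seed=seed + rep, include_latent=False, scored=True)[
            "depression_risk"
        ].mean()
        for rep in range(n_rep)
    ]
    return float(np.mean(prevs))


def calibrate_prevalence(
    cfg: SyntheticConfig,
    tol: float = 0.0012,
    *,
    n_sim: int = 100_000,
    n_rep: int = 4,
    max_iter: int = 60,
    bounds: tuple[float, float] = (-4.0, 4.0),
    sim_seed: int = 987_654_321,
) -> SyntheticConfig:
    """Bisect the mental-factor location until simulated prevalence hits target.

    Prevalence of MCS<42 is a decreasing function of ``mental_loc``; the same
    simulation seed is reused at every bisection step so the objective is a
    deterministic monotone function and bisection is well-posed.  Returns a
    copy of ``cfg`` with ``mental_loc`` updated and a ``calibration`` report
    attached.  Raises :class:`CalibrationError` when the target cannot be
    bracketed within ``bounds`` or ``tol`` is not reached in ``max_iter``
    iterations.
    """
    target = cfg.target_prevalence
    lo, hi = bounds  # prevalence(lo) high, prevalence(hi) low
    prev_lo = _simulated_prevalence(cfg.replace(mental_loc=lo), n_sim, sim_seed, n_rep)
    prev_hi = _simulated_prevalence(cfg.replace(mental_loc=hi), n_sim, sim_seed, n_rep)
    if not (prev_hi <= target <= prev_lo):
        raise CalibrationError(
            f"target {target} not bracketed: prevalence range "
            f"[{prev_hi:.4f}, {prev_lo:.4f}] over mental_loc bounds {bounds}"
        )
    history = []
    best = None
    for it in range(max_iter):
        mid = 0.5 * (lo + hi)
        prev = _simulated_prevalence(cfg.replace(mental_loc=mid), n_sim, sim_seed, n_rep)
        history.append({"iter": it, "mental_loc": mid, "prevalence": prev})
        if best is None or abs(prev - target) < abs(best[1] - target):
            best = (mid, prev)
        if abs(prev - target) <= tol:
            out = cfg.replace(mental_loc=mid)
            out.calibration = {
                "target": target,
                "achieved": prev,
                "tol": tol,
                "n_sim": n_sim,
                "iterations": it + 1,
                "history": history,
            }
            return out
        if prev > target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"calibration did not reach tol={tol} in {max_iter} iterations "
        f"(best |error| = {abs(best[1] - target):.5f} at mental_loc={best[0]:.4f})"
    )


# ---------------------------------------------------------------------------
# Marginal report
# ---------------------------------------------------------------------------


def marginal_report(
    cohort: pd.DataFrame, targets: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Empirical covariate rates, domain means/SDs and prevalence.

    Produces one row per quantity with an ``empirical`` column and, when a
    ``targets`` mapping is supplied, a ``target`` column for side-by-side
    comparison with published marginals.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows: list[dict] = []
    for d in DOMAINS:
        if d in cohort.columns:
            rows.append({"quantity": f"{d}_mean", "empirical": float(cohort[d].mean())})
            rows.append(
                {"quantity": f"{d}_sd", "empirical": float(cohort[d].std(ddof=0))}
            )
    for col in ("PCS", "MCS"):
        if col in cohort.columns:
            rows.append({"quantity": f"{col}_mean", "empirical": float(cohort[col].mean())})
    for cname in ("heart_failure", "nyha_high", "ccs_high", "male"):
        if cname in cohort.columns:
            rows.append(
                {"quantity": f"{cname}_rate", "empirical": float(cohort[cname].mean())}
            )
    if "depression_risk" in cohort.columns:
        rows.append(
            {
                "quantity": "prevalence",
                "empirical": float(cohort["depression_risk"].mean()),
            }
        )
    report = pd.DataFrame(rows)
    if targets:
        report["target"] = report["quantity"].map(dict(targets))
    return report


def config_to_dict(cfg: SyntheticConfig) -> dict:
    """JSON/YAML-serializable view of a config (coefficients flattened)."""
    out = {
        "n": cfg.n,
        "target_prevalence": cfg.target_prevalence,
        "seed": cfg.seed,
        "mental_loc": cfg.mental_loc,
        "physical_loc": cfg.physical_loc,
        "factor_corr": cfg.factor_corr,
        "item_noise_sd": cfg.item_noise_sd,
        "age_mean": cfg.age_mean,
        "age_sd": cfg.age_sd,
        "euroscore_mean": cfg.euroscore_mean,
        "euroscore_sd": cfg.euroscore_sd,
        "surgery_probs": list(cfg.surgery_probs),
        "domains": {
            d: {
                "base": m.base,
                "load_mental": m.load_mental,
                "load_physical": m.load_physical,
                "noise_sd": m.noise_sd,
            }
            for d, m in cfg.domains.items()
        },
        "covariates": {
            c: {
                "rate": l.rate,
                "coef_mental": l.coef_mental,
                "coef_physical": l.coef_physical,
            }
            for c, l in cfg.covariates.items()
        },
    }
    if cfg.calibration:
        cal = dict(cfg.calibration)
        cal.pop("history", None)
        out["calibration"] = cal
    return out


def config_from_dict(payload: Mapping) -> SyntheticConfig:
    payload = dict(payload)
    domains = payload.pop("domains", None)
    covariates = payload.pop("covariates", None)
    calibration = payload.pop("calibration", None)
    if "surgery_probs" in payload:
        payload["surgery_probs"] = tuple(payload["surgery_probs"])
    kwargs = dict(payload)
    if domains is not None:
        kwargs["domains"] = {d: DomainModel(**m) for d, m in domains.items()}
    if covariates is not None:
        kwargs["covariates"] = {c: CovariateLink(**l) for c, l in covariates.items()}
    cfg = SyntheticConfig(**kwargs)
    cfg.calibration = calibration
    return cfg
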