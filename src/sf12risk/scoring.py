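"""SF-12v2 scoring: item validation, domain scores, PCS/MCS, risk label.

The scoring engine is deliberately generic: the item metadata (response
levels, reverse-coding, domain membership) is fixed by the SF-12v2 form,
while the norm-based component scoring constants (per-domain normalization
means/SDs and PCS/MCS factor-score weights) are configuration supplied via
a :class:`ScoringCoefficients` table.  A documented default coefficient set
is shipped, but any 8-row table with the same schema can be plugged in.

Scoring steps
-------------
1. ``validate_responses`` — range-check the 12 raw item codes (optionally
   allowing half-scale imputation of missing items).
2. ``score_domains`` — recode each item so that higher = better health,
   rescale to 0–100, and average items within each of the 8 domains.
3. ``score_components`` — z-standardize domains against the coefficient
   table, take the PCS/MCS weighted sums, and apply the T-transform
   (mean 50, SD 10).
4. ``flag_depression_risk`` — label 1 iff MCS < 42 (strict).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DOMAINS",
    "ITEM_SPECS",
    "MCS_RISK_THRESHOLD",
    "ScoringCoefficients",
    "SF12Responses",
    "ValidationError",
    "CoefficientError",
    "validate_responses",
    "score_domains",
    "score_components",
    "flag_depression_risk",
    "score_cohort",
    "summarize_cohort",
    "default_coefficients",
]

#: Domain order used throughout the package.
DOMAINS = ("PF", "RP", "BP", "GH", "VT", "SF", "RE", "MH")

#: MCS threshold below which a respondent is labelled at risk of depression.
MCS_RISK_THRESHOLD = 42.0


@dataclass(frozen=True)
class ItemSpec:
    """Metadata for one SF-12v2 item.

    ``reverse`` is True when a *lower* raw code means better health, so the
    code must be flipped before rescaling to the 0–100 "higher is better"
    metric.
    """

    name: str
    domain: str
    levels: int
    reverse: bool


# SF-12v2 form layout: item -> (domain, number of response levels, reverse flag).
# q2/q3 use a 3-level scale; all other items use 5-level scales.
ITEM_SPECS: dict[str, ItemSpec] = {
    "sf12_q1": ItemSpec("sf12_q1", "GH", 5, True),   # general health rating
    "sf12_q2": ItemSpec("sf12_q2", "PF", 3, False),  # moderate activities
    "sf12_q3": ItemSpec("sf12_q3", "PF", 3, False),  # climbing stairs
    "sf12_q4": ItemSpec("sf12_q4", "RP", 5, False),  # accomplished less (physical)
    "sf12_q5": ItemSpec("sf12_q5", "RP", 5, False),  # limited in kind of work
    "sf12_q6": ItemSpec("sf12_q6", "RE", 5, False),  # accomplished less (emotional)
    "sf12_q7": ItemSpec("sf12_q7", "RE", 5, False),  # worked less carefully
    "sf12_q8": ItemSpec("sf12_q8", "BP", 5, True),   # pain interference
    "sf12_q9": ItemSpec("sf12_q9", "MH", 5, True),   # calm and peaceful
    "sf12_q10": ItemSpec("sf12_q10", "VT", 5, True), # energy
    "sf12_q11": ItemSpec("sf12_q11", "MH", 5, False),# downhearted and depressed
    "sf12_q12": ItemSpec("sf12_q12", "SF", 5, False),# social interference
}

ITEM_NAMES = tuple(ITEM_SPECS)

#: Domain -> ordered item names.
DOMAIN_ITEMS: dict[str, tuple[str, ...]] = {
    d: tuple(n for n, s in ITEM_SPECS.items() if s.domain == d) for d in DOMAINS
}


class ValidationError(ValueError):
    """Raised when raw item responses violate the form's response ranges."""


class CoefficientError(ValueError):
    """Raised when a scoring-coefficient table violates its schema."""


# ---------------------------------------------------------------------------
# Scoring coefficients
# ---------------------------------------------------------------------------

# Default norm-based scoring constants.  These approximate general-population
# domain norms and component factor weights on the SF-12 metric; they are
# shipped as editable configuration, not as a certified norm set.
_DEFAULT_COEFFICIENTS_CSV = """\
domain,norm_mean,norm_sd,pcs_weight,mcs_weight
PF,81.18,29.10,0.42,-0.23
RP,80.52,27.12,0.35,-0.12
BP,81.74,24.53,0.32,-0.10
GH,72.19,23.18,0.25,-0.02
VT,55.59,24.84,0.03,0.24
SF,83.73,22.37,-0.01,0.27
RE,86.41,22.34,-0.19,0.43
MH,70.18,20.50,-0.22,0.49
"""


@dataclass(frozen=True)
class ScoringCoefficients:
    """Norm-based component scoring constants.

    Attributes
    ----------
    norm_means, norm_sds :
        Per-domain normalization constants (domain order :data:`DOMAINS`).
    pcs_weights, mcs_weights :
        Factor-score weights applied to the domain z-scores.
    t_center, t_scale :
        T-transform constants (population mean / SD of the component scores).
    """

    norm_means: np.ndarray
    norm_sds: np.ndarray
    pcs_weights: np.ndarray
    mcs_weights: np.ndarray
    t_center: float = 50.0
    t_scale: float = 10.0

    def __post_init__(self) -> None:
        for name in ("norm_means", "norm_sds", "pcs_weights", "mcs_weights"):
            vec = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, vec)
            if vec.shape != (len(DOMAINS),):
                raise CoefficientError(
                    f"{name} must have {len(DOMAINS)} entries, got shape {vec.shape}"
                )
        if np.any(self.norm_sds <= 0):
            raise CoefficientError("norm_sds must be strictly positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "ScoringCoefficients":
        required = {"domain", "norm_mean", "norm_sd", "pcs_weight", "mcs_weight"}
        missing = required - set(df.columns)
        if missing:
            raise CoefficientError(f"coefficient table missing columns: {sorted(missing)}")
        if sorted(df["domain"]) != sorted(DOMAINS):
            raise CoefficientError(
                f"coefficient table must have exactly one row per domain {DOMAINS}"
            )
        df = df.set_index("domain").loc[list(DOMAINS)]
        return cls(
            norm_means=df["norm_mean"].to_numpy(float),
            norm_sds=df["norm_sd"].to_numpy(float),
            pcs_weights=df["pcs_weight"].to_numpy(float),
            mcs_weights=df["mcs_weight"].to_numpy(float),
            **kwargs,
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ScoringCoefficients":
        return cls.from_frame(pd.read_csv(path), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "domain": list(DOMAINS),
                "norm_mean": self.norm_means,
                "norm_sd": self.norm_sds,
                "pcs_weight": self.pcs_weights,
                "mcs_weight": self.mcs_weights,
            }
        )


def default_coefficients() -> ScoringCoefficients:
    """The shipped default coefficient table (see module docstring)."""
    return ScoringCoefficients.from_frame(pd.read_csv(io.StringIO(_DEFAULT_COEFFICIENTS_CSV)))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class SF12Responses:
    """Validated item responses for one respondent.

    ``values`` maps item name to the raw integer code, or NaN for a missing
    item accepted under the half-scale imputation policy.  ``reverse_coded``
    lists the items whose raw codes are flipped during rescaling.
    """

    values: dict[str, float]
    reverse_coded: tuple[str, ...] = field(
        default_factory=lambda: tuple(n for n, s in ITEM_SPECS.items() if s.reverse)
    )
    imputation: str = "reject"


def validate_responses(
    raw: Mapping[str, object], *, missing_policy: str = "reject"
) -> SF12Responses:
    """Validate a record of 12 raw item codes.

    Parameters
    ----------
    raw :
        Mapping with keys ``sf12_q1`` .. ``sf12_q12``.
    missing_policy :
        ``"reject"`` (default) — any missing item raises; ``"half_scale"`` —
        missing items are tolerated when at least half of each affected
        domain's items are answered, and are later imputed with the
        respondent's mean of the answered items in that domain.
    """
    if missing_policy not in ("reject", "half_scale"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    missing_items = [n for n in ITEM_NAMES if n not in raw or _is_missing(raw.get(n))]
    extra = set(raw) - set(ITEM_NAMES)
    # Extra keys are tolerated (clinical passthrough columns); absent items are not.
    if missing_items and missing_policy == "reject":
        raise ValidationError(f"missing item(s): {missing_items}")
    if missing_items:
        for domain, items in DOMAIN_ITEMS.items():
            answered = [n for n in items if n not in missing_items]
            if len(answered) < math.ceil(len(items) / 2):
                raise ValidationError(
                    f"domain {domain}: fewer than half of its items answered; "
                    "half-scale imputation not applicable"
                )
    values: dict[str, float] = {}
    for name in ITEM_NAMES:
        if name in missing_items:
            values[name] = float("nan")
            continue
        spec = ITEM_SPECS[name]
        code = raw[name]
        try:
            code_f = float(code)
        except (TypeError, ValueError):
            raise ValidationError(f"{name}: non-numeric response {code!r}") from None
        if not code_f.is_integer() or not (1 <= code_f <= spec.levels):
            raise ValidationError(
                f"{name}: response {code!r} outside allowed range 1..{spec.levels}"
            )
        values[name] = code_f
    del extra
    return SF12Responses(values=values, imputation=missing_policy)


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# Domain and component scoring
# ---------------------------------------------------------------------------


def _item_score_0_100(name: str, code: float) -> float:
    """Rescale one raw item code to the 0–100, higher-is-better metric."""
    spec = ITEM_SPECS[name]
    recoded = spec.levels + 1 - code if spec.reverse else code
    return 100.0 * (recoded - 1) / (spec.levels - 1)


def score_domains(resp: SF12Responses) -> dict[str, float]:
    """Compute the 8 domain scores (each in [0, 100]) for one respondent.

    A missing item (only possible under the half-scale policy) is imputed
    with the respondent's mean of the answered items in the same domain —
    equivalently, the domain score is the mean of the answered items.
    """
    out: dict[str, float] = {}
    for domain, items in DOMAIN_ITEMS.items():
        scores = [
            _item_score_0_100(n, resp.values[n])
            for n in items
            if not math.isnan(resp.values[n])
        ]
        if not scores:  # guarded by validate_responses
            raise ValidationError(f"domain {domain} has no answered items")
        out[domain] = float(np.mean(scores))
    return out


def score_components(
    dom: Mapping[str, float], coef: ScoringCoefficients
) -> tuple[float, float]:
    """Norm-based PCS/MCS T-scores from the 8 domain scores.

    Each domain is z-standardized with the coefficient table's means/SDs,
    the PCS/MCS weighted sums are formed, and the T-transform
    (× ``t_scale`` + ``t_center``) is applied.  Returns ``(PCS, MCS)``.
    """
    missing = [d for d in DOMAINS if d not in dom]
    if missing:
        raise ValueError(f"missing domain score(s): {missing}")
    vec = np.array([float(dom[d]) for d in DOMAINS])
    if not np.all(np.isfinite(vec)):
        raise ValueError("domain scores must be finite")
    z = (vec - coef.norm_means) / coef.norm_sds
    pcs = coef.t_center + coef.t_scale * float(z @ coef.pcs_weights)
    mcs = coef.t_center + coef.t_scale * float(z @ coef.mcs_weights)
    return pcs, mcs


def flag_depression_risk(mcs: float, threshold: float = MCS_RISK_THRESHOLD) -> int:
    """Binary depression-risk label: 1 iff MCS is strictly below ``threshold``."""
    mcs = float(mcs)
    if not math.isfinite(mcs):
        raise ValueError(f"MCS must be finite, got {mcs!r}")
    return int(mcs < threshold)


# ---------------------------------------------------------------------------
# Cohort-level scoring
# ---------------------------------------------------------------------------


def score_cohort(
    cohort: pd.DataFrame,
    coef: ScoringCoefficients | None = None,
    *,
    missing_policy: str = "reject",
) -> pd.DataFrame:
    """Score every row of a cohort table.

    ``cohort`` must carry the 12 ``sf12_q*`` columns; any other columns are
    passed through unchanged.  Returns a frame with the 8 domain columns,
    ``PCS``, ``MCS`` and ``depression_risk`` appended.
    """
    coef = coef or default_coefficients()
    missing_cols = [n for n in ITEM_NAMES if n not in cohort.columns]
    if missing_cols:
        raise ValidationError(f"cohort is missing item column(s): {missing_cols}")

    # Vectorized validation + rescaling (the per-respondent operations above
    # remain the reference implementation; this path must match them exactly).
    item_scores: dict[str, np.ndarray] = {}
    for name in ITEM_NAMES:
        spec = ITEM_SPECS[name]
        col = pd.to_numeric(cohort[name], errors="coerce").to_numpy(float)
        isnan = np.isnan(col)
        if np.any(isnan) and missing_policy == "reject":
            bad = cohort.index[isnan][:5].tolist()
            raise ValidationError(f"{name}: missing/non-numeric responses at rows {bad}")
        valid = isnan | ((col == np.floor(col)) & (col >= 1) & (col <= spec.levels))
        if not np.all(valid):
            bad = cohort.index[~valid][:5].tolist()
            raise ValidationError(
                f"{name}: responses outside allowed range 1..{spec.levels} at rows {bad}"
            )
        recoded = spec.levels + 1 - col if spec.reverse else col
        item_scores[name] = 100.0 * (recoded - 1) / (spec.levels - 1)

    domain_scores: dict[str, np.ndarray] = {}
    for domain, items in DOMAIN_ITEMS.items():
        stacked = np.column_stack([item_scores[i] for i in items])
        answered = np.sum(~np.isnan(stacked), axis=1)
        if np.any(answered < math.ceil(stacked.shape[1] / 2)):
            raise ValidationError(
                f"domain {domain}: fewer than half of its items answered for some rows"
            )
        with np.errstate(invalid="ignore"):
            domain_scores[domain] = np.nanmean(stacked, axis=1)

    dom_matrix = np.column_stack([domain_scores[d] for d in DOMAINS])
    z = (dom_matrix - coef.norm_means) / coef.norm_sds
    pcs = coef.t_center + coef.t_scale * (z @ coef.pcs_weights)
    mcs = coef.t_center + coef.t_scale * (z @ coef.mcs_weights)
    scored = pd.DataFrame(domain_scores, index=cohort.index)[list(DOMAINS)]
    scored["PCS"] = pcs
    scored["MCS"] = mcs
    scored["depression_risk"] = (mcs < MCS_RISK_THRESHOLD).astype(int)
    return pd.concat([cohort, scored], axis=1)


def summarize_cohort(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-domain and component means/SDs plus risk prevalence.

    SDs are population SDs (ddof=0) so a single-patient cohort reports 0.
    Prevalence is ``100 × flagged / n`` rounded to two decimals; the exact
    flag count is reported alongside so the identity ``count = n ×
    prevalence/100`` can always be recovered from the unrounded columns.
    """
    if len(scored) == 0:
        raise ValueError("cannot summarize an empty cohort")
    required = [*DOMAINS, "PCS", "MCS", "depression_risk"]
    missing = [c for c in required if c not in scored.columns]
    if missing:
        raise ValueError(f"scored cohort missing column(s): {missing}")
    n = len(scored)
    rows = []
    for col in [*DOMAINS, "PCS", "MCS"]:
        vals = scored[col].to_numpy(float)
        rows.append(
            {"measure": col, "mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=0))}
        )
    count = int(scored["depression_risk"].sum())
    rows.append(
        {
            "measure": "depression_risk",
            "count": count,
            "n": n,
            "prevalence_pct": round(100.0 * count / n, 2),
        }
    )
    return pd.DataFrame(rows)


def prevalence_pct(labels: Iterable[int]) -> float:
    """Risk prevalence of a label vector as a percentage, two decimals."""
    labels = np.asarray(list(labels), dtype=float)
    if labels.size == 0:
        raise ValueError("empty label vector")
    return round(100.0 * float(labels.sum()) / labels.size, 2)
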