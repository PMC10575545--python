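"""Group-level models behind the ratio table.

Estimates the four level means (female/male x autosome/Z, or PAR/non-PAR x
sex) of a transformed response (log2 expression or peak height,
arcsine-square-root methylation proportion), adjusting for standardized
covariates such as chromosome and gene length, then forms ratios of the
back-transformed level estimates with case-bootstrap CIs over features.

Fitting methods
---------------
``two_stage`` (default): feature-level means per group level, then
precision-weighted level means — consistent, fast, and the method the
bootstrap refits. ``mixed``: a REML linear mixed model with variance
components for feature and individual (statsmodels); agrees with the
two-stage fit on balanced designs and is retained as a cross-check.
``ols``: plain level-means OLS with covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zdose.datamodel import RatioEstimate, ValidationError

AZS_LEVELS = ("AAf", "AAm", "Zf", "ZZm")
AZP_LEVELS = ("PARf", "PARm", "nonPARf", "nonPARm")


@dataclass(frozen=True)
class GroupModelSpec:
    response: str                       # expression | peak_height | methylation
    transform: str                      # log2 | arcsine_sqrt
    factor: str = "AZS"                 # AZS | AZP
    covariates: tuple[str, ...] = ()
    method: str = "two_stage"           # two_stage | mixed | ols

    def __post_init__(self) -> None:
        if self.transform not in ("log2", "arcsine_sqrt"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.transform == "arcsine_sqrt" and self.response != "methylation":
            raise ValidationError("arcsine_sqrt is for proportion responses only")
        if self.factor not in ("AZS", "AZP"):
            raise ValidationError(f"unknown factor {self.factor!r}")

    @property
    def levels(self) -> tuple[str, ...]:
        return AZS_LEVELS if self.factor == "AZS" else AZP_LEVELS


@dataclass
class GroupEstimates:
    spec: GroupModelSpec
    transformed: dict                      # level -> estimate on transformed scale
    linear: dict                           # level -> back-transformed estimate
    variance_components: dict = field(default_factory=dict)
    covariate_centring: dict = field(default_factory=dict)


def _apply_transform(y: np.ndarray, transform: str) -> np.ndarray:
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite response values")
    if transform == "log2":
        if (y <= 0).any():
            raise ValidationError("log2 transform requires positive responses")
        return np.log2(y)
    if ((y < 0) | (y > 1)).any():
        raise ValidationError("proportion response outside [0, 1]")
    return np.arcsin(np.sqrt(y))


def back_transform(x, transform: str):
    """Exact inverse of the model transform (2**x or sin(x)**2)."""
    x = np.asarray(x, dtype=float)
    out = 2.0 ** x if transform == "log2" else np.sin(x) ** 2
    return out if out.ndim else float(out)


def _standardize_covariates(data: pd.DataFrame, covariates) -> tuple[np.ndarray, dict]:
    centring = {}
    cols = []
    for c in covariates:
        v = data[c].to_numpy(dtype=float)
        mu, sd = float(v.mean()), float(v.std())
        if sd == 0:
            raise ValidationError(f"covariate {c} is constant")
        cols.append((v - mu) / sd)
        centring[c] = {"mean": mu, "sd": sd}
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, centring


def _residualize(y, levels_codes, n_levels, X):
    """Partial out covariates at covariate = 0, keeping level means intact."""
    if X.shape[1] == 0:
        return y, np.zeros(0)
    D = np.zeros((len(y), n_levels))
    D[np.arange(len(y)), levels_codes] = 1.0
    full = np.column_stack([D, X])
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    return y - X @ beta[n_levels:], beta[n_levels:]


def fit_group_model(data: pd.DataFrame, spec: GroupModelSpec) -> GroupEstimates:
    """Estimate the four level means of the transformed response.

    ``data`` is a long table with columns ``response``, ``level`` (one of
    the factor's four levels), ``feature_id``, ``sample_id`` and any
    covariate columns named in the spec. Reported estimates are marginal
    level means at covariate = 0 (covariates are z-scored internally).
    """
    required = {"response", "level", "feature_id", "sample_id"}
    missing = required - set(data.columns)
    if missing:
        raise ValidationError(f"model data missing columns: {sorted(missing)}")
    present = set(data["level"].unique())
    absent = set(spec.levels) - present
    if absent:
        raise ValidationError(f"missing factor levels: {sorted(absent)}")
    y = _apply_transform(data["response"].to_numpy(dtype=float), spec.transform)
    codes = pd.Categorical(data["level"], categories=spec.levels).codes
    X, centring = _standardize_covariates(data, spec.covariates)
    y_adj, _ = _residualize(y, codes, len(spec.levels), X)

    vc: dict[str, float] = {}
    if spec.method == "two_stage":
        cell = pd.DataFrame({
            "feature": data["feature_id"].to_numpy(),
            "level": data["level"].to_numpy(),
            "y": y_adj,
        })
        fm = cell.groupby(["level", "feature"], observed=True)["y"].agg(
            ["mean", "size"]
        )
        est = {}
        for lv in spec.levels:
            sub = fm.loc[lv]
            w = sub["size"].to_numpy(dtype=float)  # precision weight: cell n
            est[lv] = float(np.average(sub["mean"].to_numpy(), weights=w))
    elif spec.method == "ols":
        D = np.zeros((len(y_adj), len(spec.levels)))
        D[np.arange(len(y_adj)), codes] = 1.0
        beta, *_ = np.linalg.lstsq(D, y_adj, rcond=None)
        est = {lv: float(beta[i]) for i, lv in enumerate(spec.levels)}
    elif spec.method == "mixed":
        est, vc = _fit_mixed(data, y_adj, spec)
    else:
        raise ValidationError(f"unknown fitting method {spec.method!r}")

    linear = {lv: back_transform(v, spec.transform) for lv, v in est.items()}
    return GroupEstimates(
        spec=spec, transformed=est, linear=linear,
        variance_components=vc, covariate_centring=centring,
    )


def _fit_mixed(data: pd.DataFrame, y_adj: np.ndarray, spec: GroupModelSpec):
    """REML mixed model: level fixed effects + variance components for
    feature (nested unit) and individual."""
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y": y_adj,
        "level": pd.Categorical(data["level"], categories=spec.levels),
        "feature_id": data["feature_id"].to_numpy(),
        "sample_id": data["sample_id"].to_numpy(),
        "g": 1,  # single group; random effects enter as variance components
    })
    vcf = {"feature": "0 + C(feature_id)", "individual": "0 + C(sample_id)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("y ~ 0 + level", df, groups="g", vc_formula=vcf)
        fit = model.fit(reml=True, method="lbfgs")
    est = {}
    for lv in spec.levels:
        key = f"level[{lv}]"
        est[lv] = float(fit.params[key])
    vc = {k: float(v) for k, v in fit.vcomp_to_dict().items()} if hasattr(
        fit, "vcomp_to_dict") else {}
    vc["residual"] = float(fit.scale)
    return est, vc


RATIO_PAIRS = {
    "AZS": (("AAf", "AAm"), ("ZZm", "AAm"), ("Zf", "ZZm"), ("Zf", "AAf")),
    "AZP": (("PARf", "PARm"), ("nonPARm", "PARm"),
            ("nonPARf", "nonPARm"), ("nonPARf", "PARf")),
}


def model_ratios(data: pd.DataFrame, spec: GroupModelSpec, n_boot: int = 1_000,
                 seed: int = 0) -> dict[str, RatioEstimate]:
    """Ratios of back-transformed level estimates, with case-bootstrap CIs.

    Features are resampled with replacement and the (two-stage) fit is
    recomputed per replicate; CIs are 2.5/97.5 percentiles. A denominator
    estimate <= 0 flags the ratio undefined (NaN bounds).
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    point = fit_group_model(data, spec)
    refit_spec = GroupModelSpec(
        response=spec.response, transform=spec.transform,
        factor=spec.factor, covariates=spec.covariates, method="two_stage",
    )
    features = data["feature_id"].unique()
    by_feature = {f: g for f, g in data.groupby("feature_id")}
    rng = np.random.default_rng(seed)
    boot_levels = {lv: np.empty(n_boot) for lv in spec.levels}
    for b in range(n_boot):
        take = rng.choice(features, size=len(features), replace=True)
        frames = []
        for i, f in enumerate(take):
            g = by_feature[f].copy()
            g["feature_id"] = f"b{i}"   # resampled copies are distinct features
            frames.append(g)
        bd = pd.concat(frames, ignore_index=True)
        try:
            fit = fit_group_model(bd, refit_spec)
        except ValidationError:
            for lv in spec.levels:
                boot_levels[lv][b] = np.nan
            continue
        for lv in spec.levels:
            boot_levels[lv][b] = fit.linear[lv]
    out: dict[str, RatioEstimate] = {}
    for num, den in RATIO_PAIRS[spec.factor]:
        label = f"{num}:{den}"
        d = point.linear[den]
        if d <= 0:
            out[label] = RatioEstimate(label, np.nan, np.nan, np.nan,
                                       len(features), n_boot)
            continue
        estimate = point.linear[num] / d
        with np.errstate(invalid="ignore", divide="ignore"):
            boot = boot_levels[num] / boot_levels[den]
        boot = boot[np.isfinite(boot)]
        if len(boot) == 0:
            lo = hi = np.nan
        else:
            lo, hi = np.percentile(boot, [2.5, 97.5])
        out[label] = RatioEstimate(
            label=label, estimate=float(estimate), ci_low=float(lo),
            ci_high=float(hi), n_features=len(features), n_boot=n_boot,
        )
    return out
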