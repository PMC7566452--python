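"""Allometric biomass models, TLS volume-to-AGB conversion and new fits.

Three model forms are supported, covering the published redwood allometries
this pipeline compares against:

``log_log``
    ln(M) = b0 + b1 * ln(D), with a multiplicative correction factor for the
    bias of the back-transformation to arithmetic units (CF >= 1).  Used by
    the generalised (Jenkins-style) models and the DBH-only species model.
``power_product``
    M = a * X1^b1 * X2^b2 * ... over the model's predictors.
``volume_density``
    V = a * X1^b1 * ... (m^3), then M = rho * V with the model's wood
    density — the same density used to convert TLS cylinder-model volume.

Predictors are any of DBH, fDBH, DTB (diameters) and H (height).  Internal
units are meters; a model may declare ``predictor_unit: cm`` (the US
generalised models do) and kilogram or ton response.  Masses are reported
in metric tons (Mg).

Uncertainty in the stem dimensions (the circle / alpha-shape fit RMSEs) is
propagated to AGB by seeded Monte Carlo with positive-truncated normal
draws of each predictor; the first-order delta method serves as the
independent cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.stats import truncnorm

from .exceptions import ConfigError, ParameterError, PredictorError
from .qsm import QSMEnsemble
from .stem import StemMetrics

VALID_FORMS = ("log_log", "power_product", "volume_density")
VALID_PREDICTORS = ("DBH", "fDBH", "DTB", "H")

__all__ = [
    "AllometricModel",
    "AGBEstimate",
    "PowerLawFit",
    "load_models",
    "default_model_bank_path",
    "predict_agb",
    "tls_agb",
    "fit_power_law",
]


@dataclass(frozen=True)
class AllometricModel:
    model_id: str
    form: str
    predictors: tuple[str, ...]
    coefficients: dict
    correction_factor: float = 1.0
    wood_density_kg_m3: float | None = None
    predictor_unit: str = "m"  # unit the coefficients expect for diameters/height
    response: str = "agb_t"  # agb_t | agb_kg | volume_m3 (volume_density only)
    source: str = ""

    def __post_init__(self):
        if self.form not in VALID_FORMS:
            raise ConfigError(f"{self.model_id}: unknown form {self.form!r}")
        if not self.predictors:
            raise ConfigError(f"{self.model_id}: predictors must be non-empty")
        for p in self.predictors:
            if p not in VALID_PREDICTORS:
                raise ConfigError(f"{self.model_id}: unknown predictor {p!r}")
        if self.correction_factor < 1.0:
            raise ConfigError(f"{self.model_id}: correction_factor must be >= 1")
        if self.form == "log_log":
            if len(self.predictors) != 1:
                raise ConfigError(f"{self.model_id}: log_log takes exactly one predictor")
            for c in ("b0", "b1"):
                if c not in self.coefficients:
                    raise ConfigError(f"{self.model_id}: missing coefficient {c!r}")
        else:
            if "a" not in self.coefficients:
                raise ConfigError(f"{self.model_id}: missing coefficient 'a'")
            for p in self.predictors:
                if f"b_{p}" not in self.coefficients:
                    raise ConfigError(f"{self.model_id}: missing coefficient 'b_{p}'")
        if self.form == "volume_density" and not self.wood_density_kg_m3:
            raise ConfigError(f"{self.model_id}: volume_density needs wood_density_kg_m3")

    def predict_t(self, values: dict[str, float]) -> float:
        """Point AGB prediction in metric tons from predictor values in meters."""
        scale = 100.0 if self.predictor_unit == "cm" else 1.0
        x = {}
        for p in self.predictors:
            if p not in values or values[p] is None or not np.isfinite(values[p]):
                raise PredictorError(f"{self.model_id}: missing predictor {p}")
            if values[p] <= 0:
                raise PredictorError(f"{self.model_id}: non-positive predictor {p}")
            x[p] = values[p] * scale
        c = self.coefficients
        if self.form == "log_log":
            raw = math.exp(c["b0"] + c["b1"] * math.log(x[self.predictors[0]]))
        else:
            raw = c["a"]
            for p in self.predictors:
                raw *= x[p] ** c[f"b_{p}"]
        raw *= self.correction_factor
        if self.form == "volume_density":
            return raw * self.wood_density_kg_m3 / 1000.0
        if self.response == "agb_kg":
            return raw / 1000.0
        return raw


@dataclass(frozen=True)
class AGBEstimate:
    tree_id: str
    method_id: str
    agb_t: float
    agb_sd_t: float

    def __post_init__(self):
        assert self.agb_t > 0 and self.agb_sd_t >= 0


def default_model_bank_path() -> Path:
    return Path(resources.files("tlstree").joinpath("data/allometric_models.yaml"))


def load_models(path: str | Path | None = None) -> list[AllometricModel]:
    """Load the allometric model bank from a YAML config.

    Coefficients are data shipped in the config, never constants in code; a
    missing coefficient raises a config error naming model and field.
    """
    path = Path(path) if path is not None else default_model_bank_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "models" not in raw:
        raise ConfigError(f"{path}: expected a top-level 'models' list")
    models = []
    for entry in raw["models"]:
        try:
            models.append(
                AllometricModel(
                    model_id=entry["model_id"],
                    form=entry["form"],
                    predictors=tuple(entry["predictors"]),
                    coefficients=dict(entry.get("coefficients", {})),
                    correction_factor=float(entry.get("correction_factor", 1.0)),
                    wood_density_kg_m3=entry.get("wood_density_kg_m3"),
                    predictor_unit=entry.get("predictor_unit", "m"),
                    response=entry.get("response", "agb_t"),
                    source=entry.get("source", ""),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"model entry missing field {exc}") from None
    return models


def save_models(models: list[AllometricModel], path: str | Path) -> None:
    data = {"models": []}
    for m in models:
        data["models"].append(
            dict(
                model_id=m.model_id, form=m.form, predictors=list(m.predictors),
                coefficients={k: float(v) for k, v in m.coefficients.items()},
                correction_factor=m.correction_factor,
                wood_density_kg_m3=m.wood_density_kg_m3,
                predictor_unit=m.predictor_unit, response=m.response, source=m.source,
            )
        )
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _metric_values(metrics: StemMetrics) -> tuple[dict, dict]:
    values = dict(DBH=metrics.dbh_m, fDBH=metrics.fdbh_m, DTB=metrics.dtb_m,
                  H=metrics.height_m)
    sds = dict(DBH=metrics.dbh_rmse_m, fDBH=metrics.fdbh_rmse_m,
               DTB=metrics.dtb_rmse_m, H=0.0)
    return values, sds


def predict_agb(
    model: AllometricModel,
    metrics: StemMetrics,
    mc_n: int = 1000,
    seed: int = 0,
) -> AGBEstimate:
    """Model AGB for one tree with Monte-Carlo uncertainty propagation.

    Each required predictor is drawn ``mc_n`` times from a positive-truncated
    normal centred on its measured value with its fit RMSE as spread; the SD
    of the resulting AGB sample is the reported uncertainty.  Height carries
    no fit RMSE and is held fixed.
    """
    values, sds = _metric_values(metrics)
    point = model.predict_t(values)
    if all((sds[p] or 0.0) == 0.0 for p in model.predictors):
        return AGBEstimate(tree_id=metrics.tree_id, method_id=model.model_id,
                           agb_t=point, agb_sd_t=0.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x616C6C6F]))
    draws = {}
    for p in model.predictors:
        mu, sd = values[p], sds[p] or 0.0
        if sd > 0:
            a = (0.0 - mu) / sd  # truncate at zero
            draws[p] = truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=mc_n, random_state=rng)
        else:
            draws[p] = np.full(mc_n, mu)
    sample = np.empty(mc_n)
    for i in range(mc_n):
        sample[i] = model.predict_t({p: float(draws[p][i]) for p in model.predictors})
    sd = float(sample.std(ddof=1))
    return AGBEstimate(tree_id=metrics.tree_id, method_id=model.model_id,
                       agb_t=point, agb_sd_t=sd)


def tls_agb(
    ensemble: QSMEnsemble | tuple[float, float],
    wood_density_kg_m3: float,
    tree_id: str = "",
) -> AGBEstimate:
    """Convert a QSM volume ensemble to AGB: agb = rho * V (exactly linear)."""
    if wood_density_kg_m3 <= 0:
        raise ParameterError("wood density must be > 0")
    if isinstance(ensemble, QSMEnsemble):
        mean, sd = ensemble.volume_mean_m3, ensemble.volume_sd_m3
    else:
        mean, sd = ensemble
    return AGBEstimate(
        tree_id=tree_id, method_id="tls",
        agb_t=wood_density_kg_m3 * mean / 1000.0,
        agb_sd_t=wood_density_kg_m3 * sd / 1000.0,
    )


@dataclass(frozen=True)
class PowerLawFit:
    coefficients: dict  # a, b_<pred> ...
    se: dict  # standard error per coefficient
    rmse_percent: float
    n: int
    predictors: tuple[str, ...]
    response: str

    def predict(self, records) -> np.ndarray:
        y = np.asarray(records[self.predictors[0]], dtype=float) ** \
            self.coefficients[f"b_{self.predictors[0]}"]
        for p in self.predictors[1:]:
            y = y * np.asarray(records[p], dtype=float) ** self.coefficients[f"b_{p}"]
        return self.coefficients["a"] * y


def fit_power_law(
    records,
    response: str,
    predictors: tuple[str, ...] | list[str],
    weighting: str = "none",
) -> PowerLawFit:
    """Fit ``y = a * prod(x_i^b_i)`` to per-tree records (DataFrame-like).

    Log-space linear least squares provides the starting point; a nonlinear
    refinement minimises arithmetic residuals (``weighting='none'``) or
    relative residuals (``weighting='relative'``).  ``rmse_percent`` is
    ``100 * RMSE(response) / mean(response)``.  Deterministic given the data.
    """
    predictors = tuple(predictors)
    y = np.asarray(records[response], dtype=float)
    X = np.column_stack([np.asarray(records[p], dtype=float) for p in predictors])
    if len(y) < 10:
        raise ParameterError(f"need >= 10 records, got {len(y)}")
    if np.any(y <= 0) or np.any(X <= 0):
        raise ParameterError("predictors and response must be positive")
    if weighting not in ("none", "relative"):
        raise ParameterError(f"unknown weighting {weighting!r}")

    # log-space initialisation
    A = np.column_stack([np.ones(len(y)), np.log(X)])
    sol, *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
    if not np.all(np.isfinite(sol)):
        raise ParameterError("singular design in log-space initialisation")
    theta0 = np.concatenate([[math.exp(sol[0])], sol[1:]])

    def model(theta):
        return theta[0] * np.prod(X ** theta[1:], axis=1)

    def resid(theta):
        r = model(theta) - y
        return r / y if weighting == "relative" else r

    fit = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14)
    theta = fit.x
    res = model(theta) - y
    rmse_percent = 100.0 * float(np.sqrt(np.mean(res**2))) / float(np.mean(y))

    # coefficient covariance from the final jacobian
    dof = max(len(y) - len(theta), 1)
    s2 = float(np.sum(fit.fun**2)) / dof
    try:
        cov = np.linalg.inv(fit.jac.T @ fit.jac) * s2
        se_vec = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_vec = np.full(len(theta), np.nan)

    names = ["a"] + [f"b_{p}" for p in predictors]
    return PowerLawFit(
        coefficients=dict(zip(names, map(float, theta))),
        se=dict(zip(names, map(float, se_vec))),
        rmse_percent=rmse_percent,
        n=len(y),
        predictors=predictors,
        response=response,
    )
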