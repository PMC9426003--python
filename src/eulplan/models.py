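"""Knowledge-based EUD-EUL linear models and the study's statistics.

A model links the geometric EUL of an organ (cm) to the gEUD (Gy) a good
plan achieves for it, via ordinary least squares ``EUD = b0 + b1 * EUL``.
Published coefficient sets for the bladder and rectum at ``a = 1`` ship
with the package and can predict an achievable mean organ dose from
geometry alone; freshly fitted models additionally carry the diagnostics
needed for confidence and prediction intervals.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EEKBModel",
    "PairedTestResult",
    "ConsistencyReport",
    "fit_eekb",
    "predict_eud",
    "prediction_interval",
    "confidence_interval",
    "consistency",
    "paired_t_test",
    "save_model",
    "load_model",
    "load_published",
    "ModelNotFittedError",
    "ModelSchemaError",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class ModelNotFittedError(ValueError):
    """Interval query on a model without fit diagnostics (e.g. published)."""


class ModelSchemaError(ValueError):
    """A model file is malformed or from an unknown schema."""


@dataclass(frozen=True)
class EEKBModel:
    """A linear EUL (cm) -> EUD (Gy) model for one organ and one ``a``.

    ``intercept_gy`` is the predicted EUD of an organ touching the target
    (EUL = 0); ``slope_gy_per_cm`` is the dose spared per centimetre of
    separation (negative).  Fitted models carry regression diagnostics;
    published models transcribe only coefficients, n and R².
    """

    organ: str
    a: float
    intercept_gy: float
    slope_gy_per_cm: float
    n: int
    r2: float
    source: str = "fitted"
    adj_r2: float | None = None
    pearson_r: float | None = None
    pearson_p: float | None = None
    residual_se_gy: float | None = None
    x_mean_cm: float | None = None
    sxx_cm2: float | None = None
    x_min_cm: float | None = None
    x_max_cm: float | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"a model needs n >= 3, got n={self.n}")
        if self.r2 > 1 + 1e-12:
            raise ValueError(f"r2 must be <= 1, got {self.r2}")
        if self.residual_se_gy is not None and self.residual_se_gy < 0:
            raise ValueError("residual standard error must be >= 0")
        if self.pearson_r is not None and not -1 <= self.pearson_r <= 1:
            raise ValueError("Pearson r must lie in [-1, 1]")

    @property
    def is_fitted(self) -> bool:
        return None not in (self.residual_se_gy, self.x_mean_cm, self.sxx_cm2)


def fit_eekb(
    euls_cm: Sequence[float],
    euds_gy: Sequence[float],
    organ: str = "",
    a: float = 1.0,
) -> EEKBModel:
    """Ordinary least squares of EUD on EUL with Pearson correlation test.

    Reports plain ``R² = 1 - SSR/SST``, adjusted
    ``R²_adj = 1 - (1 - R²)(n-1)/(n-2)``, the two-sided Pearson test and the
    residual standard error ``sqrt(SSR/(n-2))``.
    """
    x = np.asarray(euls_cm, float)
    y = np.asarray(euds_gy, float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("EUL and EUD lists must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"fit requires at least 3 points, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("EUL values are all identical; slope is undefined")

    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    ssr = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return EEKBModel(
        organ=organ,
        a=float(a),
        intercept_gy=float(res.intercept),
        slope_gy_per_cm=float(res.slope),
        n=n,
        r2=r2,
        adj_r2=adj_r2,
        pearson_r=float(res.rvalue),
        pearson_p=float(res.pvalue),
        residual_se_gy=math.sqrt(ssr / (n - 2)),
        x_mean_cm=float(x.mean()),
        sxx_cm2=sxx,
        x_min_cm=float(x.min()),
        x_max_cm=float(x.max()),
    )


def predict_eud(model: EEKBModel, eul_cm: float) -> float:
    """Predicted gEUD (Gy) at a given EUL; extrapolation is allowed but logged."""
    if (
        model.x_min_cm is not None
        and model.x_max_cm is not None
        and not model.x_min_cm <= eul_cm <= model.x_max_cm
    ):
        logger.warning(
            "EUL %.3f cm is outside the fit range [%.3f, %.3f]; extrapolating",
            eul_cm,
            model.x_min_cm,
            model.x_max_cm,
        )
    return model.intercept_gy + model.slope_gy_per_cm * eul_cm


def _interval(
    model: EEKBModel, eul_cm: float, level: float, prediction: bool
) -> tuple[float, float]:
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if not model.is_fitted:
        raise ModelNotFittedError(
            f"model for {model.organ!r} ({model.source}) carries no residual "
            "spread; intervals require a freshly fitted model"
        )
    t_crit = stats.t.ppf((1 + level) / 2, df=model.n - 2)
    leverage = 1.0 / model.n + (eul_cm - model.x_mean_cm) ** 2 / model.sxx_cm2
    half = t_crit * model.residual_se_gy * math.sqrt(
        (1.0 if prediction else 0.0) + leverage
    )
    center = predict_eud(model, eul_cm)
    return center - half, center + half


def prediction_interval(
    model: EEKBModel, eul_cm: float, level: float = 0.95
) -> tuple[float, float]:
    """Interval expected to contain a *new* plan's EUD at this EUL."""
    return _interval(model, eul_cm, level, prediction=True)


def confidence_interval(
    model: EEKBModel, eul_cm: float, level: float = 0.95
) -> tuple[float, float]:
    """Interval for the *mean* EUD of plans at this EUL (always inside the PI)."""
    return _interval(model, eul_cm, level, prediction=False)


@dataclass(frozen=True)
class ConsistencyReport:
    """How tightly one set of plans follows a single EUD-EUL line.

    A planning strategy that sets OAR objectives from geometry produces
    plans hugging one line (R² near 1); heterogeneous manual planning can
    drive the adjusted R² to zero or below.
    """

    model: EEKBModel
    r2: float
    adj_r2: float


def consistency(
    pairs: Iterable[tuple[float, float]], organ: str = "", a: float = 1.0
) -> ConsistencyReport:
    """Fit a plan set's (EUL, EUD) pairs and report plain and adjusted R²."""
    pts = list(pairs)
    if len(pts) < 3:
        raise ValueError(f"consistency needs at least 3 plans, got {len(pts)}")
    x, y = zip(*pts)
    model = fit_eekb(x, y, organ=organ, a=a)
    return ConsistencyReport(model=model, r2=model.r2, adj_r2=model.adj_r2)


@dataclass(frozen=True)
class PairedTestResult:
    """Two-tailed paired t-test between matched plan metrics."""

    t_stat: float
    p_value: float
    df: int
    mean_diff: float


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Paired t-test of matched samples; identical samples give t=0, p=1.

    Zero variance of the differences with a nonzero mean difference is a
    degenerate design (t diverges) and raises.
    """
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("paired test needs two equal-length 1-D samples")
    n = xa.size
    if n < 2:
        raise ValueError(f"paired test needs n >= 2, got {n}")
    d = xa - ya
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        if mean_d == 0:
            return PairedTestResult(t_stat=0.0, p_value=1.0, df=n - 1, mean_diff=0.0)
        raise ValueError("all paired differences are identical and nonzero")
    t = mean_d / (sd / math.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(t_stat=t, p_value=float(p), df=n - 1, mean_diff=mean_d)


# --- persistence ----------------------------------------------------------

_REQUIRED_FIELDS = (
    "schema_version",
    "organ",
    "a",
    "intercept_gy",
    "slope_gy_per_cm",
    "n",
    "r2",
    "source",
)
_OPTIONAL_FIELDS = (
    "adj_r2",
    "pearson_r",
    "pearson_p",
    "residual_se_gy",
    "x_mean_cm",
    "sxx_cm2",
    "x_min_cm",
    "x_max_cm",
)


def save_model(model: EEKBModel, path: str | Path) -> None:
    """Write a model as JSON; reals are encoded as decimal strings so a
    save/load round-trip is bit-exact."""
    payload: dict[str, object] = {"schema_version": SCHEMA_VERSION}
    for key, value in asdict(model).items():
        payload[key] = repr(float(value)) if isinstance(value, float) else value
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _model_from_payload(payload: dict, origin: str) -> EEKBModel:
    for key in _REQUIRED_FIELDS:
        if key not in payload:
            raise ModelSchemaError(f"{origin}: missing required field {key!r}")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise ModelSchemaError(
            f"{origin}: unknown schema_version {payload['schema_version']!r}"
        )
    unknown = set(payload) - set(_REQUIRED_FIELDS) - set(_OPTIONAL_FIELDS)
    if unknown:
        raise ModelSchemaError(f"{origin}: unknown fields {sorted(unknown)}")

    def real(value):
        return None if value is None else float(value)

    try:
        return EEKBModel(
            organ=str(payload["organ"]),
            a=real(payload["a"]),
            intercept_gy=real(payload["intercept_gy"]),
            slope_gy_per_cm=real(payload["slope_gy_per_cm"]),
            n=int(payload["n"]),
            r2=real(payload["r2"]),
            source=str(payload["source"]),
            **{k: real(payload.get(k)) for k in _OPTIONAL_FIELDS},
        )
    except (TypeError, ValueError) as exc:
        raise ModelSchemaError(f"{origin}: invalid model payload ({exc})") from exc


def load_model(path: str | Path) -> EEKBModel:
    """Load a model JSON written by :func:`save_model` (or shipped)."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelSchemaError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise ModelSchemaError(f"{path}: model file must contain a JSON object")
    return _model_from_payload(payload, str(path))


def load_published(organ: str, a: float = 1.0) -> EEKBModel:
    """Load a published coefficient set shipped with the package.

    Available: ``bladder`` and ``rectum`` at ``a = 1``.  These carry the
    published intercept/slope/n/R² only; interval queries on them raise
    :class:`ModelNotFittedError`.
    """
    name = f"{organ.lower()}_a{a:g}.json"
    ref = resources.files("eulplan.data").joinpath(name)
    if not ref.is_file():
        raise FileNotFoundError(
            f"no published model for organ={organ!r}, a={a:g} (looked for {name})"
        )
    payload = json.loads(ref.read_text())
    return _model_from_payload(payload, name)
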