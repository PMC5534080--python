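"""Weibull proportional-hazards simulation of right-censored survival data.

Event times follow a Weibull distribution with shape ``theta`` and a
per-subject scale

    lambda_i = exp(-beta_0/theta - sum_j beta_j x_ij / theta),

so that the cumulative hazard is H(t | x) = t^theta * exp(beta_0 + beta'x):
a proportional-hazards model with baseline hazard
h_0(t) = theta * exp(beta_0) * t^(theta-1). Shape theta > 1 gives an
increasing hazard, theta < 1 decreasing, theta = 1 constant (exponential
event times). Censoring times are Weibull with a fixed shape and a scale
calibrated by Monte-Carlo bisection so the observed censoring fraction hits
a prescribed target.

The built-in design registry reproduces the twenty-two simulation designs
used throughout the package's benchmark: six binary-covariate designs, six
polytomous (many-split-point) designs, six mixed designs and four designs
with covariate interactions, spanning sample sizes 100-2000 and censoring
targets 20/50/80%.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Invalid simulation design or covariate specification."""


class CalibrationError(RuntimeError):
    """Censoring-scale root finding could not bracket the target rate."""


@dataclass(frozen=True)
class CovariateSpec:
    """One simulated covariate.

    binary: Bernoulli(p) in {0,1} with a single regression coefficient.
    polytomous: >=3 unordered levels sampled with the given weights; each
    level carries its own coefficient (the level contrasts of the linear
    predictor).
    """

    name: str
    kind: str  # "binary" | "polytomous"
    bernoulli_p: float | None = None
    coefficient: float | None = None
    levels: tuple[str, ...] = ()
    weights: tuple[float, ...] = ()
    level_coefficients: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "binary":
            if self.bernoulli_p is None or not (0.0 < self.bernoulli_p < 1.0):
                raise ConfigurationError(
                    f"{self.name}: bernoulli_p must lie strictly in (0,1)"
                )
            if self.coefficient is None:
                raise ConfigurationError(f"{self.name}: binary spec needs a coefficient")
        elif self.kind == "polytomous":
            if len(self.levels) < 3:
                raise ConfigurationError(
                    f"{self.name}: polytomous spec needs at least 3 levels"
                )
            if len(self.weights) != len(self.levels):
                raise ConfigurationError(f"{self.name}: one weight per level required")
            if abs(sum(self.weights) - 1.0) > 1e-9:
                raise ConfigurationError(f"{self.name}: level weights must sum to 1")
            if len(self.level_coefficients) != len(self.levels):
                raise ConfigurationError(
                    f"{self.name}: one coefficient per level required"
                )
        else:
            raise ConfigurationError(f"{self.name}: unknown covariate kind {self.kind!r}")

    def numeric_contribution(self, column: np.ndarray) -> np.ndarray:
        """Per-subject contribution of this covariate to the linear predictor."""
        if self.kind == "binary":
            return self.coefficient * column.astype(float)
        coeffs = np.asarray(self.level_coefficients)
        return coeffs[column.astype(int)]


@dataclass(frozen=True)
class Interaction:
    """Product interaction between two covariates.

    Each partner enters through its numeric encoding: the 0/1 value for a
    binary covariate, the per-level coefficient for a polytomous one. The
    interaction adds ``coefficient * enc_a * enc_b`` to the linear predictor.
    """

    first: str
    second: str
    coefficient: float


@dataclass(frozen=True)
class SimDesign:
    """One executable simulation design (a row of the benchmark registry)."""

    design_id: str
    n: int
    covariates: tuple[CovariateSpec, ...]
    event_shape: float  # Weibull shape theta of the event-time distribution
    intercept: float  # beta_0 = log(rho^-theta)
    censor_shape: float
    target_censoring: float
    hazard_trend: str  # "increasing" | "decreasing" | "constant"
    censor_scale: float | None = None  # None => calibrate by root finding
    interactions: tuple[Interaction, ...] = ()

    def __post_init__(self) -> None:
        if self.event_shape <= 0 or self.censor_shape <= 0:
            raise ConfigurationError(f"{self.design_id}: Weibull shapes must be > 0")
        if not (0.0 <= self.target_censoring < 1.0):
            raise ConfigurationError(
                f"{self.design_id}: target censoring must lie in [0,1)"
            )
        expected = (
            "increasing"
            if self.event_shape > 1
            else "decreasing"
            if self.event_shape < 1
            else "constant"
        )
        if self.hazard_trend != expected:
            raise ConfigurationError(
                f"{self.design_id}: hazard_trend {self.hazard_trend!r} inconsistent "
                f"with event shape {self.event_shape}"
            )
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"{self.design_id}: duplicate covariate names")
        for inter in self.interactions:
            if inter.first not in names or inter.second not in names:
                raise ConfigurationError(
                    f"{self.design_id}: interaction names unknown covariates"
                )


@dataclass
class SurvivalDataset:
    """Right-censored dataset: observed time, event indicator, covariates.

    ``covariates`` keeps polytomous columns as pandas Categorical; binary
    columns are 0/1 integers. Latent event/censoring times are retained when
    the data were simulated, for diagnostics only.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)
    true_event_time: np.ndarray | None = None
    true_censor_time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time < 0):
            raise ValueError("observed times must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if self.covariates.shape[1] < 1:
            raise ValueError("at least one covariate column required")
        if len(self.covariates) != self.time.size or self.event.size != self.time.size:
            raise ValueError("time, event and covariates must have equal length")
        if not self.kinds:
            self.kinds = {
                c: ("polytomous" if isinstance(self.covariates[c].dtype, pd.CategoricalDtype) else "binary")
                for c in self.covariates.columns
            }

    @property
    def n(self) -> int:
        return self.time.size

    def to_csv(self, path_or_buf) -> None:
        df = self.covariates.copy()
        df.insert(0, "event", self.event)
        df.insert(0, "time", self.time)
        df.to_csv(path_or_buf, index=False, float_format="%.10g")

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, path_or_buf) -> "SurvivalDataset":
        df = pd.read_csv(path_or_buf)
        if "time" not in df.columns or "event" not in df.columns:
            raise ValueError("CSV must contain 'time' and 'event' columns")
        cov = df.drop(columns=["time", "event"])
        kinds: dict[str, str] = {}
        for c in cov.columns:
            if cov[c].dtype == object:
                cov[c] = pd.Categorical(cov[c])
                kinds[c] = "polytomous"
            else:
                vals = set(pd.unique(cov[c].dropna()))
                kinds[c] = "binary" if vals <= {0, 1} else "continuous"
        return cls(df["time"].to_numpy(), df["event"].to_numpy(), cov, kinds)


# ---------------------------------------------------------------------------
# sampling


def sample_covariates(
    spec_list: Sequence[CovariateSpec], n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw an n x p covariate frame from the given specs."""
    if not spec_list:
        raise ConfigurationError("spec_list must not be empty")
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    cols: dict[str, object] = {}
    for spec in spec_list:
        if spec.kind == "binary":
            cols[spec.name] = (rng.random(n) < spec.bernoulli_p).astype(np.int64)
        else:
            codes = rng.choice(len(spec.levels), size=n, p=np.asarray(spec.weights))
            cols[spec.name] = pd.Categorical.from_codes(
                codes, categories=list(spec.levels)
            )
    return pd.DataFrame(cols)


def _encoded_columns(design: SimDesign, X: pd.DataFrame) -> dict[str, np.ndarray]:
    enc: dict[str, np.ndarray] = {}
    for spec in design.covariates:
        col = X[spec.name]
        if spec.kind == "binary":
            enc[spec.name] = col.to_numpy(dtype=float)
        else:
            coeffs = np.asarray(spec.level_coefficients)
            enc[spec.name] = coeffs[col.cat.codes.to_numpy()]
    return enc


def linear_predictor_scale(design: SimDesign, X: pd.DataFrame) -> np.ndarray:
    """Per-subject Weibull scale lambda_i = exp(-(beta_0 + eta_i)/theta).

    eta_i sums the binary main effects beta_j * x_ij, the per-level
    contributions of polytomous covariates, and any interaction products.
    """
    missing = [c.name for c in design.covariates if c.name not in X.columns]
    if missing:
        raise ConfigurationError(f"covariate columns missing from X: {missing}")
    eta = np.zeros(len(X))
    enc = _encoded_columns(design, X)
    for spec in design.covariates:
        if spec.kind == "binary":
            eta += spec.coefficient * enc[spec.name]
        else:
            eta += enc[spec.name]
    for inter in design.interactions:
        eta += inter.coefficient * enc[inter.first] * enc[inter.second]
    theta = design.event_shape
    lam = np.exp(-(design.intercept + eta) / theta)
    return lam


def gen_event_times(
    design: SimDesign, lam: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Invert the Weibull cumulative hazard: T = lambda * (-log U)^(1/theta).

    Conditional on covariates, T is Weibull(shape=theta, scale=lambda); at
    theta = 1 this is exponential with mean lambda.
    """
    theta = design.event_shape
    if theta <= 0:
        raise ConfigurationError("event shape must be > 0")
    u = rng.random(lam.shape[0])
    # guard against log(0)
    u = np.clip(u, np.finfo(float).tiny, 1.0 - 1e-16)
    return lam * (-np.log(u)) ** (1.0 / theta)


_PROBE_SEED = 170_203  # dedicated seed for calibration probe draws


def calibrate_censoring(
    design: SimDesign,
    n_probe: int = 10_000,
    tolerance: float = 0.02,
    rng: np.random.Generator | None = None,
) -> float:
    """Find the censoring Weibull scale achieving the target censoring rate.

    Draws one fixed probe sample of latent event times T_i and baseline
    censoring draws E_i = (-log V_i)^(1/censor_shape); censoring occurs when
    s*E_i < T_i, so the empirical censoring fraction is a monotone
    non-increasing step function of the scale s. Bisection on log(s) then
    finds the root of that function minus the target.
    """
    target = design.target_censoring
    if target == 0.0:
        return np.inf
    if rng is None:
        rng = np.random.default_rng(_PROBE_SEED)
    X = sample_covariates(design.covariates, n_probe, rng)
    lam = linear_predictor_scale(design, X)
    T = gen_event_times(design, lam, rng)
    v = np.clip(rng.random(n_probe), np.finfo(float).tiny, 1.0 - 1e-16)
    E = (-np.log(v)) ** (1.0 / design.censor_shape)

    def censor_frac(s: float) -> float:
        return float(np.mean(s * E < T))

    lo, hi = 1e-6, 1e6
    for _ in range(80):  # expand until bracketing
        if censor_frac(lo) >= target:
            break
        lo /= 10.0
    for _ in range(80):
        if censor_frac(hi) <= target:
            break
        hi *= 10.0
    if censor_frac(lo) < target or censor_frac(hi) > target:
        raise CalibrationError(
            f"{design.design_id}: cannot bracket target {target}; achieved range "
            f"[{censor_frac(hi):.3f}, {censor_frac(lo):.3f}]"
        )
    llo, lhi = np.log(lo), np.log(hi)
    for _ in range(200):
        mid = 0.5 * (llo + lhi)
        if censor_frac(np.exp(mid)) > target:
            llo = mid
        else:
            lhi = mid
        if abs(censor_frac(np.exp(0.5 * (llo + lhi))) - target) <= tolerance / 4:
            break
    scale = float(np.exp(0.5 * (llo + lhi)))
    achieved = censor_frac(scale)
    if abs(achieved - target) > tolerance:
        raise CalibrationError(
            f"{design.design_id}: calibration reached {achieved:.3f}, "
            f"target {target:.3f} +- {tolerance}"
        )
    return scale


def resolve_design(design: SimDesign) -> SimDesign:
    """Return a design with a concrete censoring scale (calibrating if needed)."""
    if design.censor_scale is not None:
        return design
    return replace(design, censor_scale=calibrate_censoring(design))


def gen_dataset(design: SimDesign, seed: int) -> SurvivalDataset:
    """Simulate one dataset: observed time = min(T, C), event = I(T <= C)."""
    design = resolve_design(design)
    rng = np.random.default_rng(seed)
    X = sample_covariates(design.covariates, design.n, rng)
    lam = linear_predictor_scale(design, X)
    T = gen_event_times(design, lam, rng)
    if np.isinf(design.censor_scale):
        C = np.full(design.n, np.inf)
    else:
        v = np.clip(rng.random(design.n), np.finfo(float).tiny, 1.0 - 1e-16)
        C = design.censor_scale * (-np.log(v)) ** (1.0 / design.censor_shape)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    kinds = {c.name: c.kind for c in design.covariates}
    return SurvivalDataset(
        time, event, X, kinds, true_event_time=T, true_censor_time=C
    )


# ---------------------------------------------------------------------------
# built-in design registry

# binary designs: per hazard trend (event shape, intercept, censor shape,
# ten Bernoulli(0.5) coefficients)
_BINARY_PARAMS = {
    "decreasing": dict(
        event_shape=0.8,
        intercept=-0.98,
        censor_shape=0.4,
        coefficients=(0.5, -0.045, 0.6, -0.03, -2.0, 0.5, 0.25, -0.04, 0.33, 0.3),
    ),
    "increasing": dict(
        event_shape=1.5,
        intercept=-1.44,
        censor_shape=2.4,
        # nine printed coefficients padded with a trailing zero
        coefficients=(0.1, -0.8, 0.5, -0.2, -3.0, 0.7, 0.2, 0.4, 0.3, 0.0),
    ),
    "constant": dict(
        event_shape=1.0,
        intercept=0.9,
        censor_shape=1.0,
        coefficients=(0.4, -0.7, 1.0, -2.0, -3.0, 0.7, 0.06, 0.5, -0.43, 0.3),
    ),
}

# polytomous/mixed/interaction designs share the second simulation framework:
# event shape per trend and censoring shape per trend
_POLY_EVENT_SHAPE = {"decreasing": 0.5, "increasing": 1.5, "constant": 1.0}
_POLY_CENSOR_SHAPE = {"decreasing": 0.4, "increasing": 1.2, "constant": 1.1}

_BINARY_ROWS = [  # (n, %censoring, trend) per registry row
    (100, 0.80, "increasing"),
    (100, 0.50, "decreasing"),
    (250, 0.20, "constant"),
    (1000, 0.80, "increasing"),
    (1500, 0.50, "decreasing"),
    (2000, 0.20, "constant"),
]
_POLY_ROWS = [
    (100, 0.20, "increasing"),
    (100, 0.80, "constant"),
    (250, 0.50, "decreasing"),
    (1000, 0.20, "increasing"),
    (1500, 0.80, "constant"),
    (2000, 0.50, "decreasing"),
]
_MIXED_ROWS = [
    (1000, 0.20, "increasing"),
    (100, 0.80, "decreasing"),
    (250, 0.50, "constant"),
    (1000, 0.20, "increasing"),
    (1500, 0.80, "decreasing"),
    (2000, 0.50, "constant"),
]
_INTER_ROWS = [
    (100, 0.20, "increasing"),
    (100, 0.50, "decreasing"),
    (1000, 0.20, "increasing"),
    (1500, 0.50, "decreasing"),
]


def _binary_specs(trend: str) -> tuple[CovariateSpec, ...]:
    coeffs = _BINARY_PARAMS[trend]["coefficients"]
    return tuple(
        CovariateSpec(name=f"x{j + 1}", kind="binary", bernoulli_p=0.5, coefficient=b)
        for j, b in enumerate(coeffs)
    )


def _poly_specs(n_cov: int = 10, prefix: str = "x") -> tuple[CovariateSpec, ...]:
    """Ten many-level covariates: 3/4/5 levels cyclically, equal weights,
    per-level coefficients evenly spaced on [-1, 1]."""
    specs = []
    cycle = (3, 4, 5)
    for j in range(n_cov):
        n_lev = cycle[j % 3]
        levels = tuple(f"L{k}" for k in range(n_lev))
        specs.append(
            CovariateSpec(
                name=f"{prefix}{j + 1}",
                kind="polytomous",
                levels=levels,
                weights=tuple([1.0 / n_lev] * n_lev),
                level_coefficients=tuple(np.linspace(-1.0, 1.0, n_lev)),
            )
        )
    return tuple(specs)


def _mixed_specs() -> tuple[CovariateSpec, ...]:
    binary = tuple(
        CovariateSpec(name=f"b{j + 1}", kind="binary", bernoulli_p=0.5, coefficient=b)
        for j, b in enumerate((0.5, -0.045, 0.6, -0.03, -2.0))
    )
    poly = _poly_specs(5, prefix="p")
    return binary + poly


def builtin_designs() -> dict[str, SimDesign]:
    """The 22-design registry: 6 binary + 6 polytomous + 6 mixed + 4 interaction."""
    registry: dict[str, SimDesign] = {}
    for i, (n, cens, trend) in enumerate(_BINARY_ROWS, start=1):
        p = _BINARY_PARAMS[trend]
        registry[f"binary_{i}"] = SimDesign(
            design_id=f"binary_{i}",
            n=n,
            covariates=_binary_specs(trend),
            event_shape=p["event_shape"],
            intercept=p["intercept"],
            censor_shape=p["censor_shape"],
            target_censoring=cens,
            hazard_trend=trend,
        )
    for i, (n, cens, trend) in enumerate(_POLY_ROWS, start=1):
        registry[f"poly_{i}"] = SimDesign(
            design_id=f"poly_{i}",
            n=n,
            covariates=_poly_specs(),
            event_shape=_POLY_EVENT_SHAPE[trend],
            intercept=0.0,
            censor_shape=_POLY_CENSOR_SHAPE[trend],
            target_censoring=cens,
            hazard_trend=trend,
        )
    for i, (n, cens, trend) in enumerate(_MIXED_ROWS, start=1):
        registry[f"mixed_{i}"] = SimDesign(
            design_id=f"mixed_{i}",
            n=n,
            covariates=_mixed_specs(),
            event_shape=_POLY_EVENT_SHAPE[trend],
            intercept=0.0,
            censor_shape=_POLY_CENSOR_SHAPE[trend],
            target_censoring=cens,
            hazard_trend=trend,
        )
    for i, (n, cens, trend) in enumerate(_INTER_ROWS, start=1):
        registry[f"inter_{i}"] = SimDesign(
            design_id=f"inter_{i}",
            n=n,
            covariates=_mixed_specs(),
            event_shape=_POLY_EVENT_SHAPE[trend],
            intercept=0.0,
            censor_shape=_POLY_CENSOR_SHAPE[trend],
            target_censoring=cens,
            hazard_trend=trend,
            interactions=(
                Interaction("b1", "p1", 0.7),
                Interaction("b5", "p2", -0.7),
            ),
        )
    return registry
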