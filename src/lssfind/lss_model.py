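"""Locally spiky sparse (LSS) models and synthetic data generation.

An LSS model is an additive regression model whose mean function is a linear
combination of Boolean threshold interactions,

    E[Y | X] = beta_0 + sum_j beta_j * prod_{k in S_j} 1(x_k <= gamma_k or x_k > gamma_k),

with the inequality direction encoded per feature by a *sign*: -1 for the
"<=" branch and +1 for the ">" branch.  Features are uniform on [0, 1] under
the reference data-generating process, which makes threshold coverage and
signal variance available in closed form for disjoint interactions.

This module provides the model containers, a calibrated simulation-model
builder (threshold set so a target fraction of samples activates at least one
interaction), feature/noise samplers including the misspecification modes
(AR(1)-correlated features via a Gaussian copula, overlapping interactions,
Laplace/Cauchy noise), and enumeration of union signed interactions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import chain, combinations, product
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SignedFeature",
    "BasicInteraction",
    "LSSModel",
    "Dataset",
    "regression_function",
    "calibrate_threshold",
    "calibrate_threshold_overlap",
    "build_simulation_model",
    "build_overlap_model",
    "sample_features",
    "signal_variance",
    "sample_dataset",
    "union_signed_interactions",
]


class SignedFeature(NamedTuple):
    """A feature index (1-based) with a split direction.

    sign -1 corresponds to the "<= threshold" branch, +1 to "> threshold".
    """

    index: int
    sign: int

    def __repr__(self) -> str:  # compact: (3,-1) -> "3:-1"
        return f"{self.index}:{self.sign:+d}"


SignedFeatureSet = frozenset  # frozenset[SignedFeature]


def _check_signed_set(members: Iterable[SignedFeature]) -> frozenset:
    members = frozenset(SignedFeature(int(k), int(b)) for k, b in members)
    for k, b in members:
        if k < 1:
            raise ValueError(f"feature index must be >= 1, got {k}")
        if b not in (-1, 1):
            raise ValueError(f"sign must be -1 or +1, got {b}")
    return members


@dataclass(frozen=True)
class BasicInteraction:
    """One interaction term: a signed feature set, thresholds and coefficient."""

    features: frozenset  # of SignedFeature
    thresholds: dict  # feature index -> gamma in (0, 1)
    coefficient: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", _check_signed_set(self.features))
        idx = {f.index for f in self.features}
        if len(idx) != len(self.features):
            raise ValueError("both signs of one feature cannot appear in an interaction")
        if set(self.thresholds) != idx:
            raise ValueError("thresholds must be keyed by exactly the member feature indices")

    @property
    def indices(self) -> frozenset:
        return frozenset(f.index for f in self.features)

    @property
    def order(self) -> int:
        return len(self.features)

    def indicator(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the conjunction of threshold conditions row-wise on an n x p matrix."""
        out = np.ones(X.shape[0], dtype=bool)
        for k, b in self.features:
            col = X[:, k - 1]
            g = self.thresholds[k]
            out &= (col <= g) if b == -1 else (col > g)
        return out


@dataclass
class LSSModel:
    """An LSS regression model: intercept plus basic signed interactions."""

    p: int
    intercept: float = 0.0
    interactions: list = field(default_factory=list)  # of BasicInteraction
    c_beta: float = 0.0
    c_gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        for ia in self.interactions:
            if any(f.index > self.p for f in ia.features):
                raise ValueError("interaction references a feature index beyond p")

    @property
    def s(self) -> int:
        """Total number of signal features, sum_j |S_j|."""
        return sum(ia.order for ia in self.interactions)

    def basic_signed_interactions(self) -> list:
        return [ia.features for ia in self.interactions]

    def validate(self, strict: bool = True, allow_overlap: bool = False) -> None:
        """Check the model constraints; strict mode enforces the coefficient and
        threshold bounds (|beta_j| > C_beta, gamma in (C_gamma, 1 - C_gamma)) and
        non-overlapping interaction supports unless ``allow_overlap``."""
        if self.s > self.p:
            raise ValueError("total interaction order s exceeds p")
        if not strict:
            return
        seen: set = set()
        for ia in self.interactions:
            if abs(ia.coefficient) <= self.c_beta:
                raise ValueError(
                    f"|coefficient| = {abs(ia.coefficient)} must exceed C_beta = {self.c_beta}"
                )
            for k, g in ia.thresholds.items():
                if not (self.c_gamma < g < 1 - self.c_gamma):
                    raise ValueError(
                        f"threshold gamma_{k} = {g} outside ({self.c_gamma}, {1 - self.c_gamma})"
                    )
            if not allow_overlap and seen & ia.indices:
                raise ValueError(
                    f"interactions overlap on features {sorted(seen & ia.indices)}; "
                    "pass allow_overlap=True for a deliberately misspecified model"
                )
            seen |= ia.indices

    # -- serialization: JSON with 1-based indices on disk ------------------
    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "intercept": self.intercept,
            "interactions": [
                {
                    "features": sorted([f.index, f.sign] for f in ia.features),
                    "thresholds": {str(k): g for k, g in sorted(ia.thresholds.items())},
                    "coefficient": ia.coefficient,
                }
                for ia in self.interactions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSSModel":
        ias = [
            BasicInteraction(
                features=frozenset(SignedFeature(k, b) for k, b in e["features"]),
                thresholds={int(k): float(g) for k, g in e["thresholds"].items()},
                coefficient=float(e.get("coefficient", 1.0)),
            )
            for e in d.get("interactions", [])
        ]
        return cls(p=int(d["p"]), intercept=float(d.get("intercept", 0.0)), interactions=ias)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LSSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Dataset:
    """A feature matrix with aligned numeric response and generation provenance."""

    X: np.ndarray
    y: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.y.ndim != 1 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be n x p and y length n")
        if self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise ValueError("need n >= 1 and p >= 1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def save(self, path: str | Path) -> None:
        """Comma-delimited text with header x1,...,xp,y at full float precision."""
        header = ",".join([f"x{j}" for j in range(1, self.p + 1)] + ["y"])
        body = np.column_stack([self.X, self.y])
        np.savetxt(path, body, delimiter=",", header=header, comments="", fmt="%.17g")

    @classmethod
    def load(cls, path: str | Path, strict: bool = False) -> "Dataset":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        X, y = arr[:, :-1], arr[:, -1]
        if strict and (X.min() < 0 or X.max() > 1):
            raise ValueError("feature values outside [0, 1] in strict mode")
        return cls(X=X, y=y)


# ---------------------------------------------------------------------------
# operations


def regression_function(model: LSSModel, x: Sequence[float] | np.ndarray) -> float | np.ndarray:
    """Mean response at ``x``: intercept plus the active interaction coefficients.

    Accepts a single length-p vector (returns a scalar) or an n x p matrix
    (returns a length-n vector).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.p:
        raise ValueError(f"expected {model.p} features, got {X.shape[1]}")
    m = np.full(X.shape[0], model.intercept, dtype=float)
    for ia in model.interactions:
        m += ia.coefficient * ia.indicator(X)
    return float(m[0]) if single else m


def calibrate_threshold(J: int, L: int, coverage: float = 0.5) -> float:
    """Threshold tau for J disjoint order-L interactions under uniform features
    such that P(at least one interaction active) = ``coverage``.

    Each interaction activates with probability tau^L independently, so
    1 - (1 - tau^L)^J = coverage, giving the closed form below.
    """
    if J < 1 or L < 1:
        raise ValueError("J and L must be >= 1")
    if not 0 < coverage < 1:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    return float((1.0 - (1.0 - coverage) ** (1.0 / J)) ** (1.0 / L))


def calibrate_threshold_overlap(L: int, overlap: int, coverage: float = 0.5) -> float:
    """Threshold for two order-L interactions sharing ``overlap`` features.

    Coverage by inclusion-exclusion: 2 tau^L - tau^(2L - overlap); solved
    numerically on (0, 1).
    """
    if not 0 < coverage < 1:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    if not 0 <= overlap < L:
        raise ValueError("overlap must satisfy 0 <= overlap < L")
    from scipy.optimize import brentq

    f = lambda t: 2 * t**L - t ** (2 * L - overlap) - coverage
    return float(brentq(f, 1e-12, 1 - 1e-12))


def build_simulation_model(J: int, L: int, p: int, coverage: float = 0.5) -> LSSModel:
    """The benchmark LSS model: J disjoint order-L interactions on consecutive
    feature blocks (features (j-1)L+1 .. jL), all signs -1, unit coefficients,
    shared threshold calibrated so the union region has the target coverage."""
    if J * L > p:
        raise ValueError(f"J*L = {J * L} exceeds p = {p}")
    tau = calibrate_threshold(J, L, coverage)
    interactions = []
    for j in range(1, J + 1):
        ks = range((j - 1) * L + 1, j * L + 1)
        interactions.append(
            BasicInteraction(
                features=frozenset(SignedFeature(k, -1) for k in ks),
                thresholds={k: tau for k in ks},
                coefficient=1.0,
            )
        )
    return LSSModel(p=p, intercept=0.0, interactions=interactions)


def build_overlap_model(L: int, p: int, overlap: int = 1, coverage: float = 0.5) -> LSSModel:
    """Two order-L interactions whose supports share ``overlap`` features: the
    second block is shifted back by ``overlap`` (overlap=1, L=2 gives {1,2} and
    {2,3}).  Deliberately violates the non-overlap constraint."""
    second = range(L + 1 - overlap, 2 * L + 1 - overlap)
    if max(second) > p:
        raise ValueError("not enough features for the overlapping blocks")
    tau = calibrate_threshold_overlap(L, overlap, coverage)
    interactions = []
    for ks in (range(1, L + 1), second):
        interactions.append(
            BasicInteraction(
                features=frozenset(SignedFeature(k, -1) for k in ks),
                thresholds={k: tau for k in ks},
            )
        )
    return LSSModel(p=p, interactions=interactions)


def sample_features(
    n: int, p: int, corr: float = 0.0, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """n x p feature matrix with uniform [0,1] marginals.

    corr = 0 gives i.i.d. entries.  corr = alpha in (0, 1) induces AR(1)
    dependence of strength alpha^|j1-j2| through a latent-normal (Gaussian
    copula) construction: a stationary AR(1) normal vector is transformed to
    uniforms by the normal CDF, which preserves marginals exactly while the
    latent-scale correlation is exactly alpha^|j1-j2|.
    """
    if n < 1 or p < 1:
        raise ValueError("need n >= 1 and p >= 1")
    if not 0 <= corr < 1:
        raise ValueError(f"corr must be in [0, 1), got {corr}")
    rng = np.random.default_rng(seed)
    if corr == 0:
        return rng.random((n, p))
    z = np.empty((n, p))
    z[:, 0] = rng.standard_normal(n)
    innov_sd = math.sqrt(1.0 - corr**2)
    for j in range(1, p):
        z[:, j] = corr * z[:, j - 1] + innov_sd * rng.standard_normal(n)
    return stats.norm.cdf(z)


def signal_variance(
    model: LSSModel, mc_samples: int = 200_000, seed: int = 0
) -> float:
    """Variance of the regression function under uniform features.

    Disjoint interactions make the activation indicators independent
    Bernoulli(q_j) with q_j the product of per-feature activation
    probabilities, so Var = sum_j beta_j^2 q_j (1 - q_j).  Overlapping
    interactions fall back to Monte Carlo.
    """
    if not model.interactions:
        return 0.0
    supports = [ia.indices for ia in model.interactions]
    disjoint = sum(len(s) for s in supports) == len(frozenset().union(*supports))
    if disjoint:
        var = 0.0
        for ia in model.interactions:
            q = 1.0
            for k, b in ia.features:
                g = ia.thresholds[k]
                q *= g if b == -1 else 1.0 - g
            var += ia.coefficient**2 * q * (1.0 - q)
        return var
    X = sample_features(mc_samples, model.p, seed=seed)
    return float(np.var(regression_function(model, X)))


_NOISE_FAMILIES = ("gaussian", "laplace", "cauchy")


def sample_dataset(
    model: LSSModel,
    n: int,
    snr: float = 5.0,
    noise_family: str = "gaussian",
    corr: float = 0.0,
    seed: int | None = None,
) -> Dataset:
    """Draw n samples: uniform(-copula) features, mean response from the model,
    additive noise scaled to the requested signal-to-noise ratio.

    SNR is Var(E[Y|X]) / Var(noise).  Gaussian noise gets sd sigma with
    sigma^2 = signal_variance / snr; Laplace is scaled so its variance equals
    sigma^2 (scale sigma/sqrt(2)); Cauchy has no variance, so its scale is set
    to the same sigma as the Gaussian recipe — a nominal, not variance-based,
    normalization.  ``snr=inf`` (or math.inf) yields noiseless responses.
    """
    if noise_family not in _NOISE_FAMILIES:
        raise ValueError(f"noise_family must be one of {_NOISE_FAMILIES}")
    if not snr > 0:
        raise ValueError(f"snr must be > 0, got {snr}")
    rng = np.random.default_rng(seed)
    feature_seed, noise_seed = rng.spawn(2) if seed is None else (
        np.random.SeedSequence([seed, 0]),
        np.random.SeedSequence([seed, 1]),
    )
    X = sample_features(n, model.p, corr=corr, seed=np.random.default_rng(feature_seed))
    m = regression_function(model, X)
    sigma = 0.0 if math.isinf(snr) else math.sqrt(signal_variance(model) / snr)
    nrng = np.random.default_rng(noise_seed)
    if sigma == 0.0:
        noise = np.zeros(n)
    elif noise_family == "gaussian":
        noise = nrng.normal(0.0, sigma, n)
    elif noise_family == "laplace":
        noise = nrng.laplace(0.0, sigma / math.sqrt(2.0), n)
    else:  # cauchy: nominal scale only
        noise = sigma * nrng.standard_cauchy(n)
    return Dataset(
        X=X,
        y=m + noise,
        provenance={
            "noise_family": noise_family,
            "snr": snr,
            "sigma": sigma,
            "corr": corr,
            "seed": seed,
        },
    )


def union_signed_interactions(model: LSSModel, smax: int | None = None) -> list:
    """All union signed interactions of the model with size at most ``smax``.

    A union signed interaction is a nonempty union over any subset of the
    multi-feature basic signed interactions together with any subset of the
    single-feature interactions, each of the latter contributing either sign
    (the sign of a lone indicator is not identified: 1(x<=g) = 1 - 1(x>g)).
    """
    multi = [ia.features for ia in model.interactions if ia.order > 1]
    single = [next(iter(ia.features)).index for ia in model.interactions if ia.order == 1]
    out: set = set()
    for r in range(len(multi) + 1):
        for chosen in combinations(multi, r):
            base = frozenset(chain.from_iterable(chosen))
            for rs in range(len(single) + 1):
                for ks in combinations(single, rs):
                    for signs in product((-1, 1), repeat=rs):
                        u = base | frozenset(
                            SignedFeature(k, b) for k, b in zip(ks, signs)
                        )
                        if u and (smax is None or len(u) <= smax):
                            out.add(u)
    return sorted(out, key=lambda s: (len(s), sorted(s)))
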