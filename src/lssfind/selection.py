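"""LSSFind: interaction selection from a random-forest ensemble via DWP.

The algorithm trains (or accepts) a variance-impurity forest, estimates the
depth-weighted prevalence of signed feature sets from its decision paths, and
keeps the sets S with

    2^|S| * DWP_eps(S) >= 1 - eta          (strict selection rule)

among candidates of size at most smax.  Because DWP is bounded by 2^-|S| and
attains the bound asymptotically exactly for union signed interactions, the
selected maximal sets recover the basic signed interactions.  Candidate
generation prunes at the weaker, size-free level

    DWP_eps(S) >= (1 - eta) * 2^-smax      (relaxed / pruning rule)

which is what the frequent-set miner enumerates; relaxed mode reports all
such candidates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .dwp import DWPTable, extract_transactions, mine_frequent
from .forest import Forest, fit_forest
from .lss_model import Dataset, SignedFeature

__all__ = [
    "InteractionReport",
    "lssfind",
    "maximal_sets",
    "b_epsilon",
    "eta_range",
    "optimal_mtry",
]

_SLACK = 1e-12


@dataclass
class InteractionReport:
    """Mined signed sets with DWP estimates, selection decisions and the
    maximal subcollection."""

    selected: list  # of (frozenset[SignedFeature], dwp, passes_strict)
    maximal: list  # of frozenset[SignedFeature]
    params: dict = field(default_factory=dict)
    table: DWPTable | None = None

    def selected_sets(self) -> list:
        return [s for s, _, _ in self.selected]

    def to_dict(self) -> dict:
        enc = lambda s: sorted([f.index, f.sign] for f in s)
        return {
            "params": self.params,
            "selected": [
                {"features": enc(s), "dwp": d, "passes": bool(p)}
                for s, d, p in self.selected
            ],
            "maximal": [enc(s) for s in self.maximal],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "InteractionReport":
        d = json.loads(Path(path).read_text())
        dec = lambda fs: frozenset(SignedFeature(k, b) for k, b in fs)
        sel = [(dec(e["features"]), float(e["dwp"]), bool(e["passes"]))
               for e in d["selected"]]
        return cls(selected=sel, maximal=[dec(fs) for fs in d["maximal"]],
                   params=d.get("params", {}))


def maximal_sets(selected: Sequence[frozenset]) -> list:
    """Sets not strictly contained in another set of the collection."""
    sets = list(dict.fromkeys(frozenset(s) for s in selected))
    return [s for s in sets if not any(s < t for t in sets)]


def lssfind(
    data: Dataset | None = None,
    mtry: int | None = None,
    epsilon: float = 0.01,
    eta: float = 0.01,
    smax: int = 3,
    n_trees: int = 100,
    seed: int | None = None,
    mode: str = "strict",
    forest: Forest | None = None,
    min_child: int = 1,
) -> InteractionReport:
    """Run interaction selection; returns every candidate with its DWP and the
    strict-rule decision, the mode's selection, and the maximal subcollection.

    Strict mode selects candidates with 2^|S| * DWP >= 1 - eta; relaxed mode
    selects every candidate surviving the pruning level (1 - eta) * 2^-smax.
    An empty selection is a valid (empty) report.

    mtry defaults to p - 2 (near-full feature subsampling).  The prevalence
    threshold leaves interactions a relative margin of only eta below the
    ceiling 2^-|S|, so signal splits must be nearly deterministic (mtry close
    to p); at the same time each feature must be excluded from the candidate
    draw at a nonzero per-node rate, or sign-flipped singletons of strong
    features sit exactly on the ceiling and become false positives.  With no
    row resampling, leaving two features out per node provides that ensemble
    diversity.  Forests fitted for other purposes default to mtry = p/2 (see
    fit_forest).
    """
    if not 0 < eta < 1:
        raise ValueError(f"eta must be in (0, 1), got {eta}")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    if mode not in ("strict", "relaxed"):
        raise ValueError("mode must be 'strict' or 'relaxed'")
    if forest is None:
        if data is None:
            raise ValueError("provide data or a fitted forest")
        p = data.p
        if smax > p:
            raise ValueError(f"smax must be <= p = {p}")
        if mtry is None:
            mtry = max(1, p - 2)
        forest = fit_forest(data, n_trees=n_trees, mtry=mtry, seed=seed,
                            min_child=min_child)
    transactions = extract_transactions(forest, epsilon)
    min_support = (1.0 - eta) * 2.0 ** (-smax)
    table = mine_frequent(transactions, min_support, smax, epsilon=epsilon)
    rows = []
    for s, d in table.sorted_items():
        passes = 2.0 ** len(s) * d >= (1.0 - eta) - _SLACK
        rows.append((s, d, passes))
    if mode == "strict":
        selected = [(s, d, p) for s, d, p in rows if p]
    else:
        selected = rows
    report = InteractionReport(
        selected=selected,
        maximal=maximal_sets([s for s, _, _ in selected]),
        params={"mtry": forest.mtry, "epsilon": epsilon, "eta": eta, "smax": smax,
                "n_trees": forest.n_trees, "seed": seed, "mode": mode},
        table=table,
    )
    return report


# ---------------------------------------------------------------------------
# theory constants


def _check_constants(C_beta: float, C_gamma: float, s: int, C_m: float) -> None:
    if not C_beta > 0:
        raise ValueError("C_beta must be > 0")
    if not 0 < C_gamma < 0.5:
        raise ValueError("C_gamma must be in (0, 0.5)")
    if not 0 < C_m < 0.5:
        raise ValueError("C_m must be in (0, 0.5)")
    if s < 1:
        raise ValueError("s must be >= 1")


def b_epsilon(epsilon: float, C_beta: float, C_gamma: float, s: int, C_m: float) -> float:
    """The finite-sample slack constant

        b(eps) = (4 eps / (C_beta^2 C_gamma^(2s-1)))^(C_m^(2s) / ln(1/C_gamma)),

    which bounds how far below 2^-|S| the DWP of a union interaction can fall.
    Natural logarithm; strictly increasing in eps."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    _check_constants(C_beta, C_gamma, s, C_m)
    base = 4.0 * epsilon / (C_beta**2 * C_gamma ** (2 * s - 1))
    expo = C_m ** (2 * s) / math.log(1.0 / C_gamma)
    return base**expo


def eta_range(epsilon: float, C_beta: float, C_gamma: float, s: int, C_m: float) -> tuple:
    """Admissible open interval for the prevalence threshold eta,

        2^s b(eps) < eta < C_m^(s/2).

    Returns (lower, upper, nonempty); an empty range still reports both
    endpoints."""
    lower = 2.0**s * b_epsilon(epsilon, C_beta, C_gamma, s, C_m)
    upper = C_m ** (s / 2.0)
    return lower, upper, lower < upper


def optimal_mtry(p: int, s: int) -> int:
    """Feature-subsampling size minimizing the non-interaction DWP bound,

        mtry* = p * (0.5 - s / (2 (p - 2))),

    rounded to the nearest integer and clamped to [1, p].  Approaches p/2 for
    p >> s and p/3 when a third of the features carry signal."""
    if p < 3:
        raise ValueError("p must be >= 3")
    if not 0 <= s < p:
        raise ValueError("s must satisfy 0 <= s < p")
    val = p * (0.5 - s / (2.0 * (p - 2)))
    return int(min(max(math.floor(val + 0.5), 1), p))  # half-up, not banker's
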