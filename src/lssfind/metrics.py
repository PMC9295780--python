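"""Recovery scores comparing discovered signed sets against model truth.

The strict score is the Jaccard index between two collections of signed
feature sets, treating whole sets as elements — partial recovery of an
interaction earns nothing.  The relaxed score pools the unsigned feature
indices appearing anywhere in each collection and takes the Jaccard index of
the two pools, giving partial credit when the right features are found with
the wrong grouping or sign.
"""

from __future__ import annotations

from typing import Iterable

from .lss_model import SignedFeature

__all__ = ["strict_score", "relaxed_score", "score_pair"]


def _canon(collection: Iterable, sign_flip_singletons: bool) -> frozenset:
    out = set()
    for s in collection:
        s = frozenset(SignedFeature(int(k), int(b)) for k, b in s)
        if sign_flip_singletons and len(s) == 1:
            # a lone indicator's direction is not identified: 1(x<=g) = 1-1(x>g)
            (f,) = s
            s = frozenset({SignedFeature(f.index, 0)})
        out.add(s)
    return frozenset(out)


def strict_score(truth: Iterable, found: Iterable,
                 sign_flip_singletons: bool = True) -> float:
    """Jaccard index on collections of signed sets; no credit for subsets or
    wrong signs.  Singleton sets match either sign by default."""
    t = _canon(truth, sign_flip_singletons)
    f = _canon(found, sign_flip_singletons)
    if not t:
        raise ValueError("truth collection must be nonempty")
    if not f:
        return 0.0
    return len(t & f) / len(t | f)


def relaxed_score(truth: Iterable, found: Iterable) -> float:
    """Jaccard index on the pooled unsigned feature indices of each collection."""
    tpool = {SignedFeature(int(k), int(b)).index for s in truth for k, b in s}
    fpool = {SignedFeature(int(k), int(b)).index for s in found for k, b in s}
    if not tpool:
        raise ValueError("truth collection must be nonempty")
    if not fpool:
        return 0.0
    return len(tpool & fpool) / len(tpool | fpool)


def score_pair(truth: Iterable, found: Iterable,
               sign_flip_singletons: bool = True) -> tuple:
    """(strict, relaxed) scores of one comparison."""
    truth, found = list(truth), list(found)
    return (strict_score(truth, found, sign_flip_singletons),
            relaxed_score(truth, found))
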