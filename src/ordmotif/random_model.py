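"""Directed ordered random networks (Erdos-Renyi with a node order).

For each rank-ordered node pair j < i, an upward link j -> i appears
independently with probability ``p_up`` and a downward link i -> j with
``p_down``.  The pair-state probabilities are then

    P(none)  = (1 - p_up)(1 - p_down)      P(up)    = p_up (1 - p_down)
    P(down)  = p_down (1 - p_up)           P(bidir) = p_up p_down

and a 3-node configuration code, being three independent pairs, has
probability equal to the product of its three pair probabilities — a
six-factor product that only depends on the code's number of upward
factors u and downward factors d (bidirectional pairs count toward
both):

    P(code) = p_up**u (1-p_up)**(3-u) * p_down**d (1-p_down)**(3-d).

Codes sharing (u, d) form a *statistical class*: connected codes
realise every (u, d) in {0..3}^2 except (0,0), (1,0), (0,1), so generic
asymmetric parameters yield exactly 13 probability levels, while the
symmetric case p_up = p_down = p collapses to p**l (1-p)**(6-l) with
l = u + d in 2..6, i.e. five levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .catalog import Code, PairState, load_catalog
from .network import OrderedNetwork


@dataclass(frozen=True)
class RandomModelParams:
    """Parameters of the directed ordered random-network model."""

    n: int
    p_up: float
    p_down: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        _check_prob(self.p_up, "p_up")
        _check_prob(self.p_down, "p_down")


def _check_prob(p: float, name: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p}")


def pair_config_probs(p_up: float, p_down: float) -> tuple[float, float, float, float]:
    """Probabilities of the four pair states (none, down, up, bidir)."""
    _check_prob(p_up, "p_up")
    _check_prob(p_down, "p_down")
    return (
        (1 - p_up) * (1 - p_down),
        p_down * (1 - p_up),
        p_up * (1 - p_down),
        p_up * p_down,
    )


def substructure_prob(code: Code, p_up: float, p_down: float) -> float:
    """Appearance probability of a configuration code: the product of
    its three pair-state probabilities (six multipliers in total)."""
    probs = pair_config_probs(p_up, p_down)
    out = 1.0
    for state in code:
        out *= probs[int(state)]
    return out


@dataclass(frozen=True)
class AnalyticSpectrum:
    """Analytic appearance probabilities and expected counts.

    ``probs[k]`` is P_(q,s) for catalog entry k; ``expected[k]`` is
    eta_(q,s) = C(N,3) * P_(q,s).
    """

    params: RandomModelParams
    probs: np.ndarray
    expected: np.ndarray

    def distinct_levels(self, rtol: float = 1e-12) -> int:
        """Number of distinct probability values among the 54 entries.

        Values within relative tolerance ``rtol`` are grouped, since
        floating-point products of the same factor multiset can differ
        in the last ulp depending on evaluation order.
        """
        vals = np.sort(self.probs)
        levels = 1
        for prev, cur in zip(vals[:-1], vals[1:]):
            if not np.isclose(cur, prev, rtol=rtol, atol=0.0):
                levels += 1
        return levels

    def to_frame(self) -> pd.DataFrame:
        cat = load_catalog()
        return pd.DataFrame(
            {
                "class_id": [e.class_id for e in cat],
                "member_id": [e.member_id for e in cat],
                "probability": self.probs,
                "expected": self.expected,
            }
        )


def analytic_spectrum(params: RandomModelParams) -> AnalyticSpectrum:
    """Exact expected motif spectrum of the random model."""
    if params.n < 3:
        raise ValueError("analytic spectrum requires n >= 3")
    cat = load_catalog()
    probs = np.array([substructure_prob(e.code, params.p_up, params.p_down) for e in cat])
    return AnalyticSpectrum(params=params, probs=probs, expected=comb(params.n, 3) * probs)


def generate_random_network(
    params: RandomModelParams, rng: np.random.Generator | None = None
) -> OrderedNetwork:
    """Draw one realization; nodes are the integers 1..N in rank order."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n
    lo, hi = np.triu_indices(n, k=1)
    up = rng.random(lo.size) < params.p_up
    down = rng.random(lo.size) < params.p_down
    edges: set[tuple[int, int]] = set()
    for j, i, u, d in zip(lo, hi, up, down):
        if u:
            edges.add((int(j) + 1, int(i) + 1))
        if d:
            edges.add((int(i) + 1, int(j) + 1))
    return OrderedNetwork(tuple(range(1, n + 1)), frozenset(edges))


def mirror_code(code: Code) -> Code:
    """The top-down mirror of a code (reverse pair order, swap UP/DOWN)."""
    swap = {
        PairState.NONE: PairState.NONE,
        PairState.DOWN: PairState.UP,
        PairState.UP: PairState.DOWN,
        PairState.BIDIR: PairState.BIDIR,
    }
    # reversing the rank order maps pair slots (b,m),(b,t),(m,t) onto
    # (t,m),(t,b),(m,b) = slots (m,t),(b,t),(b,m) with direction flipped
    return (swap[code[2]], swap[code[1]], swap[code[0]])
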