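"""Null ensembles and Z-score significance profiles.

The significance of an observed ordered motif spectrum is judged
against an ensemble of null networks — rank-reordered copies of the
observed network, random-model draws, or niche-model webs — via the
per-substructure Z-score

    Z_(q,s) = (eta_obs - mean_null) / sd_null,

with the sample standard deviation (n - 1 denominator).  Entries whose
null sd is zero are flagged as degenerate rather than silently mapped
to 0 or infinity.  No multiple-testing correction is applied; the 54
Z-values form a profile to be read as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd

from .catalog import load_catalog
from .network import OrderedNetwork
from .spectrum import MotifSpectrum, spectrum_from_adjacency


@dataclass(frozen=True)
class SpectrumEnsemble:
    """Per-replicate spectra of an ensemble, with summary statistics.

    ``counts`` has one row per replicate and one column per catalog
    entry (catalog order).  ``extra`` carries model-specific
    per-replicate values, e.g. realized connectance.
    """

    counts: np.ndarray
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_reps(self) -> int:
        return self.counts.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        """Sample sd per entry; NaN (undefined) when n_reps < 2."""
        if self.n_reps < 2:
            return np.full(self.counts.shape[1], np.nan)
        return self.counts.std(axis=0, ddof=1)

    @property
    def sd_defined(self) -> bool:
        return self.n_reps >= 2

    def union_nonzero(self) -> int:
        """Number of substructures appearing in at least one replicate."""
        return int((self.counts.sum(axis=0) > 0).sum())

    def to_frame(self) -> pd.DataFrame:
        cat = load_catalog()
        return pd.DataFrame(
            {
                "class_id": [e.class_id for e in cat],
                "member_id": [e.member_id for e in cat],
                "mean": self.mean,
                "sd": self.sd,
                "n_reps": self.n_reps,
            }
        )


def reorder_null(
    net: OrderedNetwork,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> SpectrumEnsemble:
    """Random-reordering null: permute node ranks, topology fixed.

    Each replicate applies an independent uniform random permutation to
    the node ranks and recounts the ordered spectrum.  With
    ``exhaustive=True`` all N! rank orders are enumerated instead
    (guarded to N <= 8), giving the exact null mean and sd.
    """
    a = net.adjacency()
    n = net.n
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to N <= 8")
        perms = list(permutations(range(n)))
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]
    counts = np.empty((len(perms), len(load_catalog())), dtype=np.int64)
    for k, p in enumerate(perms):
        idx = np.asarray(p)
        counts[k] = spectrum_from_adjacency(a[np.ix_(idx, idx)]).counts
    return SpectrumEnsemble(counts=counts)


@dataclass(frozen=True)
class ZProfile:
    """Z-scores of an observed spectrum against a null ensemble."""

    observed: MotifSpectrum
    null_mean: np.ndarray
    null_sd: np.ndarray
    n_null: int

    @property
    def degenerate(self) -> np.ndarray:
        """True where the null sd is zero or undefined: no Z there."""
        return ~(self.null_sd > 0)

    @property
    def z(self) -> np.ndarray:
        """Z per entry; NaN at degenerate entries (see ``degenerate``)."""
        out = np.full(self.null_mean.shape, np.nan)
        ok = ~self.degenerate
        out[ok] = (self.observed.counts[ok] - self.null_mean[ok]) / self.null_sd[ok]
        return out

    def to_frame(self) -> pd.DataFrame:
        cat = load_catalog()
        return pd.DataFrame(
            {
                "class_id": [e.class_id for e in cat],
                "member_id": [e.member_id for e in cat],
                "eta_obs": self.observed.counts.astype(int),
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "z": self.z,
                "degenerate": self.degenerate,
            }
        )


def z_profile(
    observed: MotifSpectrum,
    null_mean: np.ndarray,
    null_sd: np.ndarray,
    n_null: int = 0,
) -> ZProfile:
    """Z-score profile from an observed spectrum and null summary."""
    null_mean = np.asarray(null_mean, dtype=float)
    null_sd = np.asarray(null_sd, dtype=float)
    k = len(load_catalog())
    if observed.counts.shape != (k,) or null_mean.shape != (k,) or null_sd.shape != (k,):
        raise ValueError("observed, null_mean and null_sd must all cover the 54 entries")
    return ZProfile(observed=observed, null_mean=null_mean, null_sd=null_sd, n_null=n_null)


def z_profile_from_ensemble(observed: MotifSpectrum, ensemble: SpectrumEnsemble) -> ZProfile:
    return z_profile(observed, ensemble.mean, ensemble.sd, n_null=ensemble.n_reps)


def exhaustive_reorder_mean(net: OrderedNetwork) -> np.ndarray:
    """Exact per-entry mean over all N! rank orders (small N only)."""
    return reorder_null(net, exhaustive=True).mean
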