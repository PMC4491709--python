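"""Model/results interface for ordered-motif significance analysis.

``OrderedMotifModel`` wraps an observed ordered network together with
a choice of null ensemble; ``fit`` counts the observed spectrum,
simulates the null, and returns an ``OrderedMotifResults`` carrying
the Z-score profile, summary table and plots.

Null ensembles
--------------
``"reorder"``
    Random rank permutations of the observed network (topology fixed).
    Tests whether the node order itself structures the network: the
    collapsed 13-class census is invariant, so any signal is purely
    hierarchical.
``"niche"``
    Niche-model webs fitted to the observed N and connectance C.
``"random"``
    Directed ordered random networks with upward / downward link
    probabilities estimated from the observed network
    (p_up = L_up / C(N,2), p_down = L_down / C(N,2)).
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd

from .catalog import load_catalog
from .network import OrderedNetwork
from .niche_model import NicheParams, ensemble_spectra
from .null_stats import (
    SpectrumEnsemble,
    ZProfile,
    reorder_null,
    z_profile_from_ensemble,
)
from .random_model import RandomModelParams, generate_random_network
from .spectrum import MotifSpectrum, count_spectrum, spectrum_from_adjacency

_NULLS = ("reorder", "niche", "random")


class OrderedMotifModel:
    """Significance model for the ordered motif spectrum of a network.

    Parameters
    ----------
    network
        The observed directed ordered network.
    null
        Null ensemble: ``"reorder"`` (default), ``"niche"`` or
        ``"random"``; see the module docstring.
    n_null
        Number of null replicates.
    """

    def __init__(self, network: OrderedNetwork, null: str = "reorder", n_null: int = 1000):
        if null not in _NULLS:
            raise ValueError(f"null must be one of {_NULLS}")
        if network.n < 3:
            raise ValueError("need at least 3 nodes for 3-node motif analysis")
        self.network = network
        self.null = null
        self.n_null = n_null

    @classmethod
    def from_edge_frame(
        cls,
        edges: pd.DataFrame,
        nodes: pd.DataFrame | None = None,
        **kwargs,
    ) -> "OrderedMotifModel":
        """Build from DataFrames: edges[source, target] in energy-flow
        direction, optional nodes[node_id, niche_value]."""
        edge_list = list(zip(edges.iloc[:, 0], edges.iloc[:, 1]))
        if nodes is None:
            net = OrderedNetwork.from_edges(edge_list)
        else:
            niche = dict(zip(nodes.iloc[:, 0], nodes.iloc[:, 1].astype(float)))
            net = OrderedNetwork.from_edges(edge_list, nodes=list(niche), niche_value=niche)
        return cls(net, **kwargs)

    def _simulate_null(self, seed: int | None) -> SpectrumEnsemble:
        net = self.network
        if self.null == "reorder":
            return reorder_null(net, n_perm=self.n_null, seed=seed)
        if self.null == "niche":
            params = NicheParams(n=net.n, c=net.connectance, seed=seed, reps=self.n_null)
            return ensemble_spectra(params)
        pairs = comb(net.n, 2)
        rank = {node: i for i, node in enumerate(net.nodes)}
        n_up = sum(1 for u, v in net.edges if rank[u] < rank[v])
        n_down = sum(1 for u, v in net.edges if rank[u] > rank[v])
        params = RandomModelParams(net.n, n_up / pairs, n_down / pairs)
        rng = np.random.default_rng(seed)
        cat = load_catalog()
        counts = np.empty((self.n_null, len(cat)), dtype=np.int64)
        for k in range(self.n_null):
            counts[k] = count_spectrum(generate_random_network(params, rng)).counts
        return SpectrumEnsemble(counts=counts)

    def fit(self, seed: int | None = None) -> "OrderedMotifResults":
        """Count the observed spectrum, simulate the null, Z-score."""
        observed = count_spectrum(self.network)
        ensemble = self._simulate_null(seed)
        profile = z_profile_from_ensemble(observed, ensemble)
        return OrderedMotifResults(self, observed, ensemble, profile, seed)


class OrderedMotifResults:
    """Fitted significance profile: observed vs null spectra."""

    def __init__(
        self,
        model: OrderedMotifModel,
        observed: MotifSpectrum,
        null_ensemble: SpectrumEnsemble,
        profile: ZProfile,
        seed: int | None,
    ):
        self.model = model
        self.observed = observed
        self.null_ensemble = null_ensemble
        self.profile = profile
        self.seed = seed

    @property
    def zscores(self) -> pd.Series:
        """Z_(q,s) indexed by (class_id, member_id); NaN = degenerate."""
        cat = load_catalog()
        idx = pd.MultiIndex.from_tuples(cat.keys, names=["class_id", "member_id"])
        return pd.Series(self.profile.z, index=idx, name="z")

    def frame(self) -> pd.DataFrame:
        return self.profile.to_frame()

    def collapsed_comparison(self) -> pd.DataFrame:
        """Observed vs null-mean unordered 13-class census."""
        cat = load_catalog()
        class_of = np.array([e.class_id for e in cat])
        null_mean = np.zeros(cat.n_classes)
        for q in range(1, cat.n_classes + 1):
            null_mean[q - 1] = self.null_ensemble.mean[class_of == q].sum()
        return pd.DataFrame(
            {"eta_obs": self.observed.collapse().values, "null_mean": null_mean},
            index=pd.RangeIndex(1, cat.n_classes + 1, name="class_id"),
        )

    def summary(self, top: int = 10) -> str:
        """Text summary: fit header plus the strongest deviations."""
        net = self.model.network
        frame = self.frame()
        shown = (
            frame[~frame["degenerate"]]
            .assign(abs_z=lambda f: f["z"].abs())
            .sort_values("abs_z", ascending=False)
            .drop(columns="abs_z")
            .head(top)
        )
        lines = [
            "Ordered motif significance profile",
            "=" * 50,
            f"nodes: {net.n}    edges: {net.n_edges}    connectance: {net.connectance:.4f}",
            f"null: {self.model.null}    replicates: {self.null_ensemble.n_reps}    seed: {self.seed}",
            f"observed substructures: {len(self.observed.nonzero_keys())} of {len(load_catalog())}",
            f"degenerate entries (null sd = 0): {int(self.profile.degenerate.sum())}",
            "-" * 50,
            f"top |Z| deviations (of {int((~frame['degenerate']).sum())} scored entries):",
            shown.to_string(index=False, float_format=lambda x: f"{x:.3f}"),
        ]
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Observed and null spectra on a log scale, by (q, s)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        x = np.arange(len(self.observed.counts))
        ax.scatter(x, np.where(self.observed.counts > 0, self.observed.counts, np.nan),
                   marker="o", facecolors="none", edgecolors="k", label="observed")
        mean = self.null_ensemble.mean
        ax.scatter(x, np.where(mean > 0, mean, np.nan), marker=".", color="0.4",
                   label="null mean")
        ax.set_yscale("log")
        cat = load_catalog()
        ax.set_xticks(x)
        ax.set_xticklabels([e.label for e in cat], rotation=90, fontsize=6)
        ax.set_ylabel(r"$\eta_{(q,s)}$")
        ax.legend()
        return ax
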