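"""Stage 1: within-sample Gaussian mixture clustering with held-out BIC.

Each gated sample is reduced to at most 10,000 randomly selected events,
split 80:20 into train/test, and fitted with full-covariance Gaussian
mixtures for every candidate component count k up to a cap that depends on
the culture type (single-reporter monocultures 1-2 clusters, the
dual-reporter B. vulgatus up to 4, co-cultures up to 10, sterile controls
exactly 1). The winning k minimizes the Bayesian Information Criterion
evaluated on the held-out split; the mixture is then refitted with that k on
all sampled events. Note the BIC sign convention: with BIC defined as
p·ln n − 2·ln L̂, a better fit has a *smaller* value, so selection minimizes
it; the full trace is returned so either reading can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .events import CHANNELS, EventTable, SampleMeta

DEFAULT_SUBSAMPLE = 10_000
DEFAULT_SPLIT = 0.8
MIN_EVENTS_TO_CLUSTER = 50
STERILE_MIN_EVENTS = 100
REG_COVAR = 1e-6
N_RESTARTS = 5


class TooFewEventsError(ValueError):
    """Sample has too few events to cluster; caller should skip it."""


@dataclass(frozen=True)
class Cluster:
    """One mixture component: 5-D mean, covariance, and event-share weight."""

    mean: np.ndarray
    cov: np.ndarray
    weight: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0 + 1e-12:
            raise ValueError(f"cluster weight {self.weight} outside [0, 1]")
        if self.cov.shape != (len(CHANNELS), len(CHANNELS)):
            raise ValueError("covariance must be 5x5")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


@dataclass
class ClusterSet:
    """The Gaussian mixture description of one sample."""

    clusters: list[Cluster]
    sample_id: str = ""
    bic_by_k: dict[int, float] = field(default_factory=dict)
    n_events_used: int = 0
    below_detection: bool = False
    model: GaussianMixture | None = None  # retained for responsibilities; not serialized

    @property
    def k(self) -> int:
        return len(self.clusters)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.clusters])

    def __post_init__(self) -> None:
        if self.clusters:
            total = float(self.weights.sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"cluster weights sum to {total}, not 1")

    def responsibilities(self, events: EventTable) -> np.ndarray:
        """Posterior component memberships for the given events."""
        if self.model is None:
            raise ValueError("ClusterSet carries no fitted model")
        return self.model.predict_proba(events.channel_matrix())[:, self._order]


#: Optimal-k caps by culture type.
DEFAULT_CAPS = {
    "mono:Bo": 2, "mono:Bf": 2, "mono:Bt": 2, "mono:Bv": 4,
    "co": 10, "sterile": 1,
}


@dataclass(frozen=True)
class ClusterConfig:
    subsample_n: int = DEFAULT_SUBSAMPLE
    split: float = DEFAULT_SPLIT
    min_events: int = MIN_EVENTS_TO_CLUSTER
    sterile_min_events: int = STERILE_MIN_EVENTS
    n_restarts: int = N_RESTARTS
    reg_covar: float = REG_COVAR
    asinh_cofactor: float | None = None  # optional display-scale transform, off by default


def _transform(x: np.ndarray, cfg: ClusterConfig) -> np.ndarray:
    if cfg.asinh_cofactor:
        return np.arcsinh(x / cfg.asinh_cofactor)
    return x


def subsample_events(table: EventTable, n: int = DEFAULT_SUBSAMPLE,
                     seed: int = 0) -> EventTable:
    """Sample min(n, available) events without replacement, reproducibly."""
    if n <= 0:
        raise ValueError("subsample size must be positive")
    if table.n_events == 0:
        raise TooFewEventsError(f"sample {table.sample_id!r} is empty")
    if table.n_events <= n:
        return table
    rng = np.random.default_rng(seed)
    idx = rng.choice(table.n_events, size=n, replace=False)
    return table.take(np.sort(idx))


def _fit_gmm(x: np.ndarray, k: int, seed: int, cfg: ClusterConfig) -> GaussianMixture:
    gm = GaussianMixture(
        n_components=k, covariance_type="full", reg_covar=cfg.reg_covar,
        n_init=cfg.n_restarts, random_state=seed, max_iter=200,
    )
    gm.fit(x)
    return gm


def select_k(events: EventTable, k_max: int, split: float = DEFAULT_SPLIT,
             seed: int = 0, cfg: ClusterConfig = ClusterConfig()) -> tuple[int, dict[int, float]]:
    """Choose the component count by held-out BIC.

    Fits k = 1..k_max on the training split and scores standard BIC on the
    test split (test-set n in the penalty); returns the minimizing k and the
    full trace. Ties break toward the smaller k.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x = _transform(events.channel_matrix(), cfg)
    if len(x) < cfg.min_events:
        raise TooFewEventsError(
            f"sample {events.sample_id!r} has {len(x)} events "
            f"(< {cfg.min_events}); skip it"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(x))
    n_train = max(int(round(split * len(x))), 2)
    train, test = x[perm[:n_train]], x[perm[n_train:]]
    if len(test) < 2:  # degenerate split; score on train
        test = train

    trace: dict[int, float] = {}
    for k in range(1, k_max + 1):
        if k > len(train):
            break
        gm = _fit_gmm(train, k, seed, cfg)
        trace[k] = float(gm.bic(test))
    k_best = min(trace, key=lambda k: (trace[k], k))
    return k_best, trace


def fit_clusters(events: EventTable, k: int, seed: int = 0,
                 cfg: ClusterConfig = ClusterConfig()) -> ClusterSet:
    """Fit the final k-component mixture on all sampled events.

    Clusters come back sorted by descending weight; ridge regularization on
    the covariance diagonal guards against singular fits.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = _transform(events.channel_matrix(), cfg)
    if len(x) == 0:
        raise TooFewEventsError(f"sample {events.sample_id!r} is empty")
    gm = _fit_gmm(x, k, seed, cfg)
    order = np.argsort(-gm.weights_)
    weights = gm.weights_[order] / gm.weights_[order].sum()
    clusters = [
        Cluster(mean=gm.means_[j].copy(), cov=gm.covariances_[j].copy(),
                weight=float(w), sample_id=events.sample_id)
        for j, w in zip(order, weights)
    ]
    cs = ClusterSet(clusters=clusters, sample_id=events.sample_id,
                    n_events_used=len(x), model=gm)
    cs._order = order  # component order used when exposing responsibilities
    return cs


def cluster_sample(table: EventTable, meta: SampleMeta,
                   caps: dict[str, int] = DEFAULT_CAPS,
                   cfg: ClusterConfig = ClusterConfig(),
                   seed: int = 0) -> ClusterSet:
    """Full Stage-1 treatment of one gated sample.

    Subsample -> select k under the culture-type cap -> refit on all sampled
    events. Sterile controls with >= 100 events are fitted with exactly one
    cluster; sterile controls below that (and any sample under the general
    minimum) yield an empty ClusterSet flagged below detection.
    """
    k_max = caps.get(meta.culture_type)
    if k_max is None:
        raise KeyError(f"no cluster cap for culture type {meta.culture_type!r}")

    if meta.culture_type == "sterile":
        if table.n_events < cfg.sterile_min_events:
            return ClusterSet(clusters=[], sample_id=table.sample_id,
                              below_detection=True)
        sub = subsample_events(table, cfg.subsample_n, seed)
        cs = fit_clusters(sub, 1, seed=seed, cfg=cfg)
        cs.bic_by_k = {1: float("nan")}
        return cs

    if table.n_events < cfg.min_events:
        return ClusterSet(clusters=[], sample_id=table.sample_id,
                          below_detection=True)
    sub = subsample_events(table, cfg.subsample_n, seed)
    k_best, trace = select_k(sub, k_max, split=cfg.split, seed=seed, cfg=cfg)
    cs = fit_clusters(sub, k_best, seed=seed, cfg=cfg)
    cs.bic_by_k = trace
    return cs


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def clusterset_to_dict(cs: ClusterSet) -> dict:
    return {
        "sample_id": cs.sample_id,
        "k": cs.k,
        "n_events_used": cs.n_events_used,
        "below_detection": cs.below_detection,
        "bic_by_k": {str(k): v for k, v in cs.bic_by_k.items()},
        "clusters": [
            {"mean": c.mean.tolist(), "cov": c.cov.ravel().tolist(),
             "weight": c.weight}
            for c in cs.clusters
        ],
    }


def clusterset_from_dict(d: dict) -> ClusterSet:
    p = len(CHANNELS)
    clusters = [
        Cluster(mean=np.asarray(c["mean"], dtype=float),
                cov=np.asarray(c["cov"], dtype=float).reshape(p, p),
                weight=float(c["weight"]), sample_id=d["sample_id"])
        for c in d["clusters"]
    ]
    return ClusterSet(clusters=clusters, sample_id=d["sample_id"],
                      bic_by_k={int(k): float(v) for k, v in d["bic_by_k"].items()},
                      n_events_used=int(d["n_events_used"]),
                      below_detection=bool(d["below_detection"]))
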