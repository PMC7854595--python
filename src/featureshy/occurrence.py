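"""Per-bin Bayesian occurrence probabilities from binned cumulative distance counts.

The occurrence model treats the cumulative count of locations within distance
``i`` of a feature as binomial, ``y_i ~ Binomial(n, pi_i)``, with a flat
Beta(1, 1) prior on each ``pi_i``.  Posteriors are therefore conjugate,
``pi_i | y_i ~ Beta(y_i + 1, n - y_i + 1)``, and are sampled directly; a
random-walk Metropolis sampler on the logit scale is provided as an
independent cross-check of the conjugate draws.

Each bin is modelled independently, mirroring the construction of the source
method: cumulative counts are dependent across bins, so the per-bin posteriors
are a deliberate (and documented) simplification rather than a joint model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinnedCumulativeCounts",
    "OccurrenceCurve",
    "bin_cumulative",
    "binomial_posterior",
    "binomial_posterior_mcmc",
    "hdi",
]


@dataclass(frozen=True)
class BinnedCumulativeCounts:
    """Cumulative occurrence counts per distance bin.

    ``y[i]`` is the number of locations at distance <= ``bin_upper_edges[i]``
    from the feature; ``n`` is the total number of locations (including any
    beyond the last edge).
    """

    bin_width_m: float
    bin_upper_edges: np.ndarray
    y: np.ndarray
    n: int
    role: str = ""

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_upper_edges, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if edges.ndim != 1 or y.shape != edges.shape:
            raise ValueError("edges and counts must be 1-d arrays of equal length")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(np.diff(y) < 0):
            raise ValueError("cumulative counts must be non-decreasing")
        if y.size and (y[0] < 0 or y[-1] > self.n):
            raise ValueError("counts must satisfy 0 <= y_i <= n")
        object.__setattr__(self, "bin_upper_edges", edges)
        object.__setattr__(self, "y", y)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_upper_edges - self.bin_width_m / 2.0


@dataclass
class OccurrenceCurve:
    """Posterior draws of the per-bin occurrence probabilities pi_i."""

    counts: BinnedCumulativeCounts
    draws: np.ndarray  # shape (n_draws, n_bins), values in [0, 1]
    hdi_mass: float = 0.95
    median: np.ndarray = field(init=False)
    hdi_low: np.ndarray = field(init=False)
    hdi_high: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.median = np.median(self.draws, axis=0)
        bounds = np.array([hdi(col, self.hdi_mass) for col in self.draws.T])
        self.hdi_low = bounds[:, 0]
        self.hdi_high = bounds[:, 1]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def bin_upper_edges(self) -> np.ndarray:
        return self.counts.bin_upper_edges


def bin_cumulative(
    distances,
    bin_width: float,
    max_distance: float,
    role: str = "",
) -> BinnedCumulativeCounts:
    """Bin distances into cumulative counts at edges bin_width, 2*bin_width, ...

    ``n`` is the total number of distances; locations beyond ``max_distance``
    contribute to ``n`` but to no bin.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances to bin")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    n_bins = int(np.ceil(max_distance / bin_width - 1e-9))
    if n_bins < 1:
        raise ValueError("max_distance must cover at least one bin")
    edges = bin_width * np.arange(1, n_bins + 1)
    y = np.searchsorted(np.sort(d), edges, side="right")
    return BinnedCumulativeCounts(
        bin_width_m=float(bin_width),
        bin_upper_edges=edges,
        y=y,
        n=int(d.size),
        role=role,
    )


def binomial_posterior(
    counts: BinnedCumulativeCounts,
    n_draws: int = 10_000,
    seed=None,
    hdi_mass: float = 0.95,
) -> OccurrenceCurve:
    """Conjugate posterior draws, pi_i | y_i ~ Beta(y_i + 1, n - y_i + 1)."""
    if counts.n == 0:
        raise ValueError("cannot form a posterior from zero locations")
    rng = np.random.default_rng(seed)
    a = counts.y + 1.0
    b = counts.n - counts.y + 1.0
    draws = rng.beta(a[None, :], b[None, :], size=(n_draws, counts.y.size))
    return OccurrenceCurve(counts=counts, draws=draws, hdi_mass=hdi_mass)


def binomial_posterior_mcmc(
    counts: BinnedCumulativeCounts,
    n_draws: int = 10_000,
    seed=None,
    thin: int = 10,
    burn: int = 1_000,
    hdi_mass: float = 0.95,
) -> OccurrenceCurve:
    """Random-walk Metropolis sampler for the same binomial model.

    Works on the logit scale with the Beta(1, 1) prior mapped through the
    Jacobian.  Exists as an independent route to the conjugate draws; total
    iterations stay well below 1e5 per bin at the defaults.
    """
    if counts.n == 0:
        raise ValueError("cannot form a posterior from zero locations")
    rng = np.random.default_rng(seed)
    y = counts.y.astype(float)
    n = float(counts.n)
    k = y.size

    def logpost(theta):  # theta: logit(pi), prior Beta(1,1) => density sigmoid'(theta)
        # log p = y*theta - n*log(1+e^theta) + log Jacobian(Beta(1,1))
        return (y + 1.0) * theta - (n + 2.0) * np.logaddexp(0.0, theta)

    theta = np.log((y + 1.0) / (n - y + 1.0))
    lp = logpost(theta)
    # per-bin proposal scale ~ posterior sd on logit scale
    p_hat = (y + 1.0) / (n + 2.0)
    step = 2.4 / np.sqrt(np.maximum((n + 2.0) * p_hat * (1.0 - p_hat), 1.0))
    total = burn + n_draws * thin
    out = np.empty((n_draws, k))
    j = 0
    for i in range(total):
        prop = theta + step * rng.standard_normal(k)
        lp_prop = logpost(prop)
        accept = np.log(rng.random(k)) < lp_prop - lp
        theta = np.where(accept, prop, theta)
        lp = np.where(accept, lp_prop, lp)
        if i >= burn and (i - burn) % thin == thin - 1:
            out[j] = 1.0 / (1.0 + np.exp(-theta))
            j += 1
    return OccurrenceCurve(counts=counts, draws=out[:j], hdi_mass=hdi_mass)


def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws (sliding window)."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])
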