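"""Population simulation of resultant histograms.

A population of model neurons is generated by drawing the elongation
``kappa = sigma2 / sigma1`` from a uniform distribution of ``K = log kappa``
over ``[-log kappa_max, log kappa_max]`` (i.e. log-uniform kappa on
``[1/kappa_max, kappa_max]``, default ``kappa_max = 8``), computing the
resultant modulus |R| of each cell's tuning curve, and binning into 10
equal-width bins on [0, 1].  Per-order histograms can be combined with equal
neuron counts per order to emulate mixed simple-cell populations (orders up
to 2 versus up to 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IncompatibleHistogramError, InvalidParameterError
from .resultant import resultant_closed_form

__all__ = [
    "PopulationSpec",
    "RHistogram",
    "sample_kappa",
    "simulate_histograms",
    "combine_orders",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Study conditions of the population simulation."""

    kappa_max: float = 8.0
    n_per_class: int = 10_000
    orders: tuple[int, ...] = (1, 2, 3, 4)
    include_complex: bool = True
    sampling: str = "grid"
    seed: int | None = None
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.kappa_max <= 1:
            raise InvalidParameterError("kappa_max must exceed 1")
        if self.n_per_class < 1:
            raise InvalidParameterError("n_per_class must be at least 1")
        if self.sampling not in ("grid", "random"):
            raise InvalidParameterError("sampling must be 'grid' or 'random'")
        if self.n_bins < 1:
            raise InvalidParameterError("n_bins must be at least 1")
        if not set(self.orders) <= {1, 2, 3, 4}:
            raise InvalidParameterError("orders must be a subset of {1,2,3,4}")


@dataclass
class RHistogram:
    """Binned counts of the resultant modulus over [0, 1] for one cell class."""

    edges: np.ndarray
    counts: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.edges) != len(self.counts) + 1:
            raise InvalidParameterError("edges must be one longer than counts")
        if np.any(self.counts < 0):
            raise InvalidParameterError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def sample_kappa(spec: PopulationSpec) -> np.ndarray:
    """Elongation samples with log-uniform law on [1/kappa_max, kappa_max].

    Grid mode: equally spaced values of K = log kappa including both
    endpoints.  Random mode: i.i.d. uniform K under the spec's seed.
    """
    k_max = np.log(spec.kappa_max)
    if spec.sampling == "grid":
        if spec.n_per_class < 2:
            raise InvalidParameterError("grid sampling requires n_per_class >= 2")
        big_k = np.linspace(-k_max, k_max, spec.n_per_class)
    else:
        rng = np.random.default_rng(spec.seed)
        big_k = rng.uniform(-k_max, k_max, size=spec.n_per_class)
    return np.exp(big_k)


def _bin(values: np.ndarray, n_bins: int, label: str) -> RHistogram:
    # equal-width bins on [0, 1], right-open except the last (numpy convention)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return RHistogram(edges=edges, counts=counts, label=label)


def simulate_histograms(spec: PopulationSpec) -> dict[str, RHistogram]:
    """Resultant histograms per cell class (simple orders and complex cells).

    Each class receives its own kappa sample (identical in grid mode); |R| is
    evaluated by the closed forms (hypergeometric route for the complex class,
    which is cross-validated against quadrature in the test suite).
    """
    hists: dict[str, RHistogram] = {}
    for order in spec.orders:
        kappas = sample_kappa(spec)
        mod = resultant_closed_form("simple", kappas, order=order)
        hists[f"simple_{order}"] = _bin(mod, spec.n_bins, f"simple_{order}")
    if spec.include_complex:
        kappas = sample_kappa(spec)
        mod = resultant_closed_form("complex", kappas, use_hypergeometric=True)
        hists["complex"] = _bin(mod, spec.n_bins, "complex")
    return hists


def combine_orders(spec: PopulationSpec, max_order: int = 4,
                   hists: dict[str, RHistogram] | None = None) -> RHistogram:
    """Equal-weight combination of simple-cell histograms up to ``max_order``.

    Assumes the same number of neurons per order; counts are summed bin-wise.
    """
    if max_order not in (2, 4):
        raise InvalidParameterError("max_order must be 2 or 4")
    orders = [o for o in spec.orders if o <= max_order]
    if not orders:
        raise InvalidParameterError("no simple-cell orders to combine")
    if hists is None:
        hists = simulate_histograms(spec)
    members = [hists[f"simple_{o}"] for o in orders]
    totals = {h.total for h in members}
    if len(totals) != 1:
        raise IncompatibleHistogramError("orders must have equal neuron counts")
    edges = members[0].edges
    for h in members[1:]:
        if not np.array_equal(h.edges, edges):
            raise IncompatibleHistogramError("histogram bin edges differ")
    counts = np.sum([h.counts for h in members], axis=0)
    return RHistogram(edges=edges, counts=counts,
                      label=f"simple_up_to_{max_order}")
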