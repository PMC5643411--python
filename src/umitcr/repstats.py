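"""Repertoire-level statistics: clone-size spectra, discrete power-law
maximum likelihood, diversity indices, fixed-depth subsampling, overlap
filtering and annotated-CDR3 search.

Clone-size distributions of T cell repertoires are heavy-tailed and well
described by a discrete power law f(x) = a x^(-b) above a lower cutoff
x_min.  The exponent b is estimated by maximum likelihood on the tail
(the zeta-normalized discrete model); when x_min is not given it is chosen
by minimizing the Kolmogorov-Smirnov distance between the empirical tail
and the fitted model, the standard operational reading of fitting "within
the linear range" of a log-log spectrum.

Diversity indices are computed on clone-size multisets: the Gini
coefficient (inequality; 0 = perfectly even), Shannon entropy (natural log
by default) and the inverse Simpson index (effective clone number).
Because all three depend on sample size, repertoires are compared after
subsampling to a fixed number of UMI-defined molecules.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .decombine import TcrIdentifier
from .collapse import read_freq


@dataclass(frozen=True)
class AbundanceDistribution:
    """Multiset of clone sizes (UMI-defined molecule counts, all >= 1)."""

    sizes: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=np.int64)
        object.__setattr__(self, "sizes", sizes)
        if sizes.size and sizes.min() < 1:
            raise ValueError("clone sizes must be >= 1")

    @classmethod
    def from_sizes(cls, sizes: Iterable[int]) -> "AbundanceDistribution":
        return cls(np.asarray(list(sizes), dtype=np.int64))

    @classmethod
    def from_freq_file(cls, path: str | Path) -> "AbundanceDistribution":
        return cls.from_sizes(abundance for _, abundance in read_freq(path))

    @property
    def n_clones(self) -> int:
        return int(self.sizes.size)

    @property
    def n_molecules(self) -> int:
        return int(self.sizes.sum())

    def _require_nonempty(self) -> None:
        if self.sizes.size == 0:
            raise ValueError("empty abundance distribution")


def size_spectrum(d: AbundanceDistribution) -> pd.DataFrame:
    """Proportion of clonotypes occurring once, twice, etc.

    Columns: ``abundance``, ``proportion`` (proportions sum to 1).
    """
    d._require_nonempty()
    values, counts = np.unique(d.sizes, return_counts=True)
    return pd.DataFrame(
        {"abundance": values, "proportion": counts / d.n_clones}
    )


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float  # b in f(x) = a x^-b
    x_min: int
    n_tail: int
    ks_distance: float


def _discrete_ks(tail: np.ndarray, alpha: float, x_min: int) -> float:
    """KS distance between the empirical tail and the zeta power law."""
    values = np.arange(x_min, tail.max() + 1)
    z = special.zeta(alpha, x_min)
    model_cdf = np.cumsum(values.astype(float) ** -alpha) / z
    ecdf = np.searchsorted(np.sort(tail), values, side="right") / tail.size
    return float(np.abs(ecdf - model_cdf).max())


def _fit_exact(tail: np.ndarray, x_min: int) -> float:
    """Exact discrete MLE: minimize the zeta-normalized negative
    log-likelihood in the exponent."""
    mean_log = float(np.log(tail).mean())

    def nll(alpha: float) -> float:
        return alpha * mean_log + np.log(special.zeta(alpha, x_min))

    res = optimize.minimize_scalar(nll, bounds=(1.000001, 25.0), method="bounded")
    return float(res.x)


def _fit_approx(tail: np.ndarray, x_min: int) -> float:
    """Closed-form (Hill-type) approximation 1 + n / sum ln(x/(x_min-1/2)).

    Accurate for large x_min; biased for x_min near 1, where the exact MLE
    should be preferred.
    """
    log_sum = float(np.log(tail / (x_min - 0.5)).sum())
    if log_sum == 0.0:
        raise ValueError("degenerate tail")
    return 1.0 + tail.size / log_sum


def fit_power_law(
    d: AbundanceDistribution,
    x_min: int | None = None,
    method: str = "exact",
) -> PowerLawFit:
    """Fit a discrete power law to the clone-size tail by maximum likelihood.

    With ``x_min=None`` the cutoff is selected by KS minimization over the
    distinct sizes up to the 95th percentile (ties to the smaller cutoff).
    ``method="exact"`` maximizes the zeta likelihood numerically;
    ``method="approx"`` uses the closed-form estimator.
    """
    d._require_nonempty()
    if method not in ("exact", "approx"):
        raise ValueError(f"unknown method {method!r}")

    def fit_at(xm: int) -> PowerLawFit:
        tail = d.sizes[d.sizes >= xm]
        if tail.size < 2:
            raise ValueError(f"fewer than 2 observations >= x_min={xm}")
        if np.all(tail == xm):
            raise ValueError("degenerate tail")
        alpha = _fit_exact(tail, xm) if method == "exact" else _fit_approx(tail, xm)
        return PowerLawFit(alpha, xm, int(tail.size), _discrete_ks(tail, alpha, xm))

    if x_min is not None:
        return fit_at(int(x_min))
    cutoff = np.percentile(d.sizes, 95)
    candidates = [int(v) for v in np.unique(d.sizes) if v <= cutoff]
    if not candidates:
        candidates = [int(d.sizes.min())]
    best: PowerLawFit | None = None
    for xm in candidates:
        try:
            fit = fit_at(xm)
        except ValueError:
            continue
        if best is None or fit.ks_distance < best.ks_distance:
            best = fit
    if best is None:
        raise ValueError("no admissible x_min candidate")
    return best


def sample_power_law(
    b: float, n: int, rng: np.random.Generator | int | None = None
) -> AbundanceDistribution:
    """Draw n clone sizes from the discrete power law with x_min = 1 (the
    zeta/Zipf distribution); the matched oracle for the estimator."""
    rng = np.random.default_rng(rng)
    return AbundanceDistribution(stats.zipf.rvs(b, size=n, random_state=rng))


def gini(d: AbundanceDistribution) -> float:
    """Gini coefficient of clone sizes: mean absolute size difference over
    twice the mean size; 0 for a perfectly even repertoire."""
    d._require_nonempty()
    x = np.sort(d.sizes).astype(float)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float(((2 * ranks - n - 1) * x).sum() / (n * n * x.mean()))


def shannon_entropy(d: AbundanceDistribution, base: str = "nats") -> float:
    """Shannon entropy of clone frequencies (natural log by default;
    ``base="bits"`` for log2)."""
    d._require_nonempty()
    p = d.sizes / d.n_molecules
    h = float(-(p * np.log(p)).sum())
    return h / np.log(2) if base == "bits" else h


def inverse_simpson(d: AbundanceDistribution) -> float:
    """Inverse Simpson index 1 / sum p_i^2: the effective clone number."""
    d._require_nonempty()
    p = d.sizes / d.n_molecules
    return float(1.0 / (p * p).sum())


def subsample(
    d: AbundanceDistribution,
    m: int,
    rng: np.random.Generator | int | None = 0,
) -> AbundanceDistribution:
    """Sample m molecules uniformly without replacement from the repertoire.

    Clones drawn zero times are absent from the result, whose molecule
    count is exactly m.
    """
    d._require_nonempty()
    if m > d.n_molecules:
        raise ValueError(f"cannot subsample {m} from {d.n_molecules} molecules")
    rng = np.random.default_rng(rng)
    molecules = np.repeat(np.arange(d.n_clones), d.sizes)
    drawn = rng.choice(molecules, size=m, replace=False)
    sizes = np.bincount(drawn, minlength=d.n_clones)
    return AbundanceDistribution(sizes[sizes > 0])


ClonotypeKey = TcrIdentifier | str


def remove_shared(
    naive: Mapping[ClonotypeKey, int],
    memory_sets: Sequence[Iterable[ClonotypeKey]],
) -> dict[ClonotypeKey, int]:
    """Drop from a naive repertoire every clonotype present in any memory
    subpopulation of the same donor; surviving abundances are unchanged.

    Clonotypes may be keyed by five-part identifier (nucleotide level) or
    by CDR3 amino-acid string.
    """
    shared: set[ClonotypeKey] = set()
    for mem in memory_sets:
        shared.update(mem)
    return {k: v for k, v in naive.items() if k not in shared}


def search_annotated_cdr3(
    repertoires: Mapping[str, Mapping[str, int]],
    query_cdr3s: Sequence[str],
) -> pd.DataFrame:
    """Abundance of each query CDR3 (rows) in each repertoire (columns).

    Entries are summed frequencies of exact amino-acid matches, 0 when
    absent.  Use ``top_k_queries`` to trim for reporting.
    """
    data = {
        name: [rep.get(q, 0) for q in query_cdr3s]
        for name, rep in repertoires.items()
    }
    return pd.DataFrame(data, index=list(query_cdr3s))


def top_k_queries(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k query rows with the highest row maximum (for heatmap-style
    reporting of the most abundant annotated CDR3s)."""
    order = matrix.max(axis=1).sort_values(ascending=False, kind="stable")
    return matrix.loc[order.index[:k]]
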