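"""Poisson encapsulation model and sorting-performance metrics.

When cells are encapsulated randomly into droplets, the number of cells
per droplet follows a Poisson law with mean

    lambda = CC [cells/mL] * V [mL]

where CC is the input cell concentration and V the droplet volume.  The
probability that the next droplet holds k cells is P(k) = e^-lambda
lambda^k / k!, so single-cell occupancy peaks at lambda = 1 where 36.8%
of droplets carry exactly one cell.

Sorting performance is summarised by four ratios over confusion counts
(true/false positives and negatives at the two outlets):

    efficiency = N_x_k / N_xbar_i   targets kept per target detected
    purity     = N_x_k / N_k        targets per keep-outlet droplet
    yield      = N_x_k / N_x_i      targets kept per target at input
    enrichment = (N_x_k/N_o_k) / (N_x_i/N_o_i)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps


# ---------------------------------------------------------------------------
# Poisson loading
# ---------------------------------------------------------------------------

def poisson_pk(lam: float, k: int) -> float:
    """Probability of encapsulating exactly ``k`` cells in a droplet.

    Evaluated in log-space so it stays finite and accurate for large k.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    return float(_sps.poisson.pmf(int(k), lam))


def encapsulation_rate(cc_cells_per_ml: float, volume_pl: float) -> float:
    """Mean cells per droplet, lambda = CC * V (volume given in pL)."""
    if cc_cells_per_ml < 0 or volume_pl <= 0:
        raise ValueError("concentration must be >= 0 and volume > 0")
    return cc_cells_per_ml * volume_pl * 1e-9  # 1 pL = 1e-9 mL


def concentration_for_rate(lam: float, volume_pl: float) -> float:
    """Inverse of :func:`encapsulation_rate`: CC [cells/mL] for a target lambda."""
    if lam < 0 or volume_pl <= 0:
        raise ValueError("lambda must be >= 0 and volume > 0")
    return lam / (volume_pl * 1e-9)


def estimate_lambda(cell_counts) -> tuple[float, float]:
    """Maximum-likelihood estimate of lambda from observed per-droplet counts.

    Returns
    -------
    (lam_hat, se) : the sample mean and its standard error sqrt(mean/n).
    """
    counts = np.asarray(cell_counts)
    if counts.size == 0:
        raise ValueError("empty cell-count sequence")
    if np.any(counts < 0):
        raise ValueError("cell counts must be non-negative")
    lam = float(counts.mean())
    se = math.sqrt(lam / counts.size)
    return lam, se


def expected_targets(n_droplets: int, lam: float) -> float:
    """Expected number of single-cell droplets among ``n_droplets``: n * P(1)."""
    if n_droplets < 0:
        raise ValueError("n_droplets must be non-negative")
    return n_droplets * poisson_pk(lam, 1)


@dataclass
class LoadingModel:
    """Cell concentration + droplet volume -> mean cells per droplet."""

    cc_cells_per_ml: float
    volume_pl: float

    @property
    def lam(self) -> float:
        return encapsulation_rate(self.cc_cells_per_ml, self.volume_pl)

    def pmf(self, k: int) -> float:
        return poisson_pk(self.lam, k)


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """The droplet counts feeding the four sorting metrics.

    ``targets`` are droplets satisfying the sort objective (e.g. holding a
    single cell); ``others`` are everything else.  ``targets_detected`` is
    how many targets the imaging algorithm flagged, which bounds what the
    sorter could possibly capture.
    """

    targets_in: int        # N_x_i
    others_in: int         # N_o_i
    targets_detected: int  # N_xbar_i
    targets_keep: int      # N_x_k  (true positives)
    targets_waste: int     # N_x_w  (false negatives)
    others_keep: int       # N_o_k  (false positives)
    others_waste: int      # N_o_w  (true negatives)

    def __post_init__(self) -> None:
        for name in ("targets_in", "others_in", "targets_detected",
                     "targets_keep", "targets_waste", "others_keep",
                     "others_waste"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_in(self) -> int:
        return self.targets_in + self.others_in

    @property
    def n_keep(self) -> int:
        return self.targets_keep + self.others_keep

    @property
    def n_waste(self) -> int:
        return self.targets_waste + self.others_waste


@dataclass
class SortingMetrics:
    efficiency: float
    purity: float
    sort_yield: float
    enrichment: float
    undefined: set = field(default_factory=set)

    def as_dict(self) -> dict:
        return {
            "efficiency": self.efficiency,
            "purity": self.purity,
            "yield": self.sort_yield,
            "enrichment": self.enrichment,
            "undefined": sorted(self.undefined),
        }


def _ratio(num: float, den: float, name: str, undefined: set) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> SortingMetrics:
    """Efficiency, purity, yield and enrichment from confusion counts.

    A zero denominator yields NaN and flags the metric in ``undefined``
    rather than raising, so batch reports never abort on an empty outlet.
    """
    und: set = set()
    eff = _ratio(c.targets_keep, c.targets_detected, "efficiency", und)
    pur = _ratio(c.targets_keep, c.n_keep, "purity", und)
    yld = _ratio(c.targets_keep, c.targets_in, "yield", und)
    if c.others_keep == 0 or c.others_in == 0 or c.targets_in == 0:
        und.add("enrichment")
        enr = float("nan")
    else:
        enr = (c.targets_keep / c.others_keep) / (c.targets_in / c.others_in)
    return SortingMetrics(eff, pur, yld, enr, und)


def bootstrap_enrichment(target_flags, keep_flags, n_boot: int = 1000,
                         seed: int = 0, alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI for enrichment, resampling droplets.

    ``target_flags`` and ``keep_flags`` are aligned boolean arrays over
    all input droplets.  Resamples where either ratio is undefined are
    dropped.
    """
    t = np.asarray(target_flags, dtype=bool)
    k = np.asarray(keep_flags, dtype=bool)
    if t.shape != k.shape:
        raise ValueError("target and keep flags must align")
    n = t.size
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        tb, kb = t[idx], k[idx]
        n_tk = int(np.sum(tb & kb))
        n_ok = int(np.sum(~tb & kb))
        n_ti = int(tb.sum())
        n_oi = int((~tb).sum())
        if n_ok == 0 or n_oi == 0 or n_ti == 0:
            continue
        vals.append((n_tk / n_ok) / (n_ti / n_oi))
    if not vals:
        return float("nan"), float("nan")
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
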