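"""Observer-agreement metrics between two NCS analyses of the same scan.

Two 16-sector normalized circumferential strain maps (each with mean 1 by
construction) are compared through the mean absolute sector difference, the
coefficient of variation (sample SD of the non-absolute differences divided
by the mean NCS, which equals 1), the same pair restricted to the two local
NCS maxima and two local NCS minima, and the mean circular sector distance
between paired extrema.  CoV values are rated good (<= 0.20), fair
(0.21 - 0.30) or poor (> 0.30).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

N_SECTORS = 16

#: the mean NCS, fixed at 1 by the normalization — the CoV denominator
NCS_MEAN = 1.0

GOOD_MAX = 0.20
FAIR_MAX = 0.30


def rate_cov(cov: float) -> str:
    """Qualitative rating band of a coefficient of variation."""
    if not np.isfinite(cov) or cov < 0:
        raise ConfigurationError(f"CoV must be a non-negative number, got {cov}")
    if cov <= GOOD_MAX:
        return "good"
    if cov <= FAIR_MAX:
        return "fair"
    return "poor"


def circular_sector_distance(a: int | np.ndarray, b: int | np.ndarray, n: int = N_SECTORS) -> np.ndarray:
    """Shortest sector-count distance on the circular 16-sector map (<= 8)."""
    diff = np.mod(np.asarray(a) - np.asarray(b), n)
    return np.minimum(diff, n - diff)


def _plateau_runs(values: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """Runs of equal consecutive values on the circular array.

    Returns ``(representative_index, member_indices)`` per run, the
    representative being the lowest sector index in the run (wraparound
    runs take the lowest index of the wrapped block).
    """
    n = len(values)
    start = 0
    # rotate so index 0 starts a run, making runs contiguous
    while start < n and values[start] == values[(start - 1) % n]:
        start += 1
    if start == n:  # constant map: one run covering everything
        return [(0, np.arange(n))]
    runs = []
    i = start
    while True:
        j = i
        members = [i % n]
        while values[(j + 1) % n] == values[i % n]:
            j += 1
            members.append(j % n)
        runs.append((min(members), np.array(members)))
        i = j + 1
        if i % n == start:
            break
    return runs


def circular_local_extrema(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima and minima (0-based indices) of a circular 16-vector.

    A sector is a local extremum iff it strictly exceeds (maxima) or
    undercuts (minima) both circular neighbours; a plateau of equal values
    bounded on both sides by strictly lower (higher) values counts once, at
    its lowest sector index.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    maxima, minima = [], []
    for rep, members in _plateau_runs(values):
        if len(members) == n:
            break  # constant map has no extrema
        before = values[(members[0] - 1) % n]
        after = values[(members[-1] + 1) % n]
        v = values[rep]
        if v > before and v > after:
            maxima.append(rep)
        elif v < before and v < after:
            minima.append(rep)
    return np.array(sorted(maxima), dtype=int), np.array(sorted(minima), dtype=int)


def _top_extrema(values: np.ndarray, kind: str, k: int = 2) -> np.ndarray:
    """The ``k`` most extreme local maxima (or minima) by value, ties toward
    the lower sector index."""
    maxima, minima = circular_local_extrema(values)
    idx = maxima if kind == "max" else minima
    if len(idx) == 0:
        return idx
    sign = -1.0 if kind == "max" else 1.0
    order = np.lexsort((idx, sign * values[idx]))
    return idx[order][:k]


@dataclass(frozen=True)
class ReproducibilityReport:
    """Agreement metrics between two NCS maps of the same scan."""

    abs_mean_diff: float
    cov_mean: float
    abs_extrema_diff: float
    cov_extrema: float
    extrema_sector_diff: float
    rating: str
    rating_extrema: str
    n_extrema_pairs: int

    def to_dict(self) -> dict:
        return {
            "abs_mean_diff": self.abs_mean_diff,
            "cov_mean": self.cov_mean,
            "abs_extrema_diff": self.abs_extrema_diff,
            "cov_extrema": self.cov_extrema,
            "extrema_sector_diff": self.extrema_sector_diff,
            "rating": self.rating,
            "rating_extrema": self.rating_extrema,
            "n_extrema_pairs": self.n_extrema_pairs,
        }


def compare_maps(ncs_a: np.ndarray, ncs_b: np.ndarray) -> ReproducibilityReport:
    """Observer-agreement metrics between two normalized 16-sector maps.

    Both inputs must be normalized (mean 1 within 1e-9).  Differences are
    ``b - a`` per sector; the CoV is their sample SD divided by the mean
    NCS (1 by construction).  Extrema metrics pair each of the two largest
    local maxima / two smallest local minima of map ``a`` with the nearest
    same-type extremum of map ``b`` by circular sector distance (ties
    toward the lower sector index of ``b``).
    """
    a = np.asarray(ncs_a, dtype=float)
    b = np.asarray(ncs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("NCS maps must be 1-D arrays of equal length")
    for name, m in (("ncs_a", a), ("ncs_b", b)):
        if abs(np.nanmean(m) - NCS_MEAN) > 1e-9:
            raise ConfigurationError(
                f"{name} is not normalized: mean {np.nanmean(m):.6f} != 1"
            )
    delta = b - a
    abs_mean_diff = float(np.abs(delta).mean())
    cov_mean = float(delta.std(ddof=1) / NCS_MEAN)

    pair_deltas, pair_dists = [], []
    for kind in ("max", "min"):
        ext_a = _top_extrema(a, kind)
        ext_b = _top_extrema(b, kind)
        if len(ext_b) == 0:
            continue
        for sa in ext_a:
            dists = circular_sector_distance(sa, ext_b)
            order = np.lexsort((ext_b, dists))
            sb = int(ext_b[order[0]])
            pair_deltas.append(b[sb] - a[sa])
            pair_dists.append(float(dists[order[0]]))
    if pair_deltas:
        pair_deltas_arr = np.array(pair_deltas)
        abs_extrema_diff = float(np.abs(pair_deltas_arr).mean())
        cov_extrema = (
            float(pair_deltas_arr.std(ddof=1) / NCS_MEAN)
            if len(pair_deltas_arr) > 1
            else 0.0
        )
        extrema_sector_diff = float(np.mean(pair_dists))
    else:
        abs_extrema_diff = cov_extrema = extrema_sector_diff = 0.0
    return ReproducibilityReport(
        abs_mean_diff=abs_mean_diff,
        cov_mean=cov_mean,
        abs_extrema_diff=abs_extrema_diff,
        cov_extrema=cov_extrema,
        extrema_sector_diff=extrema_sector_diff,
        rating=rate_cov(cov_mean),
        rating_extrema=rate_cov(cov_extrema),
        n_extrema_pairs=len(pair_deltas),
    )


def mean_reports(*reports: ReproducibilityReport) -> ReproducibilityReport:
    """Average several pairwise reports (e.g. one reader vs two analyses by
    another), re-rating the averaged CoV values."""
    if not reports:
        raise ConfigurationError("need at least one report to average")

    def avg(attr):
        return float(np.mean([getattr(r, attr) for r in reports]))

    cov_mean = avg("cov_mean")
    cov_extrema = avg("cov_extrema")
    return ReproducibilityReport(
        abs_mean_diff=avg("abs_mean_diff"),
        cov_mean=cov_mean,
        abs_extrema_diff=avg("abs_extrema_diff"),
        cov_extrema=cov_extrema,
        extrema_sector_diff=avg("extrema_sector_diff"),
        rating=rate_cov(cov_mean),
        rating_extrema=rate_cov(cov_extrema),
        n_extrema_pairs=int(np.sum([r.n_extrema_pairs for r in reports])),
    )
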