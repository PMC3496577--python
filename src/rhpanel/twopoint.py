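"""Two-point linkage under the haploid radiation-hybrid retention model.

For a marker pair scored across a panel, the model has two parameters: the
breakage fraction theta (probability that an irradiation break separated the
two loci) and the retention probability r (probability a fragment is kept in
a hybrid).  The joint cell probabilities over informative hybrids are

    P11 = (1-theta) r + theta r^2
    P10 = P01 = theta r (1-r)
    P00 = (1-theta)(1-r) + theta (1-r)^2

i.e. with probability 1-theta both markers ride one fragment (retained with
probability r), and with probability theta they ride two independently
retained fragments.  The LOD score is the log10 likelihood ratio of the
fitted (theta, r) against independence (theta = 1).  Distance in centirays is
d = -100 ln(1-theta), annotated with the irradiation dose (cR_6000).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .io import ABSENT, PRESENT, UNKNOWN

LN10 = float(np.log(10.0))


class NoInformationError(ValueError):
    """No hybrid is informative for both markers."""


@dataclass(frozen=True)
class TwoPointCounts:
    """Joint present/absent tallies over doubly-informative hybrids."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def N(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n10, self.n01, self.n00)


def two_point_counts(row_a: np.ndarray, row_b: np.ndarray) -> TwoPointCounts:
    """Tally joint calls, excluding hybrids unknown in either row."""
    a = np.asarray(row_a)
    b = np.asarray(row_b)
    if a.shape != b.shape:
        raise ValueError("rows must share the hybrid ordering and length")
    keep = (a != UNKNOWN) & (b != UNKNOWN)
    if not keep.any():
        raise NoInformationError("no hybrid informative for both markers")
    a, b = a[keep], b[keep]
    return TwoPointCounts(
        n11=int(((a == PRESENT) & (b == PRESENT)).sum()),
        n10=int(((a == PRESENT) & (b == ABSENT)).sum()),
        n01=int(((a == ABSENT) & (b == PRESENT)).sum()),
        n00=int(((a == ABSENT) & (b == ABSENT)).sum()),
    )


def loglik(counts: TwoPointCounts, theta: float, r: float) -> float:
    """Natural-log multinomial likelihood of the haploid model."""
    p11 = (1.0 - theta) * r + theta * r * r
    p10 = theta * r * (1.0 - r)
    p00 = (1.0 - theta) * (1.0 - r) + theta * (1.0 - r) ** 2
    out = 0.0
    for n, p in ((counts.n11, p11), (counts.n10, p10), (counts.n01, p10), (counts.n00, p00)):
        if n:
            if p <= 0.0:
                return -np.inf
            out += n * np.log(p)
    return float(out)


def _theta_given_r(a: float, m: float, d: float, r: float) -> float:
    """Closed-form maximiser of a log(1-th*u) + m log th + d log(1-th*r).

    ``a`` = concordant-present weight, ``m`` = discordant weight, ``d`` =
    concordant-absent weight, ``u = 1-r``.  Stationary points solve
    ``th^2 u r N - th (m + a u + d r) + m = 0`` with ``N = a+m+d``; the
    maximiser among the in-range roots and the endpoints {0, 1} is returned.
    """
    u = 1.0 - r
    n_tot = a + m + d
    candidates = [0.0, 1.0]
    denom = 2.0 * u * r * n_tot
    if denom > 0:
        bq = m + a * u + d * r
        disc = bq * bq - 4.0 * u * r * n_tot * m
        if disc >= 0:
            root = np.sqrt(disc)
            for th in ((bq - root) / denom, (bq + root) / denom):
                if 0.0 < th < 1.0:
                    candidates.append(float(th))

    def f(th: float) -> float:
        val = 0.0
        for w, p in ((a, 1.0 - th * u), (m, th), (d, 1.0 - th * r)):
            if w > 0.0:
                if p <= 0.0:
                    return -np.inf
                val += w * np.log(p)
        return val

    return max(candidates, key=f)


@dataclass(frozen=True)
class TwoPointResult:
    """Fitted two-point linkage between one marker pair.

    ``lod`` compares the fit against theta = 1 at the shared fitted r (so it
    is non-negative by construction); ``distance_cr`` is -100 ln(1-theta),
    infinite at theta = 1.
    """

    theta: float
    r: float
    lod: float
    distance_cr: float
    N: int
    loglik: float  # natural log at the optimum
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            "Two-point RH linkage (haploid retention model)",
            f"  informative hybrids N = {self.N}",
            f"  breakage fraction theta = {self.theta:.4f}",
            f"  retention r             = {self.r:.4f}",
            f"  LOD                     = {self.lod:.2f}",
            f"  distance                = {self.distance_cr:.1f} cR_6000",
        ]
        if self.degenerate:
            lines.append("  [degenerate: retention at boundary]")
        return "\n".join(lines)


class TwoPointModel:
    """Maximum-likelihood two-point model for one marker pair.

    The likelihood is maximised by profiling: for each r the optimal theta
    has a closed form (quadratic stationarity equation), and the profile in r
    is maximised numerically from a coarse bracketing grid.
    """

    def __init__(self, counts: TwoPointCounts):
        if counts.N == 0:
            raise NoInformationError("N = 0: no informative hybrids")
        self.counts = counts

    @classmethod
    def from_rows(cls, row_a: np.ndarray, row_b: np.ndarray) -> "TwoPointModel":
        return cls(two_point_counts(row_a, row_b))

    def moment_estimates(self) -> tuple[float, float]:
        """Moment initialisation (theta0, r0); r0 is the marginal retention."""
        c = self.counts
        r0 = (2 * c.n11 + c.n10 + c.n01) / (2 * c.N)
        if 0.0 < r0 < 1.0:
            theta0 = (c.n10 + c.n01) / (2 * c.N * r0 * (1.0 - r0))
        else:
            theta0 = 1.0
        return float(np.clip(theta0, 0.0, 1.0)), float(r0)

    def _profile(self, r: float) -> tuple[float, float]:
        c = self.counts
        th = _theta_given_r(c.n11, c.n10 + c.n01, c.n00, r)
        return th, loglik(c, th, r)

    def fit(self, independent_null: bool = False) -> TwoPointResult:
        """Fit (theta, r) and the LOD against the theta = 1 null.

        With ``independent_null`` the null likelihood uses its own retention
        MLE at theta = 1 (the marginal rate) instead of the shared fitted r.
        """
        c = self.counts
        n_pos = 2 * c.n11 + c.n10 + c.n01
        if n_pos == 0 or n_pos == 2 * c.N:
            # all-absent or all-present: r at the boundary, theta unidentifiable
            r_b = 1.0 - 1e-9 if n_pos else 1e-9
            return TwoPointResult(
                theta=1.0,
                r=r_b,
                lod=0.0,
                distance_cr=np.inf,
                N=c.N,
                loglik=loglik(c, 1.0, r_b),
                degenerate=True,
            )

        lo, hi = 1e-6, 1.0 - 1e-6
        grid = np.linspace(lo, hi, 101)
        vals = [self._profile(r)[1] for r in grid]
        k = int(np.argmax(vals))
        a = grid[max(0, k - 1)]
        b = grid[min(len(grid) - 1, k + 1)]
        res = minimize_scalar(
            lambda r: -self._profile(r)[1],
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-10},
        )
        r_hat = float(res.x)
        theta_hat, ll = self._profile(r_hat)
        if ll < vals[k]:  # numerical guard: never fall below the grid best
            r_hat = float(grid[k])
            theta_hat, ll = self._profile(r_hat)

        if independent_null:
            r_null = n_pos / (2 * c.N)
            ll_null = loglik(c, 1.0, r_null)
        else:
            ll_null = loglik(c, 1.0, r_hat)
        lod = max(0.0, (ll - ll_null) / LN10)
        theta_hat = float(theta_hat)
        if theta_hat >= 1.0:
            lod = 0.0 if not independent_null else lod
            dist = np.inf
        else:
            dist = -100.0 * float(np.log1p(-theta_hat))
        return TwoPointResult(
            theta=theta_hat,
            r=r_hat,
            lod=float(lod),
            distance_cr=dist,
            N=c.N,
            loglik=float(ll),
        )


def two_point_fit(counts: TwoPointCounts, independent_null: bool = False) -> TwoPointResult:
    """Functional front-end to :class:`TwoPointModel`."""
    return TwoPointModel(counts).fit(independent_null=independent_null)


def grid_search_fit(
    counts: TwoPointCounts, n_theta: int = 1000, n_r: int = 999
) -> tuple[float, float, float]:
    """Brute-force (theta, r) maximisation on a dense grid.

    Independent oracle for the numeric fit: returns (theta, r, natural-log
    likelihood) at the best of ``n_theta x n_r`` grid points, vectorised.
    """
    thetas = np.linspace(0.0, 1.0, n_theta)[:, None]
    rs = np.linspace(1e-6, 1.0 - 1e-6, n_r)[None, :]
    p11 = (1.0 - thetas) * rs + thetas * rs**2
    p10 = thetas * rs * (1.0 - rs)
    p00 = (1.0 - thetas) * (1.0 - rs) + thetas * (1.0 - rs) ** 2
    ll = np.zeros(np.broadcast_shapes(p11.shape, p10.shape))
    with np.errstate(divide="ignore"):
        # a zero count contributes 0 even where its cell probability is 0
        for n, p in ((counts.n11, p11), (counts.n10 + counts.n01, p10), (counts.n00, p00)):
            if n:
                ll = ll + n * np.log(p)
    k = int(np.argmax(ll))
    i, j = divmod(k, n_r)
    return float(thetas[i, 0]), float(rs[0, j]), float(ll[i, j])


def pairwise_lod_matrix(
    calls: np.ndarray, min_informative: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs LOD and theta matrices for a call matrix (markers x hybrids).

    Pairs with fewer than ``min_informative`` doubly-informative hybrids get
    LOD = -inf and theta = 1 (treated as unlinked downstream).
    """
    n = calls.shape[0]
    lod = np.full((n, n), -np.inf)
    theta = np.ones((n, n))
    np.fill_diagonal(theta, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                c = two_point_counts(calls[i], calls[j])
            except NoInformationError:
                continue
            if c.N < min_informative:
                continue
            res = two_point_fit(c)
            lod[i, j] = lod[j, i] = res.lod
            theta[i, j] = theta[j, i] = res.theta
    return lod, theta
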