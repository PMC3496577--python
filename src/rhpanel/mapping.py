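"""Multipoint RH mapping: marker ordering and map construction.

Along a candidate marker order, the hidden presence of a hybrid's DNA follows
a two-state Markov chain: the first marker is retained with probability r,
and between adjacent markers i, i+1 (breakage fraction theta_i)

    P(1->1) = 1 - theta (1-r)      P(1->0) = theta (1-r)
    P(0->1) = theta r              P(0->0) = 1 - theta r

which is the stationary, reversible chain of the haploid retention model: a
break between the two loci (probability theta) re-draws retention
independently.  Observed calls are the chain states; unknown calls are
marginalised by the forward algorithm.  Maps are fitted by EM
(forward-backward expected transition counts; closed-form per-interval theta
M-step, shared retention r profiled numerically), orders are searched
exhaustively up to 8 markers and by greedy insertion plus 2-opt /
sliding-window refinement above that, and positions are cumulative
-100 ln(1-theta) centirays (cR_6000).

During order search and framework construction the shared retention is held
at the group's marginal estimate (it is order-invariant to first order),
which makes candidate scoring a pure theta problem; every returned map is
refitted with r free.

Framework maps keep only markers whose best placement beats the runner-up by
a log10-likelihood margin (default 3); comparative maps penalise marker
orders by the number of adjacency breakpoints against a reference genome
order; robust maps keep the largest marker subset whose relative order is
stable across bootstrap resamples of the hybrids.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io import ABSENT, PRESENT, UNKNOWN, GenotypeMatrix
from .retention import marker_retention
from .twopoint import LN10, pairwise_lod_matrix, two_point_counts, two_point_fit
from .twopoint import NoInformationError

_EPS_R = 1e-6


class ConvergenceError(RuntimeError):
    """EM failed to converge within the sweep budget."""


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# linkage groups

@dataclass(frozen=True)
class LinkageGroup:
    """A single-linkage component of the pairwise-LOD graph."""

    marker_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.marker_ids)

    def __iter__(self):
        return iter(self.marker_ids)


def linkage_groups(matrix: GenotypeMatrix, lod_threshold: float) -> list[LinkageGroup]:
    """Single-linkage marker groups at a pairwise LOD threshold.

    Groups are ordered by decreasing size, then by their lexicographically
    smallest marker id; within a group, matrix order is preserved.
    """
    if matrix.n_markers < 2:
        raise ParameterError("need at least 2 markers to form linkage groups")
    lod, _ = pairwise_lod_matrix(matrix.calls)
    g = nx.Graph()
    g.add_nodes_from(range(matrix.n_markers))
    for i in range(matrix.n_markers):
        for j in range(i + 1, matrix.n_markers):
            if lod[i, j] >= lod_threshold:
                g.add_edge(i, j)
    groups = [
        LinkageGroup(tuple(matrix.marker_ids[i] for i in sorted(comp)))
        for comp in nx.connected_components(g)
    ]
    groups.sort(key=lambda grp: (-len(grp), min(grp.marker_ids)))
    return groups


# ---------------------------------------------------------------------------
# array-level likelihood core
#
# e0/e1 are (n_markers, n_hybrids) float indicators of calls compatible with
# the absent/present state (unknown rows are 1 in both).

def _emissions(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (
        (calls != PRESENT).astype(float),
        (calls != ABSENT).astype(float),
    )


def _forward_ll(e0: np.ndarray, e1: np.ndarray, thetas: np.ndarray, r: float) -> float:
    """Scaled forward pass returning only the total log-likelihood."""
    a0 = e0[0] * (1.0 - r)
    a1 = e1[0] * r
    c = a0 + a1
    np.maximum(c, np.finfo(float).tiny, out=c)
    ll = np.log(c).sum()
    a0 /= c
    a1 /= c
    for i in range(1, e0.shape[0]):
        th = thetas[i - 1]
        t01 = th * r
        t10 = th * (1.0 - r)
        b0 = (a0 * (1.0 - t01) + a1 * t10) * e0[i]
        b1 = (a0 * t01 + a1 * (1.0 - t10)) * e1[i]
        c = b0 + b1
        np.maximum(c, np.finfo(float).tiny, out=c)
        ll += np.log(c).sum()
        a0 = b0 / c
        a1 = b1 / c
    return float(ll)


def _forward_backward(e0: np.ndarray, e1: np.ndarray, thetas: np.ndarray, r: float):
    """Returns (loglik, gamma0 sums (2,), xi sums (n-1, 2, 2))."""
    n, h = e0.shape
    alpha0 = np.empty((n, h))
    alpha1 = np.empty((n, h))
    scale = np.empty((n, h))
    a0 = e0[0] * (1.0 - r)
    a1 = e1[0] * r
    c = a0 + a1
    np.maximum(c, np.finfo(float).tiny, out=c)
    alpha0[0] = a0 / c
    alpha1[0] = a1 / c
    scale[0] = c
    t01s = thetas * r
    t10s = thetas * (1.0 - r)
    for i in range(1, n):
        t01, t10 = t01s[i - 1], t10s[i - 1]
        b0 = (alpha0[i - 1] * (1.0 - t01) + alpha1[i - 1] * t10) * e0[i]
        b1 = (alpha0[i - 1] * t01 + alpha1[i - 1] * (1.0 - t10)) * e1[i]
        c = b0 + b1
        np.maximum(c, np.finfo(float).tiny, out=c)
        alpha0[i] = b0 / c
        alpha1[i] = b1 / c
        scale[i] = c
    ll = float(np.log(scale).sum())
    if n == 1:
        return ll, np.array([alpha0[0].sum(), alpha1[0].sum()]), np.empty((0, 2, 2))

    xi = np.empty((n - 1, 2, 2))
    beta0 = np.ones(h)
    beta1 = np.ones(h)
    for i in range(n - 2, -1, -1):
        t01, t10 = t01s[i], t10s[i]
        w0 = e0[i + 1] * beta0 / scale[i + 1]
        w1 = e1[i + 1] * beta1 / scale[i + 1]
        xi[i, 0, 0] = (1.0 - t01) * np.dot(alpha0[i], w0)
        xi[i, 0, 1] = t01 * np.dot(alpha0[i], w1)
        xi[i, 1, 0] = t10 * np.dot(alpha1[i], w0)
        xi[i, 1, 1] = (1.0 - t10) * np.dot(alpha1[i], w1)
        nb0 = (1.0 - t01) * w0 + t01 * w1
        nb1 = t10 * w0 + (1.0 - t10) * w1
        beta0, beta1 = nb0, nb1
    gamma0 = np.array(
        [(alpha0[0] * beta0).sum(), (alpha1[0] * beta1).sum()]
    )
    return ll, gamma0, xi


def _theta_profile(a, m, d, r):
    """Vectorised maximiser of a log(1-th(1-r)) + m log th + d log(1-th r).

    Stationary points solve th^2 u r N - th (m + a u + d r) + m = 0 with
    u = 1-r, N = a+m+d; the best of the in-range roots and the endpoints
    {0, 1} is returned along with its objective value.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    m = np.atleast_1d(np.asarray(m, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    u = 1.0 - r
    n_tot = a + m + d
    denom = 2.0 * u * r * n_tot
    bq = m + a * u + d * r
    disc = bq * bq - 4.0 * u * r * n_tot * m
    ok = (denom > 0) & (disc >= 0)
    root = np.sqrt(np.where(ok, disc, 0.0))
    safe = np.where(denom > 0, denom, 1.0)
    cands = [
        np.zeros_like(a),
        np.ones_like(a),
        np.clip(np.where(ok, (bq - root) / safe, 0.0), 0.0, 1.0),
        np.clip(np.where(ok, (bq + root) / safe, 0.0), 0.0, 1.0),
    ]

    def val(th):
        out = np.zeros_like(a)
        for w, p in ((a, 1.0 - th * u), (m, th), (d, 1.0 - th * r)):
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(w > 1e-300, w * np.log(np.maximum(p, 1e-300)), 0.0)
                # w > 0 with p == 0 must be -inf, not w*log(tiny)
                term = np.where((w > 1e-300) & (p <= 0.0), -np.inf, term)
            out = out + term
        return out

    best_th = cands[0]
    best_val = val(best_th)
    for th in cands[1:]:
        v = val(th)
        better = v > best_val
        best_th = np.where(better, th, best_th)
        best_val = np.where(better, v, best_val)
    return best_th, best_val


def _fit_arrays(
    e0: np.ndarray,
    e1: np.ndarray,
    r0: float,
    thetas0: np.ndarray | None = None,
    fix_r: bool = False,
    tol: float = 1e-6,
    max_sweeps: int = 500,
) -> tuple[float, np.ndarray, float, int]:
    """EM on raw emission arrays; returns (loglik, thetas, r, sweeps)."""
    n = e0.shape[0]
    r = float(np.clip(r0, _EPS_R, 1.0 - _EPS_R))
    thetas = (
        np.asarray(thetas0, dtype=float).copy()
        if thetas0 is not None
        else np.full(max(n - 1, 0), 0.2)
    )
    ll_prev = -np.inf
    for sweep in range(max_sweeps):
        ll, gamma0, xi = _forward_backward(e0, e1, thetas, r)
        if sweep > 0 and ll - ll_prev < tol:
            return ll, thetas, r, sweep
        ll_prev = ll
        g0, g1 = float(gamma0[0]), float(gamma0[1])
        if n == 1:
            if fix_r:
                return ll, thetas, r, sweep
            r = float(np.clip(g1 / max(g0 + g1, 1e-300), _EPS_R, 1.0 - _EPS_R))
            continue
        a = xi[:, 1, 1]
        b = xi[:, 1, 0]
        c = xi[:, 0, 1]
        d = xi[:, 0, 0]
        m = b + c
        if fix_r:
            thetas, _ = _theta_profile(a, m, d, r)
            continue

        def neg_q(rr: float) -> float:
            _, vals = _theta_profile(a, m, d, rr)
            q = g1 * np.log(rr) + g0 * np.log(1.0 - rr)
            q += float(np.sum(b * np.log(1.0 - rr) + c * np.log(rr) + vals))
            return -q

        res = minimize_scalar(
            neg_q, bounds=(_EPS_R, 1.0 - _EPS_R), method="bounded",
            options={"xatol": 1e-9},
        )
        r = float(res.x)
        thetas, _ = _theta_profile(a, m, d, r)
    raise ConvergenceError(
        f"EM did not converge in {max_sweeps} sweeps (last ll={ll_prev:.6f})"
    )


def map_loglik(
    order: Sequence[str],
    matrix: GenotypeMatrix,
    r: float,
    thetas: Sequence[float],
) -> float:
    """Natural-log multipoint likelihood of an order at given parameters."""
    thetas = np.asarray(thetas, dtype=float)
    if len(thetas) != max(len(order) - 1, 0):
        raise ParameterError("need one theta per adjacent marker pair")
    if not 0.0 < r < 1.0:
        raise ParameterError("r must be in (0, 1)")
    e0, e1 = _emissions(matrix.subset(order).calls)
    return _forward_ll(e0, e1, thetas, r)


# ---------------------------------------------------------------------------
# fitted map container

@dataclass
class RHMapResult:
    """A fitted RH map: ordered markers, interval thetas, shared retention.

    ``positions_cr`` are cumulative -100 ln(1-theta) from the first marker
    (0-based); ``log_likelihood`` is in natural log units (use
    ``log10_likelihood`` against LOD-scale thresholds).  ``status`` tags each
    marker (framework / placed / robust / nonrobust).
    """

    marker_ids: list[str]
    thetas: np.ndarray
    r: float
    log_likelihood: float
    n_hybrids: int
    map_kind: str = "carthagene_style"
    status: dict[str, str] = field(default_factory=dict)
    placements: dict[str, dict] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def positions_cr(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            d = -100.0 * np.log1p(-np.asarray(self.thetas, dtype=float))
        return np.concatenate(([0.0], np.cumsum(d)))

    @property
    def length_cr(self) -> float:
        return float(self.positions_cr[-1]) if self.marker_ids else 0.0

    @property
    def log10_likelihood(self) -> float:
        return self.log_likelihood / LN10

    def to_frame(self) -> pd.DataFrame:
        pos = self.positions_cr
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "position_cR_6000": pos,
                "status": [self.status.get(m, "") for m in self.marker_ids],
                "theta_next": list(self.thetas) + [np.nan],
            }
        )

    def summary(self) -> str:
        lines = [
            f"RH map ({self.map_kind}), {len(self.marker_ids)} markers, "
            f"{self.n_hybrids} hybrids",
            f"  retention r       = {self.r:.4f}",
            f"  map length        = {self.length_cr:.1f} cR_6000",
            f"  log10-likelihood  = {self.log10_likelihood:.3f}",
            "",
            f"  {'marker':<18}{'cR_6000':>10}  status",
        ]
        pos = self.positions_cr
        for k, mid in enumerate(self.marker_ids):
            lines.append(f"  {mid:<18}{pos[k]:>10.1f}  {self.status.get(mid, '')}")
        return "\n".join(lines)


class MultipointModel:
    """Maximum-likelihood multipoint model for one ordered marker set.

    ``fit`` runs EM: the E-step is a scaled forward-backward pass over the
    two-state presence chain (unknown calls marginalised), the M-step updates
    every interval theta in closed form while profiling the shared retention
    r numerically.  Convergence is declared when the observed log-likelihood
    improves by less than ``tol`` (natural-log units).
    """

    def __init__(self, matrix: GenotypeMatrix, order: Sequence[str] | None = None):
        self.order = list(order) if order is not None else list(matrix.marker_ids)
        if not self.order:
            raise ParameterError("empty marker order")
        self.matrix = matrix
        self._calls = matrix.subset(self.order).calls
        self._e0, self._e1 = _emissions(self._calls)

    def loglik(self, r: float, thetas: Sequence[float]) -> float:
        return _forward_ll(self._e0, self._e1, np.asarray(thetas, dtype=float), r)

    def marginal_retention(self) -> float:
        informative = self._calls != UNKNOWN
        denom = int(informative.sum())
        r0 = float((self._calls == PRESENT).sum() / denom) if denom else 0.25
        return float(np.clip(r0, 0.02, 0.98))

    def fit(
        self,
        r0: float | None = None,
        thetas0: Sequence[float] | None = None,
        fix_r: bool = False,
        tol: float = 1e-6,
        max_sweeps: int = 500,
        map_kind: str = "carthagene_style",
    ) -> RHMapResult:
        r_start = r0 if r0 is not None else self.marginal_retention()
        ll, thetas, r, sweeps = _fit_arrays(
            self._e0, self._e1, r_start, thetas0, fix_r, tol, max_sweeps
        )
        return RHMapResult(
            marker_ids=list(self.order),
            thetas=thetas,
            r=r,
            log_likelihood=ll,
            n_hybrids=self.matrix.n_hybrids,
            map_kind=map_kind,
            diagnostics={"em_sweeps": sweeps},
        )


def fit_map(
    matrix: GenotypeMatrix,
    order: Sequence[str] | None = None,
    **kwargs,
) -> RHMapResult:
    """Fit interval thetas and shared retention for a fixed marker order."""
    return MultipointModel(matrix, order).fit(**kwargs)


# ---------------------------------------------------------------------------
# order search machinery

def _canonical(order: Sequence[str]) -> tuple[str, ...]:
    t = tuple(order)
    return min(t, t[::-1])


class _GroupScorer:
    """Fast candidate-order scorer over one marker group.

    Emission arrays are computed once; candidate orders are index
    permutations scored by EM with the retention fixed at the group marginal
    and a loose tolerance.  ``refit`` produces the final free-retention map.
    """

    def __init__(self, matrix: GenotypeMatrix, ids: Sequence[str]):
        self.matrix = matrix
        self.ids = list(ids)
        sub = matrix.subset(self.ids)
        self.calls = sub.calls
        self.e0, self.e1 = _emissions(self.calls)
        informative = self.calls != UNKNOWN
        denom = int(informative.sum())
        self.r_group = float(
            np.clip((self.calls == PRESENT).sum() / max(denom, 1), 0.02, 0.98)
        )
        self._cache: dict[tuple, float] = {}

    def _canon_idx(self, idx: tuple[int, ...]) -> tuple[int, ...]:
        return min(idx, idx[::-1])

    def score_idx(self, idx: Sequence[int], tol: float = 1e-4, max_sweeps: int = 100) -> float:
        key = (self._canon_idx(tuple(idx)), tol)
        if key not in self._cache:
            perm = list(key[0])
            ll, _, _, _ = _fit_arrays(
                self.e0[perm], self.e1[perm], self.r_group,
                fix_r=True, tol=tol, max_sweeps=max_sweeps,
            )
            self._cache[key] = ll
        return self._cache[key]

    def score_order(self, order: Sequence[str], **kw) -> float:
        return self.score_idx([self.ids.index(m) for m in order], **kw)

    def refit(self, order: Sequence[str], map_kind: str = "carthagene_style") -> RHMapResult:
        return MultipointModel(self.matrix, order).fit(map_kind=map_kind)


def _all_orders_idx(n: int):
    """All index permutations modulo reversal (first < last)."""
    for perm in itertools.permutations(range(n)):
        if perm[0] < perm[-1]:
            yield perm


def _pick_best_order(
    scorer: _GroupScorer, candidates, score_fn, shortlist: int = 40
) -> tuple[list[str], float]:
    """Two-stage exhaustive scan: coarse EM scores for every candidate, then
    a tight refit of the ``shortlist`` best before choosing the winner."""
    coarse: list[tuple[float, tuple[int, ...]]] = []
    for idx in candidates:
        order = [scorer.ids[k] for k in idx]
        s = score_fn(idx, order, 1e-2, 30)
        coarse.append((s, tuple(idx)))
    coarse.sort(key=lambda t: (-t[0], t[1]))
    best_order: list[str] | None = None
    best_score = -np.inf
    for _, idx in coarse[:shortlist]:
        order = [scorer.ids[k] for k in idx]
        s = score_fn(idx, order, 1e-6, 500)
        if s > best_score + 1e-9 or (
            s > best_score - 1e-9
            and best_order is not None
            and _canonical(order) < _canonical(best_order)
        ):
            best_order, best_score = order, s
    return best_order, best_score


def _local_refine_idx(scorer: _GroupScorer, start_idx: list[int], score_fn, window: int = 4,
                      tol: float = 1e-6) -> tuple[list[int], float]:
    """2-opt and sliding-window passes until no score gain above tol."""
    best = list(start_idx)
    best_score = score_fn(tuple(best), [scorer.ids[k] for k in best])
    n = len(best)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                cand = best[:i] + best[i : j + 1][::-1] + best[j + 1 :]
                if scorer._canon_idx(tuple(cand)) == scorer._canon_idx(tuple(best)):
                    continue
                s = score_fn(tuple(cand), [scorer.ids[k] for k in cand])
                if s > best_score + tol:
                    best, best_score = cand, s
                    improved = True
        if n > window:
            for i in range(n - window + 1):
                seg = best[i : i + window]
                for perm in itertools.permutations(seg):
                    if list(perm) == seg:
                        continue
                    cand = best[:i] + list(perm) + best[i + window :]
                    if scorer._canon_idx(tuple(cand)) == scorer._canon_idx(tuple(best)):
                        continue
                    s = score_fn(tuple(cand), [scorer.ids[k] for k in cand])
                    if s > best_score + tol:
                        best, best_score = cand, s
                        improved = True
    return best, best_score


def _greedy_seed_idx(scorer: _GroupScorer) -> list[int]:
    """Highest-LOD pair seed, then best-insertion by decreasing linkage."""
    lod, _ = pairwise_lod_matrix(scorer.calls)
    n = len(scorer.ids)
    pairs = [(lod[i, j], i, j) for i in range(n) for j in range(i + 1, n)]
    _, bi, bj = max(pairs, key=lambda t: (t[0], -t[1], -t[2]))
    order = [bi, bj]
    remaining = [k for k in range(n) if k not in order]
    while remaining:
        _, marker = max(
            ((max(lod[m, k] for k in order), m) for m in remaining),
            key=lambda t: (t[0], -t[1]),
        )
        best_cand, best_ll = None, -np.inf
        for pos in range(len(order) + 1):
            cand = order[:pos] + [marker] + order[pos:]
            ll = scorer.score_idx(cand)
            if ll > best_ll:
                best_cand, best_ll = cand, ll
        order = best_cand
        remaining.remove(marker)
    return order


def order_search(
    matrix: GenotypeMatrix,
    group: Iterable[str] | LinkageGroup,
    exhaustive_limit: int = 8,
) -> RHMapResult:
    """Best-likelihood marker order for one linkage group.

    Exhaustive over all orders modulo reversal for n <= ``exhaustive_limit``;
    otherwise greedy best-insertion seeded by the highest-LOD pair, refined
    by 2-opt and sliding-window (window 4) passes until no gain.  Ties break
    on the lexicographically smallest reversal-invariant order.
    """
    ids = list(group.marker_ids) if isinstance(group, LinkageGroup) else list(group)
    if len(ids) < 3:
        return fit_map(matrix, ids)
    scorer = _GroupScorer(matrix, ids)

    def score_fn(idx, order, tol=1e-4, max_sweeps=100):
        return scorer.score_idx(idx, tol, max_sweeps)

    if len(ids) <= exhaustive_limit:
        best_order, _ = _pick_best_order(scorer, _all_orders_idx(len(ids)), score_fn)
    else:
        seed = _greedy_seed_idx(scorer)
        best_idx, _ = _local_refine_idx(scorer, seed, score_fn)
        best_order = [scorer.ids[k] for k in best_idx]
    return scorer.refit(best_order)


# ---------------------------------------------------------------------------
# framework and comprehensive maps

def _insertion_scan(
    scorer: _GroupScorer, order_idx: list[int], marker_idx: int
) -> tuple[float, int, float]:
    """(log10 margin best-vs-second placement, best position, best ll)."""
    lls = []
    for pos in range(len(order_idx) + 1):
        cand = order_idx[:pos] + [marker_idx] + order_idx[pos:]
        lls.append(scorer.score_idx(cand))
    ranked = sorted(range(len(lls)), key=lambda p: (-lls[p], p))
    best_pos = ranked[0]
    second = lls[ranked[1]] if len(ranked) > 1 else -np.inf
    return (lls[best_pos] - second) / LN10, best_pos, lls[best_pos]


def build_framework(
    matrix: GenotypeMatrix,
    group: Iterable[str] | LinkageGroup,
    delta_lod: float = 3.0,
) -> RHMapResult:
    """Framework map: only markers ordered with a log10 margin >= delta_lod.

    Starts from the triple whose best internal order beats its runner-up by
    the largest margin (exhaustive over triples), then repeatedly inserts
    the unplaced marker with the largest placement margin, while that margin
    stays >= ``delta_lod``.  Returns an empty map with diagnostics when no
    triple reaches the margin.
    """
    ids = list(group.marker_ids) if isinstance(group, LinkageGroup) else list(group)
    if len(ids) < 3:
        raise ParameterError("framework construction needs >= 3 markers")
    scorer = _GroupScorer(matrix, ids)
    n = len(ids)

    best_triple, best_margin = None, -np.inf
    for i, j, k in itertools.combinations(range(n), 3):
        lls = []
        for order in ((i, j, k), (i, k, j), (j, i, k)):
            lls.append((scorer.score_idx(order), order))
        lls.sort(key=lambda t: (-t[0], t[1]))
        margin = (lls[0][0] - lls[1][0]) / LN10
        if margin > best_margin:
            best_triple, best_margin = list(lls[0][1]), margin
    if best_margin < delta_lod:
        return RHMapResult(
            marker_ids=[],
            thetas=np.empty(0),
            r=float("nan"),
            log_likelihood=float("nan"),
            n_hybrids=matrix.n_hybrids,
            diagnostics={
                "reason": "no starting triple with sufficient margin",
                "best_triple_margin": best_margin,
            },
        )

    order_idx = best_triple
    unplaced = sorted(set(range(n)) - set(order_idx), key=lambda k: ids[k])
    while unplaced:
        scored = []
        for m in unplaced:
            margin, pos, _ = _insertion_scan(scorer, order_idx, m)
            scored.append((margin, ids[m], m, pos))
        margin, _, m, pos = max(scored, key=lambda t: (t[0], t[1]))
        if margin < delta_lod:
            break
        order_idx = order_idx[:pos] + [m] + order_idx[pos:]
        unplaced.remove(m)

    order = [ids[k] for k in order_idx]
    result = scorer.refit(order)
    result.status = {m: "framework" for m in order}
    result.diagnostics["unplaced"] = sorted(ids[k] for k in unplaced)
    result.diagnostics["start_triple_margin"] = best_margin
    return result


def place_comprehensive(
    framework: RHMapResult,
    matrix: GenotypeMatrix,
    others: Iterable[str],
    link_lod: float = 3.0,
) -> RHMapResult:
    """Comprehensive map: framework plus remaining markers at ML positions.

    Each non-framework marker is tried at every insertion point of the
    framework order (which stays fixed); its best interval and the log10
    margin to the second-best placement are recorded.  Markers with
    two-point LOD < ``link_lod`` against every framework marker stay
    unplaced.  The map may extend beyond the framework ends.
    """
    fw_order = list(framework.marker_ids)
    if not fw_order:
        raise ParameterError("empty framework")
    others = sorted(set(others) - set(fw_order))
    scorer = _GroupScorer(matrix, fw_order + others)
    fw_idx = [scorer.ids.index(m) for m in fw_order]

    placements: dict[str, dict] = {}
    inserted: list[tuple[int, str]] = []
    for marker in others:
        row = matrix.row(marker)
        linked = False
        for fm in fw_order:
            try:
                if two_point_fit(two_point_counts(row, matrix.row(fm))).lod >= link_lod:
                    linked = True
                    break
            except NoInformationError:
                continue
        if not linked:
            placements[marker] = {"position": None, "delta_lod": 0.0}
            continue
        margin, pos, _ = _insertion_scan(scorer, fw_idx, scorer.ids.index(marker))
        placements[marker] = {"position": pos, "delta_lod": margin}
        inserted.append((pos, marker))

    order = list(fw_order)
    # insert right-to-left so recorded framework positions stay valid
    for pos, marker in sorted(inserted, key=lambda t: (-t[0], t[1])):
        order.insert(pos, marker)
    result = scorer.refit(order)
    result.status = {
        m: ("framework" if m in framework.status else "placed") for m in order
    }
    result.placements = placements
    return result


# ---------------------------------------------------------------------------
# comparative mapping

def count_breakpoints(order: Sequence[str], reference_order: Sequence[str]) -> int:
    """Adjacent pairs of ``order`` not adjacent in the reference order.

    The reference is first restricted to the markers of ``order``; adjacency
    is orientation-insensitive, so a full reversal counts zero breakpoints.
    """
    members = set(order)
    missing = members - set(reference_order)
    if missing:
        raise ParameterError(f"markers absent from reference: {sorted(missing)}")
    ref = [m for m in reference_order if m in members]
    adj = {frozenset(p) for p in zip(ref[:-1], ref[1:])}
    return sum(1 for p in zip(order[:-1], order[1:]) if frozenset(p) not in adj)


@dataclass
class ComparativeConfig:
    """Reference order plus the breakpoint penalty and resampling scheme."""

    reference_order: list[str]
    lambda_penalty: float = 3.0  # log10-likelihood units per breakpoint
    bootstrap_B: int = 100
    robust_conf: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_penalty < 0:
            raise ParameterError("lambda_penalty must be >= 0")
        if not 0.0 < self.robust_conf <= 1.0:
            raise ParameterError("robust_conf must be in (0, 1]")


def comparative_map(
    matrix: GenotypeMatrix,
    group: Iterable[str] | LinkageGroup,
    config: ComparativeConfig,
    exhaustive_limit: int = 8,
) -> RHMapResult:
    """Best order under score = log10-likelihood - lambda x breakpoints.

    The search mirrors :func:`order_search` but is initialised at (and, for
    small groups, exhaustively compared against) the reference order, so with
    a large penalty the reference order wins and with ``lambda_penalty = 0``
    the result coincides with the unpenalised search.
    """
    ids = list(group.marker_ids) if isinstance(group, LinkageGroup) else list(group)
    ref = [m for m in config.reference_order if m in set(ids)]
    if set(ref) != set(ids):
        raise ParameterError("every group marker needs a reference position")
    scorer = _GroupScorer(matrix, ids)

    def score_fn(idx, order, tol=1e-4, max_sweeps=100):
        return scorer.score_idx(idx, tol, max_sweeps) / LN10 - (
            config.lambda_penalty * count_breakpoints(order, config.reference_order)
        )

    if len(ids) < 3:
        best_order = ref
    elif len(ids) <= exhaustive_limit:
        best_order, _ = _pick_best_order(scorer, _all_orders_idx(len(ids)), score_fn)
    else:
        ref_idx = [scorer.ids.index(m) for m in ref]
        best_idx, _ = _local_refine_idx(scorer, ref_idx, score_fn)
        best_order = [scorer.ids[k] for k in best_idx]

    result = scorer.refit(best_order, map_kind="comparative")
    result.diagnostics["breakpoints"] = count_breakpoints(
        best_order, config.reference_order
    )
    result.diagnostics["score"] = (
        result.log10_likelihood
        - config.lambda_penalty * result.diagnostics["breakpoints"]
    )
    return result


def robust_map(
    matrix: GenotypeMatrix,
    group: Iterable[str] | LinkageGroup,
    config: ComparativeConfig,
    base_map: RHMapResult | None = None,
) -> RHMapResult:
    """Comparative map with robust flags from bootstrap resampling.

    Hybrids are resampled with replacement ``bootstrap_B`` times and the
    comparative map rebuilt each time (local search from the reference
    order, which keeps the resampling affordable).  The robust set is the
    largest marker subset whose relative order (mod reversal) matches the
    base map in >= ``robust_conf`` of the bootstrap maps, found by greedily
    removing the marker whose removal most improves agreement.
    """
    if config.bootstrap_B < 10:
        raise ParameterError("bootstrap_B must be >= 10")
    ids = list(group.marker_ids) if isinstance(group, LinkageGroup) else list(group)
    base = base_map or comparative_map(matrix, ids, config)
    base_order = list(base.marker_ids)
    ref = [m for m in config.reference_order if m in set(ids)]

    rng = np.random.default_rng(config.seed)
    boot_orders: list[list[str]] = []
    for _ in range(config.bootstrap_B):
        cols = rng.integers(matrix.n_hybrids, size=matrix.n_hybrids)
        bm = GenotypeMatrix(
            marker_ids=list(matrix.marker_ids),
            hybrid_ids=[f"b{k}" for k in range(matrix.n_hybrids)],
            calls=matrix.calls[:, cols],
        )
        scorer = _GroupScorer(bm, ids)

        def score_fn(idx, order, tol=1e-4, max_sweeps=100):
            return scorer.score_idx(idx, tol, max_sweeps) / LN10 - (
                config.lambda_penalty * count_breakpoints(order, config.reference_order)
            )

        ref_idx = [scorer.ids.index(m) for m in ref]
        bidx, _ = _local_refine_idx(scorer, ref_idx, score_fn)
        boot_orders.append([scorer.ids[k] for k in bidx])

    def agreement(subset: set[str]) -> float:
        base_sub = _canonical([m for m in base_order if m in subset])
        hits = sum(
            1
            for bo in boot_orders
            if _canonical([m for m in bo if m in subset]) == base_sub
        )
        return hits / len(boot_orders)

    subset = set(base_order)
    while len(subset) > 2 and agreement(subset) < config.robust_conf:
        scored = [(agreement(subset - {m}), m) for m in sorted(subset)]
        _, marker = max(scored, key=lambda t: (t[0], t[1]))
        subset.discard(marker)

    robust = set(subset) if agreement(subset) >= config.robust_conf else set()
    # markers with identical call rows carry no information about their
    # mutual order: keep at most one of each identical group robust
    by_row: dict[bytes, list[str]] = {}
    for m in base_order:
        by_row.setdefault(matrix.row(m).tobytes(), []).append(m)
    for group_ids in by_row.values():
        dup_robust = sorted(m for m in group_ids if m in robust)
        for m in dup_robust[1:]:
            robust.discard(m)
    base.status = {m: ("robust" if m in robust else "nonrobust") for m in base_order}
    base.diagnostics["bootstrap_B"] = config.bootstrap_B
    base.diagnostics["robust_agreement"] = agreement(subset) if robust else 0.0
    return base


# ---------------------------------------------------------------------------
# centromere hint

def centromere_hint(
    matrix: GenotypeMatrix,
    rh_map: RHMapResult,
    excess_threshold: float = 0.05,
    window: int = 3,
) -> str | None:
    """Marker at the retention peak along the map, if the peak is real.

    Retention rises near centromeres, so a smoothed (moving-average)
    per-marker retention profile peaking clearly above the map's median
    retention hints at the centromere position.  Returns None for flat or
    uniformly high profiles.
    """
    ids = rh_map.marker_ids
    if len(ids) < window:
        return None
    f = np.array([marker_retention(matrix.row(m), m).f for m in ids])
    smoothed = np.convolve(f, np.ones(window) / window, mode="valid")
    k = int(np.argmax(smoothed))
    if smoothed[k] - float(np.median(f)) <= excess_threshold:
        return None
    return ids[k + window // 2]
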