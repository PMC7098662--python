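"""Detection of periodically expressed genes in synchronized time courses.

Two nonparametric tests are run on every gene's expression series:

* a JTK-style test — Kendall rank correlation (tau-b) between the series and
  discretized cosine reference waveforms over a grid of periods (in sample
  units) and phase lags;
* a RAIN-style umbrella test — a Jonckheere–Terpstra-type statistic for a
  monotone rise to a candidate peak phase followed by a monotone fall, taken
  circularly within one period and evaluated over a grid of peak phases and
  rise/fall asymmetries.

Both statistics are linear forms in the pairwise order signs of the series,
so their permutation nulls are shared across genes (for series without ties)
and are computed once per parameter set.  Series of length <= 7 use the exact
null over all n! permutations.  Per-gene significance is reported after a
multiplicity adjustment over the waveform/phase grid: either a permutation
minP adjustment (default; calibrated under the null) or Bonferroni
(conservative, because the grid hypotheses are strongly correlated).

Genes are then ranked per test on Benjamini–Hochberg adjusted p-values, the
two ranks are summed into a combined rank, and the periodic set is selected
by a dual cutoff: combined rank below a loose cutoff in each replicate and
within the strict-cutoff best of the replicate-averaged dataset.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("cycletx.periodicity")

__all__ = [
    "ExpressionTimeCourse",
    "PeriodicityParams",
    "SelectionRule",
    "filter_expressed",
    "zscore_normalize",
    "average_replicates",
    "jtk_pvalue",
    "jtk_waveform_pvalues",
    "rain_pvalue",
    "rain_waveform_pvalues",
    "periodicity_pvalues",
    "rank_and_combine",
    "select_periodic",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTimeCourse:
    """A genes x time-points expression matrix for one replicate.

    ``values`` holds tpm (non-negative) unless ``normalized`` is set, in
    which case rows are dimensionless z-scores.  ``times`` are hours since
    release and must be strictly increasing.
    """

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    replicate_label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x times matrix")
        if self.values.shape != (len(self.gene_ids), len(self.times)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.times)} times"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.normalized and np.any(self.values < 0):
            raise ValueError("tpm values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"t{t:.2f}" for t in self.times]
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=cols)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass(frozen=True)
class PeriodicityParams:
    """Parameters of the two rank tests.

    Periods are counted in samples, not hours: with 0.75 h spacing the
    default grid 14–16 samples spans 10.5–12 h, bracketing one cell cycle.
    """

    period_grid_samples: tuple[int, ...] = (14, 15, 16)
    rain_period_samples: int = 16
    sample_interval_hours: float = 0.75
    n_permutations: int = 20000
    seed: int = 0
    combine: str = "minp"          # "minp" | "bonferroni"
    method: str = "auto"           # "auto" | "exact" | "permutation" | "normal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "period_grid_samples", tuple(self.period_grid_samples))
        if any(p < 4 for p in self.period_grid_samples):
            raise ValueError("all periods must span at least 4 samples")
        if self.rain_period_samples < 4:
            raise ValueError("rain period must span at least 4 samples")
        if self.n_permutations < 1000:
            raise ValueError("n_permutations must be >= 1000")
        if self.combine not in ("minp", "bonferroni"):
            raise ValueError(f"unknown combine mode {self.combine!r}")
        if self.method not in ("auto", "exact", "permutation", "normal"):
            raise ValueError(f"unknown method {self.method!r}")

    def resolved_method(self, n_samples: int) -> str:
        if self.method == "auto":
            return "exact" if n_samples <= 7 else "permutation"
        return self.method


@dataclass
class TestResult:
    """Combined p-value for one gene under one test, with the best waveform."""

    p: float
    best_period: int | None = None
    best_lag: int | None = None
    tau: float | None = None
    best_peak: int | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------

def filter_expressed(tc: ExpressionTimeCourse, threshold: float = 1.0) -> ExpressionTimeCourse:
    """Retain genes whose mean expression over the series is strictly above
    ``threshold`` (tpm)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = tc.values.mean(axis=1) > threshold
    if not keep.any():
        logger.warning("filter_expressed: no gene above %g tpm", threshold)
    return ExpressionTimeCourse(
        gene_ids=[g for g, k in zip(tc.gene_ids, keep) if k],
        times=tc.times,
        values=tc.values[keep],
        replicate_label=tc.replicate_label,
        normalized=tc.normalized,
    )


def zscore_normalize(tc: ExpressionTimeCourse) -> ExpressionTimeCourse:
    """Center each gene to mean 0 and scale to unit population SD
    (divide by sqrt(mean squared deviation), i.e. ddof=0)."""
    mu = tc.values.mean(axis=1, keepdims=True)
    sd = tc.values.std(axis=1, ddof=0, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        names = [tc.gene_ids[i] for i in flat[:5]]
        raise ValueError(f"constant expression rows (zero SD): {names}")
    return ExpressionTimeCourse(
        gene_ids=tc.gene_ids,
        times=tc.times,
        values=(tc.values - mu) / sd,
        replicate_label=tc.replicate_label,
        normalized=True,
    )


def average_replicates(tcs: list[ExpressionTimeCourse]) -> ExpressionTimeCourse:
    """Element-wise arithmetic mean of tpm across replicates sharing one gene
    set and time grid."""
    if not tcs:
        raise ValueError("no replicates given")
    first = tcs[0]
    for tc in tcs[1:]:
        if tc.gene_ids != first.gene_ids:
            a, b = set(first.gene_ids), set(tc.gene_ids)
            diff = sorted(a.symmetric_difference(b))
            raise ValueError(f"replicate gene sets differ; symmetric difference: {diff}")
        if not np.allclose(tc.times, first.times):
            raise ValueError("replicate time grids differ")
    mean = np.mean([tc.values for tc in tcs], axis=0)
    return ExpressionTimeCourse(
        gene_ids=first.gene_ids,
        times=first.times,
        values=mean,
        replicate_label="average",
        normalized=first.normalized,
    )


# ---------------------------------------------------------------------------
# pairwise-sign machinery shared by both tests
# ---------------------------------------------------------------------------

def _pair_idx(n: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(n, k=1)
    return i, j


def _pair_signs(X: np.ndarray) -> np.ndarray:
    """sign(x_j - x_i) over all ordered pairs i<j; X is (m, n)."""
    i, j = _pair_idx(X.shape[1])
    return np.sign(X[:, j] - X[:, i])


def _cosine_references(n_samples: int, periods: tuple[int, ...]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    refs, meta = [], []
    t = np.arange(n_samples)
    for period in periods:
        for lag in range(period):
            refs.append(np.cos(2 * np.pi * (t - lag) / period))
            meta.append((period, lag))
    return np.asarray(refs), meta


def _umbrella_weights(n_samples: int, period: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Circular umbrella contrast vectors over pair signs.

    For peak phase k and trough phase m, expression is modelled as rising
    monotonically along the circle from m to k and falling from k to m; the
    statistic is the tie-aware count of concordant minus discordant pairs
    within each arm.  Trough offsets range over period/4 .. 3*period/4,
    admitting asymmetric rise/fall shapes.
    """
    i_idx, j_idx = _pair_idx(n_samples)
    pair_pos = {(int(a), int(b)): r for r, (a, b) in enumerate(zip(i_idx, j_idx))}
    lo = max(2, int(round(period / 4)))
    hi = min(period - 2, int(round(3 * period / 4)))
    weights, meta = [], []
    for peak in range(period):
        for off in range(lo, hi + 1):
            trough = (peak + off) % period
            w = np.zeros(len(pair_pos))
            for start, stop, sgn in ((trough, peak, 1.0), (peak, trough, -1.0)):
                arc = []
                s = start
                while True:
                    if s < n_samples:
                        arc.append(s)
                    if s == stop:
                        break
                    s = (s + 1) % period
                for a in range(len(arc)):
                    for b in range(a + 1, len(arc)):
                        x, y = arc[a], arc[b]
                        r = pair_pos[(min(x, y), max(x, y))]
                        concordant = (arc.index(x) < arc.index(y)) == (x < y)
                        w[r] += sgn * (1.0 if concordant else -1.0)
            weights.append(w)
            meta.append((peak, trough))
    return np.asarray(weights), meta


@lru_cache(maxsize=8)
def _permutation_signs(n_samples: int, n_perm: int, seed: int, exact: bool) -> np.ndarray:
    """Pair-sign matrix of permutations of 0..n-1 (all n! if exact)."""
    if exact:
        perms = np.array(list(itertools.permutations(range(n_samples))), dtype=float)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n_samples) for _ in range(n_perm)], dtype=float)
    return _pair_signs(perms)


class _GridNull:
    """Shared permutation null for a bank of linear pair-sign statistics."""

    def __init__(self, contrasts: np.ndarray, n_samples: int, params: PeriodicityParams):
        self.contrasts = contrasts           # (W, npairs)
        self.n_samples = n_samples
        self.method = params.resolved_method(n_samples)
        self.exact = self.method == "exact"
        if self.method == "normal":
            self.sd = np.sqrt(self._exact_variances(contrasts, n_samples))
            return
        ps = _permutation_signs(n_samples, params.n_permutations, params.seed, self.exact)
        self.m = ps.shape[0]
        null_s = ps @ contrasts.T                       # (M, W)
        self.sorted_null = np.sort(null_s, axis=0)
        # per-permutation per-waveform p (self-inclusive), then min across grid
        null_p = self._tail_fraction(null_s)
        self.sorted_min_p = np.sort(null_p.min(axis=1))

    @staticmethod
    def _exact_variances(contrasts: np.ndarray, n: int) -> np.ndarray:
        """Var(S_w) under a uniform random permutation of an untied series.

        Uses exact second moments of pair signs: E[s_r^2] = 1; for pairs
        sharing one sample the moment is +1/3 when the shared sample is at the
        same end of both pairs, -1/3 otherwise; disjoint pairs contribute 0.
        """
        i, j = _pair_idx(n)
        npairs = i.size
        m2 = np.zeros((npairs, npairs))
        for r in range(npairs):
            for q in range(npairs):
                if r == q:
                    m2[r, q] = 1.0
                    continue
                a, b, c, d = i[r], j[r], i[q], j[q]
                shared = {a, b} & {c, d}
                if not shared:
                    continue
                # s_ij = sign(x_j - x_i): shared tail (i==k) or shared head
                # (j==l) is concordant-anchored (+1/3); head-to-tail is -1/3
                if (a == c) or (b == d):
                    m2[r, q] = 1.0 / 3.0
                else:
                    m2[r, q] = -1.0 / 3.0
        return np.einsum("wr,rq,wq->w", contrasts, m2, contrasts)

    def _tail_fraction(self, s: np.ndarray) -> np.ndarray:
        """P_hat(S_null >= s) per waveform column, denominator m."""
        out = np.empty_like(s, dtype=float)
        for c in range(s.shape[1]):
            idx = np.searchsorted(self.sorted_null[:, c], s[:, c], side="left")
            out[:, c] = (self.m - idx) / self.m
        return out

    def waveform_pvalues(self, s_obs: np.ndarray) -> np.ndarray:
        """Per-waveform one-sided p-values for observed statistics (G, W).

        Exact mode: the enumeration tail fraction itself (matches a full
        permutation enumeration bit for bit).  Permutation mode: add-one
        smoothed so p in (0, 1].
        """
        if self.method == "normal":
            from scipy.stats import norm
            return norm.sf(s_obs / self.sd[None, :])
        frac = self._tail_fraction(s_obs)
        if self.exact:
            return frac
        return (frac * self.m + 1) / (self.m + 1)

    def combined_pvalues(self, s_obs: np.ndarray, combine: str) -> tuple[np.ndarray, np.ndarray]:
        """Grid-adjusted p per gene and the per-waveform p matrix."""
        pw = self.waveform_pvalues(s_obs)
        if combine == "bonferroni" or self.method == "normal":
            n_hyp = np.unique(self.contrasts, axis=0).shape[0]
            return np.minimum(pw.min(axis=1) * n_hyp, 1.0), pw
        # minP: compare the observed min tail fraction with its permutation null
        min_frac = self._tail_fraction(s_obs).min(axis=1)
        idx = np.searchsorted(self.sorted_min_p, min_frac, side="right")
        if self.exact:
            p = idx / self.m
        else:
            p = (idx + 1) / (self.m + 1)
        return p, pw


@lru_cache(maxsize=8)
def _jtk_bank(n_samples: int, params: PeriodicityParams):
    refs, meta = _cosine_references(n_samples, params.period_grid_samples)
    contrasts = _pair_signs(refs)
    return _GridNull(contrasts, n_samples, params), refs, meta


@lru_cache(maxsize=8)
def _rain_bank(n_samples: int, params: PeriodicityParams):
    contrasts, meta = _umbrella_weights(n_samples, params.rain_period_samples)
    return _GridNull(contrasts, n_samples, params), meta


def _row_null_pvalue(row: np.ndarray, contrasts: np.ndarray, params: PeriodicityParams,
                     combine: str) -> tuple[float, np.ndarray]:
    """Dedicated permutation null for a tied series (ties break the shared-null
    shortcut); permutes the observed values themselves."""
    n = row.size
    exact = params.resolved_method(n) == "exact"
    if exact:
        perms = np.array(list(itertools.permutations(row)))
    else:
        rng = np.random.default_rng(params.seed + 1)
        m = params.n_permutations
        perms = row[np.argsort(rng.random((m, n)), axis=1)]
    null_s = _pair_signs(perms) @ contrasts.T
    s_obs = (_pair_signs(row[None, :]) @ contrasts.T)[0]
    m = null_s.shape[0]
    tail = (null_s >= s_obs[None, :] - 1e-12).mean(axis=0)
    if exact:
        pw = tail
    else:
        pw = (tail * m + 1) / (m + 1)
    if combine == "bonferroni":
        n_hyp = np.unique(contrasts, axis=0).shape[0]
        return float(min(pw.min() * n_hyp, 1.0)), pw
    null_tail = np.empty_like(null_s)
    order = np.sort(null_s, axis=0)
    for c in range(null_s.shape[1]):
        null_tail[:, c] = (m - np.searchsorted(order[:, c], null_s[:, c], side="left")) / m
    null_min = np.sort(null_tail.min(axis=1))
    idx = np.searchsorted(null_min, tail.min(), side="right")
    p = idx / m if exact else (idx + 1) / (m + 1)
    return float(p), pw


def _tau_b(series: np.ndarray, ref: np.ndarray) -> float:
    ss = _pair_signs(series[None, :])[0]
    rs = _pair_signs(ref[None, :])[0]
    s = float(ss @ rs)
    n0 = ss.size
    t1 = n0 - float(np.sum(ss != 0))
    t2 = n0 - float(np.sum(rs != 0))
    denom = math.sqrt((n0 - t1) * (n0 - t2))
    return s / denom if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# the two tests
# ---------------------------------------------------------------------------

def _is_degenerate(series: np.ndarray) -> bool:
    return bool(np.all(series == series[0]))


def _best_waveform(pw: np.ndarray, s_obs: np.ndarray, contrasts: np.ndarray) -> int:
    """Best grid hypothesis: minimal p, ties broken by the largest
    norm-standardized statistic (the permutation p floors at 1/(M+1), so
    several waveforms can share the minimum)."""
    norm = s_obs / np.linalg.norm(contrasts, axis=1)
    tied = pw <= pw.min() + 1e-15
    idx = np.flatnonzero(tied)
    return int(idx[np.argmax(norm[idx])])


def jtk_waveform_pvalues(series: np.ndarray, params: PeriodicityParams) -> pd.DataFrame:
    """Per-waveform one-sided p-values of the cosine-correlation statistic,
    one row per (period, lag); exact for series length <= 7."""
    series = np.asarray(series, dtype=float)
    bank, refs, meta = _jtk_bank(series.size, params)
    if _is_degenerate(series):
        pw = np.ones(len(meta))
    elif np.unique(series).size < series.size:
        _, pw = _row_null_pvalue(series, bank.contrasts, params, params.combine)
    else:
        s_obs = _pair_signs(series[None, :]) @ bank.contrasts.T
        pw = bank.waveform_pvalues(s_obs)[0]
    return pd.DataFrame({"period": [m[0] for m in meta], "lag": [m[1] for m in meta], "p": pw})


def rain_waveform_pvalues(series: np.ndarray, params: PeriodicityParams) -> pd.DataFrame:
    """Per-(peak, trough) umbrella p-values; exact for series length <= 7."""
    series = np.asarray(series, dtype=float)
    bank, meta = _rain_bank(series.size, params)
    if _is_degenerate(series):
        pw = np.ones(len(meta))
    elif np.unique(series).size < series.size:
        _, pw = _row_null_pvalue(series, bank.contrasts, params, params.combine)
    else:
        s_obs = _pair_signs(series[None, :]) @ bank.contrasts.T
        pw = bank.waveform_pvalues(s_obs)[0]
    return pd.DataFrame({"peak": [m[0] for m in meta], "trough": [m[1] for m in meta], "p": pw})


def jtk_pvalue(series: np.ndarray, params: PeriodicityParams | None = None) -> TestResult:
    """Grid-adjusted JTK-style p-value with the best (period, lag, tau)."""
    params = params or PeriodicityParams()
    series = np.asarray(series, dtype=float)
    if series.size < 4:
        raise ValueError("series must have at least 4 samples")
    if _is_degenerate(series):
        return TestResult(p=1.0, degenerate=True)
    bank, refs, meta = _jtk_bank(series.size, params)
    s_obs = _pair_signs(series[None, :]) @ bank.contrasts.T
    if np.unique(series).size < series.size:
        p, pw = _row_null_pvalue(series, bank.contrasts, params, params.combine)
    else:
        p_arr, pw_mat = bank.combined_pvalues(s_obs, params.combine)
        p, pw = float(p_arr[0]), pw_mat[0]
    best = _best_waveform(pw, s_obs[0], bank.contrasts)
    period, lag = meta[best]
    return TestResult(p=p, best_period=period, best_lag=lag,
                      tau=_tau_b(series, refs[best]))


def rain_pvalue(series: np.ndarray, params: PeriodicityParams | None = None) -> TestResult:
    """Grid-adjusted umbrella p-value with the best peak phase."""
    params = params or PeriodicityParams()
    series = np.asarray(series, dtype=float)
    if series.size < 4:
        raise ValueError("series must have at least 4 samples")
    if _is_degenerate(series):
        return TestResult(p=1.0, degenerate=True)
    bank, meta = _rain_bank(series.size, params)
    s_obs = _pair_signs(series[None, :]) @ bank.contrasts.T
    if np.unique(series).size < series.size:
        p, pw = _row_null_pvalue(series, bank.contrasts, params, params.combine)
    else:
        p_arr, pw_mat = bank.combined_pvalues(s_obs, params.combine)
        p, pw = float(p_arr[0]), pw_mat[0]
    best = _best_waveform(pw, s_obs[0], bank.contrasts)
    return TestResult(p=p, best_peak=meta[best][0])


def periodicity_pvalues(tc: ExpressionTimeCourse,
                        params: PeriodicityParams | None = None) -> pd.DataFrame:
    """Both tests for every gene of a time course (vectorized over genes).

    Rows without ties share one precomputed permutation null; tied rows fall
    back to a per-row permutation of their own values, and constant rows get
    p = 1 with a degenerate flag.
    """
    params = params or PeriodicityParams()
    n = tc.n_times
    jbank, refs, jmeta = _jtk_bank(n, params)
    rbank, rmeta = _rain_bank(n, params)

    vals = tc.values
    has_tie = np.array([np.unique(v).size < n for v in vals])
    degenerate = np.array([_is_degenerate(v) for v in vals])

    p_jtk = np.ones(tc.n_genes)
    p_rain = np.ones(tc.n_genes)
    best_period = np.zeros(tc.n_genes, dtype=int)
    best_lag = np.zeros(tc.n_genes, dtype=int)
    best_tau = np.zeros(tc.n_genes)
    best_peak = np.zeros(tc.n_genes, dtype=int)

    clean = ~has_tie
    if clean.any():
        signs = _pair_signs(vals[clean])
        s_j = signs @ jbank.contrasts.T
        s_r = signs @ rbank.contrasts.T
        pj, pwj = jbank.combined_pvalues(s_j, params.combine)
        pr, pwr = rbank.combined_pvalues(s_r, params.combine)
        idx = np.flatnonzero(clean)
        p_jtk[idx] = pj
        p_rain[idx] = pr
        bj = [_best_waveform(pwj[r], s_j[r], jbank.contrasts) for r in range(len(idx))]
        br = [_best_waveform(pwr[r], s_r[r], rbank.contrasts) for r in range(len(idx))]
        best_period[idx] = [jmeta[b][0] for b in bj]
        best_lag[idx] = [jmeta[b][1] for b in bj]
        best_tau[idx] = [_tau_b(vals[i], refs[b]) for i, b in zip(idx, bj)]
        best_peak[idx] = [rmeta[b][0] for b in br]

    for i in np.flatnonzero(has_tie & ~degenerate):
        rj = jtk_pvalue(vals[i], params)
        rr = rain_pvalue(vals[i], params)
        p_jtk[i], p_rain[i] = rj.p, rr.p
        best_period[i], best_lag[i] = rj.best_period, rj.best_lag
        best_tau[i], best_peak[i] = rj.tau, rr.best_peak

    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("periodicity_pvalues: %d constant (degenerate) rows, p set to 1", n_deg)

    return pd.DataFrame({
        "gene_id": tc.gene_ids,
        "p_jtk": p_jtk,
        "p_rain": p_rain,
        "best_period": best_period,
        "best_lag": best_lag,
        "tau": best_tau,
        "best_peak": best_peak,
        "degenerate": degenerate,
    })


# ---------------------------------------------------------------------------
# ranking and selection
# ---------------------------------------------------------------------------

def rank_and_combine(p_jtk: pd.Series, p_rain: pd.Series) -> pd.DataFrame:
    """Benjamini–Hochberg within each test, rank on adjusted values ascending
    (ties by raw p, then gene id), and sum the two ranks.

    Inputs are per-gene p-value Series indexed by gene id over one common
    universe; returns the periodicity table with one row per gene.
    """
    if set(p_jtk.index) != set(p_rain.index):
        missing = sorted(set(p_jtk.index).symmetric_difference(p_rain.index))
        raise ValueError(f"gene universes differ between tests: {missing[:5]}")
    if p_jtk.isna().any() or p_rain.isna().any():
        raise ValueError("missing p-values")
    genes = sorted(p_jtk.index)
    p_jtk = p_jtk.loc[genes]
    p_rain = p_rain.loc[genes]
    q_jtk = pd.Series(multipletests(p_jtk.to_numpy(), method="fdr_bh")[1], index=genes)
    q_rain = pd.Series(multipletests(p_rain.to_numpy(), method="fdr_bh")[1], index=genes)

    def _rank(q: pd.Series, p: pd.Series) -> pd.Series:
        order = sorted(genes, key=lambda g: (q[g], p[g], g))
        return pd.Series({g: r + 1 for r, g in enumerate(order)})

    rank_jtk = _rank(q_jtk, p_jtk)
    rank_rain = _rank(q_rain, p_rain)
    table = pd.DataFrame({
        "gene_id": genes,
        "p_jtk": p_jtk.to_numpy(),
        "q_jtk": q_jtk.to_numpy(),
        "rank_jtk": rank_jtk.loc[genes].to_numpy(),
        "p_rain": p_rain.to_numpy(),
        "q_rain": q_rain.to_numpy(),
        "rank_rain": rank_rain.loc[genes].to_numpy(),
    })
    table["combined_rank"] = table["rank_jtk"] + table["rank_rain"]
    table["selected"] = False
    return table


@dataclass
class SelectionRule:
    """Dual-cutoff selection: loose per-replicate rank cutoff, strict cutoff
    on the replicate-averaged dataset, plus manual include/exclude lists."""

    loose_cutoff: int = 2000
    strict_cutoff: int = 800
    manual_include: tuple[str, ...] = ()
    manual_exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strict_cutoff > self.loose_cutoff:
            raise ValueError("strict_cutoff must be <= loose_cutoff")
        self.manual_include = tuple(self.manual_include)
        self.manual_exclude = tuple(self.manual_exclude)


def select_periodic(table_rep1: pd.DataFrame, table_rep2: pd.DataFrame,
                    table_avg: pd.DataFrame, rule: SelectionRule) -> list[str]:
    """Select the periodic gene set.

    Candidates pass the loose combined-rank cutoff in both replicates; the
    strict-cutoff best candidates by average-dataset combined rank are kept,
    then manual includes are added and manual excludes removed.  Returns gene
    ids ordered by average-dataset combined rank.
    """
    universe = set(table_avg["gene_id"])
    for t in (table_rep1, table_rep2):
        if set(t["gene_id"]) != universe:
            raise ValueError("selection tables must share one gene universe")
    for g in rule.manual_include:
        if g not in universe:
            raise ValueError(f"manual_include gene {g!r} absent from the universe")

    cr1 = dict(zip(table_rep1["gene_id"], table_rep1["combined_rank"]))
    cr2 = dict(zip(table_rep2["gene_id"], table_rep2["combined_rank"]))
    avg = dict(zip(table_avg["gene_id"], table_avg["combined_rank"]))

    candidates = [g for g in universe
                  if cr1[g] <= rule.loose_cutoff and cr2[g] <= rule.loose_cutoff]
    candidates.sort(key=lambda g: (avg[g], g))
    selected = candidates[: rule.strict_cutoff]
    for g in rule.manual_include:
        if g not in selected:
            selected.append(g)
    selected = [g for g in selected if g not in set(rule.manual_exclude)]
    selected.sort(key=lambda g: (avg[g], g))
    return selected
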