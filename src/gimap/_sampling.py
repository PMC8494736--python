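"""Low-level randomization engines.

Two primitives live here:

* a curveball Markov chain that samples binary matrices uniformly from the
  space of matrices with the observed row and column sums (the fixed-margin
  null), and
* a weighted without-replacement row resampler (exponential-race
  construction, distribution-identical to sequential draws with weight
  renormalization) used by the WeSME-style test.

The curveball trade loop is JIT-compiled with numba; everything else is
vectorized numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["CurveballChain", "weighted_wor_draws"]


@njit(cache=True)
def _seed_numba(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _curveball_trades(rows, deg, n_trades, mark, shared, pool, stamp0):
    """Perform ``n_trades`` curveball trades in place.

    ``rows`` is an (n_rows, max_deg) int32 array of column indices padded
    with -1; ``deg`` the per-row degree.  A trade picks two distinct rows
    and randomly redistributes their non-shared column indices, which
    preserves all row and column sums.
    """
    n_rows = rows.shape[0]
    stamp = stamp0
    for _ in range(n_trades):
        i = np.random.randint(0, n_rows)
        j = np.random.randint(0, n_rows - 1)
        if j >= i:
            j += 1
        di = deg[i]
        dj = deg[j]
        stamp += 1
        for a in range(di):
            mark[rows[i, a]] = stamp
        nshared = 0
        npool = 0
        for b in range(dj):
            c = rows[j, b]
            if mark[c] == stamp:
                shared[nshared] = c
                nshared += 1
                mark[c] = stamp - 1  # unmark: leftovers are i-only
            else:
                pool[npool] = c
                npool += 1
        for a in range(di):
            c = rows[i, a]
            if mark[c] == stamp:
                pool[npool] = c
                npool += 1
        ai = di - nshared  # columns row i draws from the pool
        for a in range(ai):
            r = a + np.random.randint(0, npool - a)
            tmp = pool[a]
            pool[a] = pool[r]
            pool[r] = tmp
        for a in range(nshared):
            rows[i, a] = shared[a]
            rows[j, a] = shared[a]
        for a in range(ai):
            rows[i, nshared + a] = pool[a]
        for b in range(npool - ai):
            rows[j, nshared + b] = pool[ai + b]
    return stamp


class CurveballChain:
    """Curveball MCMC over binary matrices with fixed margins.

    Parameters
    ----------
    X : bool ndarray (n_rows, n_cols)
        Starting matrix; margins of every sampled matrix equal its margins.
    rng : numpy Generator
        Drives the chain (numba's RNG is re-seeded from it each step).
    burn_in, thin : int, optional
        Trades before the first sample and between samples.  Defaults:
        5x and 1x the number of 1-entries.
    """

    def __init__(self, X: np.ndarray, rng: np.random.Generator,
                 burn_in: int | None = None, thin: int | None = None) -> None:
        X = np.asarray(X, dtype=bool)
        self.shape = X.shape
        self.rng = rng
        n_ones = int(X.sum())
        self.burn_in = int(5 * n_ones) if burn_in is None else int(burn_in)
        self.thin = max(1, n_ones) if thin is None else int(thin)
        deg = X.sum(axis=1).astype(np.int32)
        max_deg = int(deg.max()) if deg.size else 0
        rows = np.full((X.shape[0], max(max_deg, 1)), -1, dtype=np.int32)
        for i in range(X.shape[0]):
            cols = np.flatnonzero(X[i])
            rows[i, : len(cols)] = cols
        self._rows = rows
        self._deg = deg
        self._mark = np.zeros(X.shape[1], dtype=np.int64)
        self._shared = np.empty(max(max_deg, 1), dtype=np.int32)
        self._pool = np.empty(max(2 * max_deg, 1), dtype=np.int32)
        self._stamp = 0
        self._burned = False
        # trades are only possible with >= 2 rows
        self._mixable = X.shape[0] >= 2 and n_ones > 0

    def step(self, n_trades: int | None = None) -> None:
        """Advance the chain by ``n_trades`` trades (default: thinning)."""
        if not self._mixable:
            return
        n = self.thin if n_trades is None else int(n_trades)
        if n <= 0:
            return
        _seed_numba(int(self.rng.integers(0, 2**31 - 1)))
        self._stamp = _curveball_trades(
            self._rows, self._deg, n, self._mark,
            self._shared, self._pool, self._stamp,
        )

    def sample(self) -> np.ndarray:
        """Burn in (first call) or thin, then return the current matrix."""
        if not self._burned:
            self.step(self.burn_in)
            self._burned = True
        else:
            self.step(self.thin)
        return self.dense()

    def dense(self) -> np.ndarray:
        """Current state as a dense boolean matrix."""
        n_rows, n_cols = self.shape
        out = np.zeros(n_rows * n_cols, dtype=bool)
        mask = np.arange(self._rows.shape[1]) < self._deg[:, None]
        flat = (np.repeat(np.arange(n_rows), self._deg)
                * n_cols + self._rows[mask])
        out[flat] = True
        return out.reshape(n_rows, n_cols)


@njit(cache=True)
def _wor_membership(margins, inv_w, cum_w, n_draws):  # pragma: no cover
    # Two equivalent samplers per gene row, both realizing sequential
    # weighted sampling without replacement:
    #  - small k: rejection sampling from the cumulative weight table
    #    (a rejected duplicate is a draw from the renormalized remainder),
    #  - large k: exponential race keys with a streaming top-k max-heap.
    n_genes = margins.size
    n_samples = inv_w.size
    total_w = cum_w[n_samples - 1]
    out = np.zeros((n_draws, n_genes, n_samples), dtype=np.bool_)
    kmax = 0
    for g in range(n_genes):
        if margins[g] > kmax:
            kmax = margins[g]
    heap_key = np.empty(max(kmax, 1), dtype=np.float64)
    heap_idx = np.empty(max(kmax, 1), dtype=np.int64)
    for d in range(n_draws):
        for g in range(n_genes):
            k = margins[g]
            if k == 0:
                continue
            if k >= n_samples:
                out[d, g, :] = True
                continue
            if 4 * k <= n_samples:
                picked = 0
                misses = 0
                while picked < k and misses < 64:
                    u = np.random.random() * total_w
                    s = np.searchsorted(cum_w, u, side="right")
                    if s >= n_samples:
                        s = n_samples - 1
                    if out[d, g, s]:
                        misses += 1
                    else:
                        out[d, g, s] = True
                        picked += 1
                        misses = 0
                if picked == k:
                    continue
                # pathological rejection rate: restart row via race keys
                for s in range(n_samples):
                    out[d, g, s] = False
            n = 0
            for s in range(n_samples):
                key = np.random.exponential() * inv_w[s]
                if n < k:
                    # push and sift up
                    i = n
                    heap_key[i] = key
                    heap_idx[i] = s
                    n += 1
                    while i > 0:
                        parent = (i - 1) >> 1
                        if heap_key[parent] < heap_key[i]:
                            heap_key[parent], heap_key[i] = (
                                heap_key[i], heap_key[parent])
                            heap_idx[parent], heap_idx[i] = (
                                heap_idx[i], heap_idx[parent])
                            i = parent
                        else:
                            break
                elif key < heap_key[0]:
                    # replace the root and sift down
                    heap_key[0] = key
                    heap_idx[0] = s
                    i = 0
                    while True:
                        left = 2 * i + 1
                        if left >= k:
                            break
                        big = left
                        right = left + 1
                        if right < k and heap_key[right] > heap_key[left]:
                            big = right
                        if heap_key[big] > heap_key[i]:
                            heap_key[big], heap_key[i] = (
                                heap_key[i], heap_key[big])
                            heap_idx[big], heap_idx[i] = (
                                heap_idx[i], heap_idx[big])
                            i = big
                        else:
                            break
            for i in range(k):
                out[d, g, heap_idx[i]] = True
    return out


def weighted_wor_draws(margins: np.ndarray, weights: np.ndarray,
                       n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Draw resampled mutated-sample sets for many genes at once.

    For each draw and each gene ``g`` with margin ``k_g``, selects ``k_g``
    distinct samples with probability proportional to ``weights`` without
    replacement (exponential-race keys ``E_s ~ Exp(w_s)``; taking the k
    smallest reproduces sequential weighted sampling with renormalization).

    Returns a bool array of shape ``(n_draws, n_genes, n_samples)``.
    """
    margins = np.asarray(margins, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(margins > np.count_nonzero(weights > 0)):
        raise ValueError(
            "gene margin exceeds the number of positive-weight samples"
        )
    with np.errstate(divide="ignore"):
        inv_w = np.where(weights > 0, 1.0 / weights, np.inf)
    _seed_numba(int(rng.integers(0, 2**31 - 1)))
    return _wor_membership(margins, inv_w, np.cumsum(weights),
                           int(n_draws))
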