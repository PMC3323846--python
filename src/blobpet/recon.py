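"""ML-EM reconstruction on blob coefficients with a wedge-folded SRM.

The measured coincidence counts y_d per LOR are modelled as independent
Poisson variables with mean q_d = sum_b p_{d,b} c_b.  The expectation-
maximization update

    c_b' = (c_b / s_b) * sum_d p_{d,b} * y_d / q_d,     s_b = sum_d p_{d,b}

monotonically increases the Poisson log-likelihood sum_d (y_d ln q_d - q_d)
and preserves non-negativity.  All sums range over every blob/LOR through
symmetry unfolding: with p_{d,T(b0)} = p_{T^-1(d),b0}, the forward
projection gathers the folded matrix across all group transforms

    q = sum_T  Perm_T^-1 ( S @ c_T ),

where c_T collects the coefficients of blobs whose stored transform is T,
and the backprojection is the adjoint sum.

Two backprojection strategies mirror how a scattering operation can be made
safe against lost updates: 'transpose' iterates a blob-ordered (transposed)
copy of the SRM, while 'scatter' iterates the LOR-ordered rows in
independent chunks with chunk-local accumulators merged by summation
(optionally in a seeded random chunk order).  Both are exact adjoints of
the forward projection up to floating-point summation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .blobgrid import BlobImage
from .geometry import SymmetryLUT, lor_count
from .srm import SparseSRM, transpose_srm

logger = logging.getLogger("blobpet")

Q_FLOOR = 1e-300


@dataclass
class LORHistogram:
    """Non-negative integer coincidence counts per LOR."""

    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if self.y.ndim != 1:
            raise ValueError("histogram must be one-dimensional")
        if np.any(self.y < 0):
            raise ValueError("coincidence counts must be non-negative")


@dataclass
class ReconState:
    """Coefficients plus per-iteration bookkeeping from :func:`run_mlem`."""

    c: np.ndarray
    iteration: int
    log_likelihood: list
    sensitivity: np.ndarray
    excluded_lors: list


class FoldedSystem:
    """Symmetry-aware forward/backward projector for a wedge-folded SRM.

    Precomputes, per group transform T: the LOR permutation d -> T(d), its
    inverse, and the list of blobs whose stored unfolding transform is T
    together with their wedge column slots.
    """

    def __init__(self, srm: SparseSRM, lut: SymmetryLUT):
        if srm.ordering != "lor" or not srm.wedge_folded:
            raise ValueError("FoldedSystem needs a wedge-folded LOR-ordered SRM")
        n_lor = lor_count(lut.spec)
        if srm.n_rows != n_lor:
            raise ValueError("SRM row count disagrees with the scanner spec")
        if srm.n_cols != lut.n_wedge:
            raise ValueError("SRM column count disagrees with the wedge size")
        self.srm = srm
        self.lut = lut
        self.n_lor = n_lor
        self.n_blobs = lut.grid.n_blobs
        self.n_wedge = lut.n_wedge
        self.S = srm.matrix.astype(np.float64)
        self.ST = transpose_srm(srm).matrix.astype(np.float64)

        tids = np.unique(lut.blob_tf)
        self._groups = []
        for tid in tids:
            blobs = np.nonzero(lut.blob_tf == tid)[0]
            cols = lut.wedge_col[lut.blob_canon[blobs]]
            perm = lut.lor_perms[tid]
            perm_inv = lut.lor_perms[lut.inv_ids[tid]]
            self._groups.append((int(tid), blobs, cols, perm, perm_inv))

    # -- projections ------------------------------------------------------

    def forward(self, c: np.ndarray) -> np.ndarray:
        """q_d = sum over ALL blobs of p_{d,b} c_b (gather)."""
        c = np.asarray(c, dtype=np.float64)
        if c.shape != (self.n_blobs,):
            raise ValueError("coefficient vector has the wrong length")
        q = np.zeros(self.n_lor)
        for _tid, blobs, cols, _perm, perm_inv in self._groups:
            ct = np.zeros(self.n_wedge)
            np.add.at(ct, cols, c[blobs])
            q += (self.S @ ct)[perm_inv]
        return q

    def back(self, r: np.ndarray, strategy: str = "transpose",
             n_chunks: int = 8, chunk_seed=None) -> np.ndarray:
        """b_i = sum_d p_{d,i} r_d (scatter), via the chosen strategy."""
        r = np.asarray(r, dtype=np.float64)
        if r.shape != (self.n_lor,):
            raise ValueError("LOR vector has the wrong length")
        out = np.zeros(self.n_blobs)
        for _tid, blobs, cols, perm, _perm_inv in self._groups:
            rt = r[perm]
            if strategy == "transpose":
                bt = self.ST @ rt
            elif strategy == "scatter":
                bt = self._scatter(rt, n_chunks, chunk_seed)
            else:
                raise ValueError("strategy must be 'transpose' or 'scatter'")
            out[blobs] += bt[cols]
        return out

    def _scatter(self, rt: np.ndarray, n_chunks: int, chunk_seed) -> np.ndarray:
        """Row-wise scatter over the LOR-ordered SRM with chunk-local
        accumulators; lost updates are impossible because each chunk owns
        its accumulator and the merge is a plain sum."""
        bounds = np.linspace(0, self.n_lor, n_chunks + 1).astype(np.int64)
        order = np.arange(n_chunks)
        if chunk_seed is not None:
            np.random.default_rng(chunk_seed).shuffle(order)
        acc = np.zeros(self.n_wedge)
        for k in order:
            lo, hi = bounds[k], bounds[k + 1]
            if lo == hi:
                continue
            local = self.S[lo:hi].T @ rt[lo:hi]    # chunk-local accumulator
            acc += local
        return acc

    def sensitivity(self) -> np.ndarray:
        """s_b = sum_d p_{d,b}, the ML-EM normalizer (= back of all-ones)."""
        return self.back(np.ones(self.n_lor))


def forward_project(c, srm: SparseSRM, lut: SymmetryLUT) -> np.ndarray:
    if isinstance(c, BlobImage):
        c = c.c
    return FoldedSystem(srm, lut).forward(c)


def back_project(r, srm: SparseSRM, lut: SymmetryLUT,
                 strategy: str = "transpose", **kw) -> np.ndarray:
    return FoldedSystem(srm, lut).back(r, strategy=strategy, **kw)


def sensitivity(srm: SparseSRM, lut: SymmetryLUT) -> np.ndarray:
    return FoldedSystem(srm, lut).sensitivity()


def mlem_update(c: np.ndarray, y: np.ndarray, system: FoldedSystem,
                s: np.ndarray, strategy: str = "transpose",
                chunk_seed=None):
    """One multiplicative EM step.  Returns (c', n_excluded).

    LORs with y_d > 0 but q_d below a tiny floor are excluded from the
    update (and counted) instead of clamped, which would silently bias the
    ratio.  Blobs with zero sensitivity stay exactly zero.
    """
    c = np.asarray(c, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("coefficients must be non-negative")
    q = system.forward(c)
    bad = (y > 0) & (q < Q_FLOOR)
    n_excluded = int(bad.sum())
    ratio = np.zeros_like(q)
    ok = (y > 0) & ~bad
    ratio[ok] = y[ok] / q[ok]
    bp = system.back(ratio, strategy=strategy, chunk_seed=chunk_seed)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_new = np.where(s > 0, c * bp / s, 0.0)
    return c_new, n_excluded


def poisson_loglik(y: np.ndarray, q: np.ndarray) -> float:
    """sum_d (y_d ln q_d - q_d), excluding unmodellable y>0, q=0 bins."""
    ok = q >= Q_FLOOR
    pos = ok & (y > 0)
    return float(np.sum(y[pos] * np.log(q[pos])) - np.sum(q[ok]))


def run_mlem(y, srm: SparseSRM, lut: SymmetryLUT, n_iter: int,
             init=None, strategy: str = "transpose", log_every: int = 1,
             chunk_seed=None) -> ReconState:
    """Run ``n_iter`` ML-EM iterations from a uniform (or given) start.

    Deterministic given identical inputs; the Poisson log-likelihood is
    recorded every ``log_every`` iterations (and at the last).
    """
    if isinstance(y, LORHistogram):
        y = y.y
    y = np.asarray(y, dtype=np.float64)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    system = FoldedSystem(srm, lut)
    if y.shape != (system.n_lor,):
        raise ValueError("histogram length disagrees with the scanner spec")
    s = system.sensitivity()
    if init is None:
        c = np.where(s > 0, 1.0, 0.0)
    else:
        c = np.asarray(init, dtype=np.float64).copy()
        if c.shape != (system.n_blobs,):
            raise ValueError("init has the wrong length")
        if np.any(c < 0):
            raise ValueError("init must be non-negative")
        c[s == 0] = 0.0

    loglik = []
    excluded = []
    for it in range(1, n_iter + 1):
        c, n_exc = mlem_update(c, y, system, s, strategy=strategy,
                               chunk_seed=chunk_seed)
        excluded.append(n_exc)
        if it % log_every == 0 or it == n_iter:
            ll = poisson_loglik(y, system.forward(c))
            loglik.append((it, ll))
            logger.info("ML-EM iter %d: log-likelihood %.6f, excluded %d",
                        it, ll, n_exc)
    return ReconState(c=c, iteration=n_iter, log_likelihood=loglik,
                      sensitivity=s, excluded_lors=excluded)
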