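"""Binned Hi-C contact maps: loading, balancing, expected profiles and the
pseudocounted distance-normalised signal.

The container is a genome-wide symmetric sparse matrix over the bins of a
:class:`~cyclehic.genome.BinTable`. Balancing is iterative correction (ICE)
per chromosome to an equal-cis-margin fixed point. The distance-normalised
signal z(i,j) = (observed+1)/(expected+1) is the workhorse quantity for
loop and interaction strength comparisons: the +1 pseudocounts keep it
defined (and equal to 1/(expected+1)) on zero-count pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .genome import BinTable, ParseError

logger = logging.getLogger(__name__)


class ContactMap:
    """Symmetric binned contact matrix with optional balancing weights.

    ``counts`` holds the full symmetric matrix (both triangles); the
    reported ``total_contacts`` is the upper-triangle (including diagonal)
    sum, i.e. the number of distinct contacts.
    """

    def __init__(self, bins: BinTable, counts: sp.spmatrix) -> None:
        counts = sp.csr_matrix(counts)
        if counts.shape != (bins.n_bins, bins.n_bins):
            raise ValueError("counts shape does not match bin table")
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("negative contact counts")
        self.bins = bins
        self.counts = counts
        self.weights: np.ndarray | None = None  # NaN = filtered bin
        self.balance_converged: bool | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_triplets(
        cls, bins: BinTable, i: np.ndarray, j: np.ndarray, c: np.ndarray
    ) -> "ContactMap":
        """Build from global bin-id triplets; duplicates summed, symmetrised."""
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        c = np.asarray(c, dtype=np.float64)
        if i.size and (i.min() < 0 or j.min() < 0 or max(i.max(), j.max()) >= bins.n_bins):
            bad = np.nonzero((i < 0) | (j < 0) | (i >= bins.n_bins) | (j >= bins.n_bins))[0][0]
            raise ValueError(f"bin out of range at record {bad}")
        m = sp.coo_matrix((c, (i, j)), shape=(bins.n_bins, bins.n_bins)).tocsr()
        lower = sp.tril(m, k=-1)
        sym = sp.triu(m) + sp.triu(m, k=1).T + lower + lower.T
        return cls(bins, sym)

    @property
    def total_contacts(self) -> float:
        return float(sp.triu(self.counts).sum())

    def is_empty(self) -> bool:
        return self.counts.nnz == 0

    def _require_nonempty(self) -> None:
        if self.is_empty():
            raise ValueError("empty matrix")

    # -- views ---------------------------------------------------------

    def cis_dense(self, chrom: str, balanced: bool = False) -> np.ndarray:
        """Dense cis sub-matrix for one chromosome (raw or balanced)."""
        sl = self.bins.chrom_slice(chrom)
        m = self.counts[sl, sl].toarray().astype(float)
        if balanced:
            if self.weights is None:
                raise ValueError("map is not balanced")
            w = self.weights[sl]
            m = m * np.outer(w, w)
            m[~np.isfinite(m)] = 0.0
        return m

    def mask(self, chrom: str) -> np.ndarray:
        """Boolean per-bin mask of filtered bins (True = filtered)."""
        sl = self.bins.chrom_slice(chrom)
        if self.weights is None:
            return np.zeros(self.bins.n_bins_of(chrom), dtype=bool)
        return ~np.isfinite(self.weights[sl])

    def copy(self) -> "ContactMap":
        out = ContactMap(self.bins, self.counts.copy())
        out.weights = None if self.weights is None else self.weights.copy()
        out.balance_converged = self.balance_converged
        return out


def load_contacts(path: str | Path, bins: BinTable) -> ContactMap:
    """Load triplet text ``chrom1 start1 chrom2 start2 count``."""
    ii: list[int] = []
    jj: list[int] = []
    cc: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns")
            c1, s1, c2, s2, cnt = parts
            try:
                ii.append(bins.bin_id(c1, int(s1)))
                jj.append(bins.bin_id(c2, int(s2)))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            v = float(cnt)
            if v < 0 or v != int(v):
                raise ParseError(f"{path}: line {lineno}: non-integral count {cnt}")
            cc.append(v)
    return ContactMap.from_triplets(bins, np.array(ii, dtype=np.int64),
                                    np.array(jj, dtype=np.int64),
                                    np.array(cc, dtype=np.float64))


def write_contacts(cmap: ContactMap, path: str | Path) -> None:
    """Write the upper triangle as triplet text."""
    coo = sp.triu(cmap.counts).tocoo()
    bins = cmap.bins
    with open(path, "w") as fh:
        for i, j, c in zip(coo.row, coo.col, coo.data):
            fh.write(
                f"{bins.chrom[i]}\t{bins.start[i]}\t{bins.chrom[j]}\t{bins.start[j]}\t{int(c)}\n"
            )


# ---------------------------------------------------------------------------
# Balancing (iterative correction)
# ---------------------------------------------------------------------------

def balance(
    cmap: ContactMap,
    max_iter: int = 500,
    tol: float = 1e-6,
    filter_frac: float = 0.02,
) -> ContactMap:
    """Iterative correction per chromosome to equal cis margins.

    Bins whose raw cis marginal is below ``filter_frac`` times the
    chromosome median (of nonzero marginals) are masked (weight NaN).
    Weights are scaled so the balanced cis sum equals the raw cis sum of
    each chromosome. Non-convergence sets ``balance_converged=False``
    rather than failing silently.
    """
    cmap._require_nonempty()
    out = cmap.copy()
    weights = np.full(out.bins.n_bins, np.nan)
    converged = True
    for chrom in out.bins.sizes.names:
        sl = out.bins.chrom_slice(chrom)
        m = out.counts[sl, sl].toarray().astype(float)
        n = m.shape[0]
        marg = m.sum(axis=1)
        nz = marg[marg > 0]
        if nz.size == 0:
            continue
        keep = marg >= filter_frac * np.median(nz)
        if keep.sum() < 2:
            continue
        sub = m[np.ix_(keep, keep)]
        w = np.ones(keep.sum())
        ok = False
        for _ in range(max_iter):
            s = (sub * np.outer(w, w)).sum(axis=1)
            mean_s = s.mean()
            if mean_s == 0:
                break
            rel = s / mean_s
            if np.abs(rel - 1).max() < tol:
                ok = True
                break
            w = w / np.sqrt(np.maximum(rel, 1e-300))
        if not ok:
            converged = False
        # rescale so balanced cis sum == raw cis sum
        bal_sum = (sub * np.outer(w, w)).sum()
        if bal_sum > 0:
            w = w * np.sqrt(sub.sum() / bal_sum)
        wc = np.full(n, np.nan)
        wc[keep] = w
        weights[sl] = wc
    out.weights = weights
    out.balance_converged = converged
    if not converged:
        logger.warning("balance: not converged within %d iterations", max_iter)
    return out


# ---------------------------------------------------------------------------
# Expected profile and distance normalisation
# ---------------------------------------------------------------------------

@dataclass
class ExpectedProfile:
    """Per-chromosome mean signal as a function of bin separation."""

    bins: BinTable
    values: dict[str, np.ndarray]  # chrom -> expected[d], NaN where undefined
    balanced: bool

    def at(self, chrom: str, d: int) -> float:
        v = self.values[chrom]
        if not (0 <= d < v.size) or not np.isfinite(v[d]):
            raise ValueError(f"expected undefined at distance {d} on {chrom}")
        return float(v[d])


def expected_by_distance(cmap: ContactMap, use_weights: bool = True) -> ExpectedProfile:
    """Mean signal per bin separation, excluding filtered bins.

    ``use_weights`` selects balanced signal (requires balancing) versus raw
    counts; which one the pseudocount formula should see is configurable,
    balanced being the default policy.
    """
    cmap._require_nonempty()
    if use_weights and cmap.weights is None:
        raise ValueError("use_weights=True requires a balanced map")
    values: dict[str, np.ndarray] = {}
    for chrom in cmap.bins.sizes.names:
        m = cmap.cis_dense(chrom, balanced=use_weights)
        n = m.shape[0]
        mask = cmap.mask(chrom) if use_weights else np.zeros(n, dtype=bool)
        valid = ~mask
        exp = np.full(n, np.nan)
        vv = valid.astype(float)
        for d in range(n):
            if d == 0:
                diag = np.diag(m)
                pair_valid = vv
            else:
                diag = np.diagonal(m, offset=d)
                pair_valid = vv[:-d] * vv[d:]
            npairs = pair_valid.sum()
            if npairs > 0:
                exp[d] = (diag * pair_valid).sum() / npairs
        values[chrom] = exp
    return ExpectedProfile(cmap.bins, values, balanced=use_weights)


@dataclass
class DistNormMap:
    """Dense per-chromosome z = (observed+1)/(expected+1) maps.

    Rows/columns of filtered bins are NaN; everywhere else z > 0, and if
    observed matches expected on every diagonal then z is identically 1.
    """

    bins: BinTable
    z: dict[str, np.ndarray]

    def chrom_z(self, chrom: str) -> np.ndarray:
        return self.z[chrom]

    def same_bins(self, other: "DistNormMap") -> bool:
        return self.bins.same_bins(other.bins)


def distance_normalize(cmap: ContactMap, expected: ExpectedProfile) -> DistNormMap:
    """Compute the pseudocounted distance-normalised cis signal."""
    if not cmap.bins.same_bins(expected.bins):
        raise ValueError("mismatched bin tables between map and expected profile")
    zmaps: dict[str, np.ndarray] = {}
    for chrom in cmap.bins.sizes.names:
        m = cmap.cis_dense(chrom, balanced=expected.balanced)
        n = m.shape[0]
        exp = expected.values[chrom]
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        e = exp[d]
        z = (m + 1.0) / (e + 1.0)
        mask = cmap.mask(chrom) if expected.balanced else np.zeros(n, dtype=bool)
        z[mask, :] = np.nan
        z[:, mask] = np.nan
        zmaps[chrom] = z
    return DistNormMap(cmap.bins, zmaps)


# ---------------------------------------------------------------------------
# Downsampling, replicate distances, trans fractions
# ---------------------------------------------------------------------------

def downsample(cmap: ContactMap, target_total: int, seed: int = 0) -> ContactMap:
    """Exact contact-level sampling without replacement to a target depth.

    Draws a multivariate hypergeometric sample over the upper-triangle
    cells, so the new total equals ``target_total`` exactly and each cell's
    expectation is proportional to its original count.
    """
    total = cmap.total_contacts
    if target_total > total:
        raise ValueError(f"target {target_total} exceeds total {total:.0f}")
    coo = sp.triu(cmap.counts).tocoo()
    colors = coo.data.astype(np.int64)
    rng = np.random.default_rng(seed)
    if len(colors) == 0 or target_total == 0:
        new = np.zeros_like(colors)
    else:
        new = rng.multivariate_hypergeometric(colors, int(target_total), method="marginals")
    out = ContactMap.from_triplets(cmap.bins, coo.row, coo.col, new.astype(float))
    return out


def prepare(cmap: ContactMap, use_weights: bool = True):
    """Balance a raw map and derive its expected profile and z map.

    Convenience for the standard chain balance -> expected_by_distance ->
    distance_normalize; returns ``(balanced, expected, z)``.
    """
    balanced = balance(cmap)
    expected = expected_by_distance(balanced, use_weights=use_weights)
    return balanced, expected, distance_normalize(balanced, expected)


def sum_maps(maps: list[ContactMap]) -> ContactMap:
    """Combine replicates by summing counts (weights are not carried over)."""
    if not maps:
        raise ValueError("need >=1 map")
    bins = maps[0].bins
    for m in maps[1:]:
        if not m.bins.same_bins(bins):
            raise ValueError("bin-table mismatch between maps")
    total = maps[0].counts.copy()
    for m in maps[1:]:
        total = total + m.counts
    return ContactMap(bins, total)


def informative_max_dist(expected: ExpectedProfile, min_expected: float = 20.0) -> int:
    """Largest bin separation whose expected signal still reaches
    ``min_expected`` on every chromosome.

    Pairs beyond this separation carry mostly shot noise and drown out
    replicate structure in sample-to-sample distances.
    """
    caps = []
    for v in expected.values.values():
        ok = np.nonzero(np.nan_to_num(v) >= min_expected)[0]
        caps.append(int(ok.max()) if ok.size else 1)
    return max(min(caps), 1)


def replicate_distances(
    maps: list[DistNormMap], max_dist_bins: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-to-sample Euclidean distances on log2 z, plus a 2-D embedding.

    Uses the union of informative cis pairs (finite z in every map, upper
    triangle, optionally capped at ``max_dist_bins`` separation — see
    :func:`informative_max_dist` for a coverage-based cap). The embedding
    is classical multidimensional scaling (principal coordinates).
    """
    if len(maps) < 2:
        raise ValueError("need >=2 maps")
    first = maps[0]
    for m in maps[1:]:
        if not m.same_bins(first):
            raise ValueError("bin-table mismatch between maps")
    feats = []
    for m in maps:
        vec = []
        for chrom in m.bins.sizes.names:
            z = m.z[chrom]
            n = z.shape[0]
            iu, ju = np.triu_indices(n, k=1)
            if max_dist_bins is not None:
                keep = (ju - iu) <= max_dist_bins
                iu, ju = iu[keep], ju[keep]
            vec.append(z[iu, ju])
        feats.append(np.concatenate(vec))
    X = np.log2(np.vstack(feats))
    finite = np.all(np.isfinite(X), axis=0)
    X = X[:, finite]
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    # classical MDS
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:2]
    emb = evecs[:, order] * np.sqrt(np.maximum(evals[order], 0))
    return D, emb


def trans_fraction(cmap: ContactMap, by_chromosome: bool = False):
    """Fraction of contacts between chromosomes.

    Returns the global trans fraction, or with ``by_chromosome`` also a
    dict of per-chromosome trans ratios (trans contacts over all contacts
    touching that chromosome).
    """
    cmap._require_nonempty()
    coo = sp.triu(cmap.counts).tocoo()
    chrom_of = np.empty(cmap.bins.n_bins, dtype=np.int64)
    for k, name in enumerate(cmap.bins.sizes.names):
        chrom_of[cmap.bins.chrom_slice(name)] = k
    ci, cj = chrom_of[coo.row], chrom_of[coo.col]
    is_trans = ci != cj
    total = coo.data.sum()
    global_trans = float(coo.data[is_trans].sum() / total) if total else 0.0
    if not by_chromosome:
        return global_trans
    per: dict[str, float] = {}
    for k, name in enumerate(cmap.bins.sizes.names):
        touch = (ci == k) | (cj == k)
        tot_k = coo.data[touch].sum()
        trans_k = coo.data[touch & is_trans].sum()
        per[name] = float(trans_k / tot_k) if tot_k else 0.0
    return global_trans, per
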