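"""A/B compartment eigenvector calling and differential compartments.

Per chromosome, the balanced cis map is converted to observed/expected,
Pearson-correlated, and the eigenvector of the largest-magnitude
eigenvalue is taken as the compartment signal. Positive values define the
A compartment after orienting the sign so the track correlates positively
with an activity proxy (ATAC-peak density per bin, or TSS density).
Eigenvectors are scaled to unit standard deviation over unmasked bins so
that an absolute difference threshold is comparable across samples; the
default threshold 0.42 is the quartile-shift criterion (a bin is flagged
when its signal moves by more than the distance between quartiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactMap, expected_by_distance
from .genome import BinTable, Interval

logger = logging.getLogger(__name__)


@dataclass
class EigenTrack:
    """Per-chromosome compartment eigenvector.

    ``e`` is NaN on masked bins; ``labels`` is "A" where e > 0 else "B";
    ``oriented`` records whether an activity track fixed the global sign.
    """

    chrom: str
    bins: BinTable
    e: np.ndarray
    mask: np.ndarray
    oriented: bool

    @property
    def labels(self) -> np.ndarray:
        lab = np.where(self.e > 0, "A", "B").astype(object)
        lab[~np.isfinite(self.e)] = "."
        return lab


def call_eigenvector(
    cmap: ContactMap,
    orient_track: np.ndarray | None = None,
    min_bins: int = 10,
) -> dict[str, EigenTrack]:
    """Leading correlation-matrix eigenvector per chromosome.

    ``orient_track`` is a per-bin (global) activity density; when absent
    the result is returned unoriented and flagged as such.
    """
    if cmap.weights is None:
        raise ValueError("call_eigenvector requires a balanced map")
    expected = expected_by_distance(cmap, use_weights=True)
    tracks: dict[str, EigenTrack] = {}
    for chrom in cmap.bins.sizes.names:
        m = cmap.cis_dense(chrom, balanced=True)
        n = m.shape[0]
        mask = cmap.mask(chrom)
        valid = ~mask
        if valid.sum() < min_bins:
            logger.warning("call_eigenvector: skipping %s (<%d unmasked bins)", chrom, min_bins)
            continue
        exp = expected.values[chrom]
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = m / exp[d]
        sub = oe[np.ix_(valid, valid)]
        sub[~np.isfinite(sub)] = 0.0
        sd = sub.std(axis=1)
        degenerate = sd == 0
        if degenerate.all():
            logger.warning("call_eigenvector: %s degenerate (constant matrix)", chrom)
            e = np.full(n, np.nan)
            tracks[chrom] = EigenTrack(chrom, cmap.bins, e, np.ones(n, dtype=bool), False)
            continue
        # correlation over rows; zero-variance rows dropped into the mask
    # (re-filter and recompute if any degenerate rows slipped through)
        if degenerate.any():
            valid_idx = np.flatnonzero(valid)[~degenerate]
            valid = np.zeros(n, dtype=bool)
            valid[valid_idx] = True
            sub = oe[np.ix_(valid, valid)]
            sub[~np.isfinite(sub)] = 0.0
        corr = np.corrcoef(sub)
        corr[~np.isfinite(corr)] = 0.0
        evals, evecs = np.linalg.eigh(corr)
        lead = np.argmax(np.abs(evals))
        v = evecs[:, lead]
        sd_v = v.std()
        if sd_v > 0:
            v = v / sd_v
        oriented = False
        if orient_track is not None:
            act = np.asarray(orient_track, dtype=float)[cmap.bins.chrom_slice(chrom)][valid]
            if act.std() > 0 and v.std() > 0:
                r = np.corrcoef(v, act)[0, 1]
                if np.isfinite(r) and r != 0:
                    v = v * np.sign(r)
                    oriented = True
        if not oriented:
            logger.warning("call_eigenvector: %s left unoriented", chrom)
        e = np.full(n, np.nan)
        e[valid] = v
        tracks[chrom] = EigenTrack(chrom, cmap.bins, e, ~valid, oriented)
    return tracks


@dataclass
class DiffCompartmentResult:
    """Per-bin eigenvector differences for one chromosome pair of tracks."""

    chrom: str
    delta: np.ndarray          # e_A - e_B, NaN where either side masked
    flagged: np.ndarray        # |delta| > tau
    tau: float

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    def span_mb(self, bin_size: int) -> float:
        """Genomic span of flagged bins: count x bin size, in Mb."""
        return flagged_span_mb(self.n_flagged, bin_size)


def flagged_span_mb(n_flagged: int, bin_size: int) -> float:
    """Bookkeeping identity: flagged bins x bin size, reported in Mb."""
    return n_flagged * bin_size / 1e6


def diff_compartments(
    track_a: EigenTrack,
    track_b: EigenTrack,
    tau: float | str = 0.42,
) -> DiffCompartmentResult:
    """Flag bins whose eigenvector difference exceeds the quartile shift.

    ``tau="auto"`` derives the threshold as the interquartile range of the
    pooled eigenvector distribution (the quartile-shift reading: a change
    as large as the distance between quartiles).
    """
    if track_a.chrom != track_b.chrom or not track_a.bins.same_bins(track_b.bins):
        raise ValueError("tracks must share chromosome and bins")
    ea, eb = track_a.e, track_b.e
    sa = np.nanstd(ea)
    sb = np.nanstd(eb)
    if sa > 0 and sb > 0 and abs(sa - sb) / max(sa, sb) > 0.10:
        logger.warning(
            "diff_compartments: eigenvector scales differ by >10%% (%.3f vs %.3f)", sa, sb
        )
    if tau == "auto":
        pooled = np.concatenate([ea[np.isfinite(ea)], eb[np.isfinite(eb)]])
        q25, q75 = np.percentile(pooled, [25, 75])
        tau_val = float(q75 - q25)
    else:
        tau_val = float(tau)
    delta = ea - eb
    flagged = np.abs(delta) > tau_val
    flagged &= np.isfinite(delta)
    return DiffCompartmentResult(track_a.chrom, delta, flagged, tau_val)


def diff_summary(
    results: dict[str, DiffCompartmentResult], bin_size: int
) -> pd.DataFrame:
    """Per-chromosome flagged-bin counts and spanned Mb."""
    rows = [
        {
            "chrom": chrom,
            "n_flagged": r.n_flagged,
            "span_mb": r.span_mb(bin_size),
            "tau": r.tau,
        }
        for chrom, r in results.items()
    ]
    return pd.DataFrame(rows)


def compare_groups(
    results: dict[str, DiffCompartmentResult],
    sex_chroms: set[str],
) -> dict:
    """Wilcoxon rank-sum of per-bin |delta|: X chromosome vs autosomes."""
    x_vals, a_vals = [], []
    for chrom, r in results.items():
        v = np.abs(r.delta[np.isfinite(r.delta)])
        (x_vals if chrom in sex_chroms else a_vals).append(v)
    if not x_vals or not a_vals:
        raise ValueError("both groups (X and autosomes) must be non-empty")
    x = np.concatenate(x_vals)
    a = np.concatenate(a_vals)
    res = stats.mannwhitneyu(x, a, alternative="two-sided", method="auto")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_x": float(np.median(x)),
        "median_autosome": float(np.median(a)),
        "n_x": int(x.size),
        "n_autosome": int(a.size),
    }


def direction_concordance(
    diff1: dict[str, DiffCompartmentResult],
    diff2: dict[str, DiffCompartmentResult],
) -> dict:
    """Do two condition contrasts move bins in the same direction?

    Restricted to bins flagged in either comparison; returns the
    sign-agreement fraction and a Spearman rank correlation of the deltas.
    """
    d1, d2 = [], []
    for chrom in diff1:
        if chrom not in diff2:
            continue
        r1, r2 = diff1[chrom], diff2[chrom]
        sel = (r1.flagged | r2.flagged) & np.isfinite(r1.delta) & np.isfinite(r2.delta)
        d1.append(r1.delta[sel])
        d2.append(r2.delta[sel])
    d1 = np.concatenate(d1) if d1 else np.array([])
    d2 = np.concatenate(d2) if d2 else np.array([])
    if d1.size == 0:
        return {"agreement": np.nan, "rho": np.nan, "n": 0, "defined": False}
    agree = float(np.mean(np.sign(d1) == np.sign(d2)))
    rho = stats.spearmanr(d1, d2).statistic if d1.size > 1 else np.nan
    return {"agreement": agree, "rho": float(rho), "n": int(d1.size), "defined": True}


def gene_eigen(track: EigenTrack, genes: list[Interval]) -> pd.Series:
    """Length-weighted mean eigenvector over each gene body.

    Genes entirely on masked bins get NaN.
    """
    bins = track.bins
    sl = bins.chrom_slice(track.chrom)
    starts = bins.start[sl]
    ends = bins.end[sl]
    out = {}
    for g in genes:
        if g.chrom != track.chrom:
            continue
        first = g.start // bins.bin_size
        last = (g.end - 1) // bins.bin_size
        num = den = 0.0
        for b in range(first, min(last, len(starts) - 1) + 1):
            ov = min(g.end, int(ends[b])) - max(g.start, int(starts[b]))
            if ov <= 0 or not np.isfinite(track.e[b]):
                continue
            num += ov * track.e[b]
            den += ov
        out[g.name] = num / den if den > 0 else np.nan
    return pd.Series(out, dtype=float)
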