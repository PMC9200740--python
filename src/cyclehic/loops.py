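"""Punctate loop calling, master-list merging, differential loops, anchor
annotation, APA and insulation aggregates.

The caller works on the pseudocounted distance-normalised map z: Gaussian
smoothing (sigma = 1 bin), regional maxima above a floor, then a Poisson
upper-tail test of the observed raw counts against a local-ring background
(the peak's 3x3 core excluded), with Benjamini-Hochberg control across
candidates. Loops further than a span cap from the diagonal are ignored,
as are pixels closer than a minimum distance (diagonal artefacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .contacts import ContactMap, DistNormMap, ExpectedProfile
from .genome import Interval, overlaps_any

# ---------------------------------------------------------------------------
# Small shared helpers
# ---------------------------------------------------------------------------

def bh_qvalues(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1).

    ``m`` overrides the family size when the supplied p-values are a
    pre-screened subset of a larger tested family (screened-out members
    implicitly have large p).
    """
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    if p.size == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(p.size) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(p.size)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def peak_z(z: np.ndarray, i: int, j: int, halo: int = 1) -> float:
    """Max z over the (2*halo+1)^2 neighbourhood of a pixel.

    Absorbs 1-bin peak drift between samples when reading a master pixel
    in each condition.
    """
    n = z.shape[0]
    win = z[max(i - halo, 0): i + halo + 1, max(j - halo, 0): j + halo + 1]
    win = win[np.isfinite(win)]
    return float(win.max()) if win.size else np.nan


def apply_differential_rule(
    z_a: np.ndarray, z_b: np.ndarray, min_z: float = 2.0, min_fold: float = 2.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The shared differential rule: max z > min_z AND fold >= min_fold.

    Returns (fold, flagged, direction) where direction is "A-specific"
    when the first condition is the stronger one.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    hi = np.maximum(z_a, z_b)
    lo = np.minimum(z_a, z_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = hi / lo
    flagged = (hi > min_z) & (fold >= min_fold)
    direction = np.where(z_a >= z_b, "A-specific", "B-specific").astype(object)
    return fold, flagged, direction


# ---------------------------------------------------------------------------
# Loop calling
# ---------------------------------------------------------------------------

@dataclass
class LoopSet:
    """Called loops plus the parameters that produced them."""

    loops: pd.DataFrame  # chrom, bin1, bin2 (chrom-local), z, p, q, sample
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.loops)

    def anchors(self) -> pd.DataFrame:
        """Deduplicated anchor table (chrom, bin)."""
        a = pd.concat(
            [
                self.loops[["chrom", "bin1"]].rename(columns={"bin1": "bin"}),
                self.loops[["chrom", "bin2"]].rename(columns={"bin2": "bin"}),
            ]
        )
        return a.drop_duplicates().reset_index(drop=True)


def call_loops(
    z: DistNormMap,
    raw: ContactMap,
    expected: ExpectedProfile,
    smooth_sigma: float = 1.0,
    max_span: int = 2000,
    fdr: float = 0.01,
    min_dist: int = 5,
    window_r: int = 3,
    peak_r: int = 1,
    rel_floor: float = 1.2,
    min_enrichment: float = 2.0,
    sample: str = "",
) -> LoopSet:
    """Detect punctate cis loops on the distance-normalised map.

    Candidates are local maxima of the sigma-smoothed z within a
    (2*peak_r+1)^2 footprint whose smoothed signal exceeds ``rel_floor``
    times the local background. The background at a pixel is the larger of
    two annulus means of z around it -- an inner 5x5-minus-3x3 ring and an
    outer (2*window_r+1)^2-minus-5x5 ring -- so that the checkerboard
    compartment plaid (where a global ring would mix A and B parity)
    cannot masquerade as focal enrichment. Each candidate's observed count
    is tested Poisson upper-tail against the background rescaled to count
    space through the expected profile; because a candidate is by
    construction the maximum of its footprint the p-value is
    Sidak-corrected for the footprint size, then Benjamini-Hochberg
    across candidates at ``fdr``. ``min_enrichment`` additionally requires
    the pseudocounted observed/background ratio to reach a minimum fold,
    discarding significant-but-weak pixels.
    """
    if all(not np.isfinite(m).any() for m in z.z.values()):
        raise ValueError("empty matrix")

    def _box_sum(a: np.ndarray, size: int) -> np.ndarray:
        return ndimage.uniform_filter(a, size=size, mode="constant", cval=0.0) * size * size

    rows = []
    n_examined_total: list[int] = []
    outer = 2 * window_r + 1
    for chrom in z.bins.sizes.names:
        zc = z.z[chrom]
        n = zc.shape[0]
        if n == 0:
            continue
        finite = np.isfinite(zc)
        zf = np.where(finite, zc, 0.0)
        fl = finite.astype(float)
        sm = ndimage.gaussian_filter(np.where(finite, zc, 1.0), sigma=smooth_sigma, mode="nearest")
        # annulus means of z (inner: 5^2-3^2, outer: (2w+1)^2-5^2)
        sums = {s: _box_sum(zf, s) for s in (3, 5, outer)}
        cnts = {s: _box_sum(fl, s) for s in (3, 5, outer)}
        # horizontal/vertical bands at offsets 2..band_r: these cells share
        # the pixel's compartment parity, so at plaid-block corners (where
        # both annuli mix A and B cells) they keep the background honest
        band_r = max(window_r, 5)
        bw, cw = 2 * band_r + 1, 3
        h_sum = (
            ndimage.uniform_filter1d(zf, bw, axis=1, mode="constant") * bw
            - ndimage.uniform_filter1d(zf, cw, axis=1, mode="constant") * cw
        )
        h_cnt = (
            ndimage.uniform_filter1d(fl, bw, axis=1, mode="constant") * bw
            - ndimage.uniform_filter1d(fl, cw, axis=1, mode="constant") * cw
        )
        v_sum = (
            ndimage.uniform_filter1d(zf, bw, axis=0, mode="constant") * bw
            - ndimage.uniform_filter1d(zf, cw, axis=0, mode="constant") * cw
        )
        v_cnt = (
            ndimage.uniform_filter1d(fl, bw, axis=0, mode="constant") * bw
            - ndimage.uniform_filter1d(fl, cw, axis=0, mode="constant") * cw
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            inner_bg = (sums[5] - sums[3]) / (cnts[5] - cnts[3])
            outer_bg = (sums[outer] - sums[5]) / (cnts[outer] - cnts[5])
            horiz_bg = h_sum / h_cnt
            vert_bg = v_sum / v_cnt
            # immediate 3x3 ring: parity-pure even where both anchors sit
            # at compartment-block corners and all wider filters mix A/B
            core_bg = (sums[3] - zf) / (cnts[3] - fl)
        bg = np.fmax(
            np.fmax(np.fmax(inner_bg, outer_bg), np.fmax(horiz_bg, vert_bg)),
            core_bg,
        )
        foot = 2 * peak_r + 1
        local_max = sm == ndimage.maximum_filter(sm, size=foot, mode="nearest")
        sm_bg = ndimage.uniform_filter(sm, size=5, mode="nearest")
        sep = np.arange(n)[None, :] - np.arange(n)[:, None]  # j - i
        in_range = (sep >= min_dist) & (sep <= max_span)
        examined = local_max & finite & np.isfinite(bg) & (bg > 0) & in_range
        n_examined_total.append(int(examined.sum()))
        cand = examined & (sm > rel_floor * sm_bg)
        ii, jj = np.nonzero(cand)
        if ii.size == 0:
            continue
        obs = raw.cis_dense(chrom, balanced=False)
        exp = expected.values[chrom]
        n_foot = foot * foot
        for i, j in zip(ii, jj):
            d = j - i
            if not (0 <= d < exp.size) or not np.isfinite(exp[d]):
                continue
            mu = max(float(bg[i, j]) * (exp[d] + 1.0) - 1.0, 1e-6)
            o = float(obs[i, j])
            enrichment = (o + 1.0) / (mu + 1.0)
            if enrichment < min_enrichment:
                continue
            p_raw = stats.poisson.sf(o - 1, mu)
            # selected as the max of its footprint: Sidak over those cells
            p = float(-np.expm1(n_foot * np.log1p(-min(p_raw, 1 - 1e-12))))
            rows.append(
                {
                    "chrom": chrom, "bin1": int(i), "bin2": int(j),
                    "z": float(zc[i, j]), "smoothed_z": float(sm[i, j]),
                    "observed": o, "bg_mu": mu, "enrichment": enrichment,
                    "p": p,
                }
            )
    params = {
        "smooth_sigma": smooth_sigma, "max_span": max_span, "fdr": fdr,
        "min_dist": min_dist, "window_r": window_r, "peak_r": peak_r,
        "rel_floor": rel_floor, "min_enrichment": min_enrichment,
    }
    cols = ["chrom", "bin1", "bin2", "z", "smoothed_z", "observed",
            "bg_mu", "enrichment", "p", "q", "sample"]
    if not rows:
        return LoopSet(pd.DataFrame(columns=cols), params)
    df = pd.DataFrame(rows)
    # family = every local maximum examined, not just floor-passing ones:
    # the floor is a computational screen, and screened-out maxima still
    # count as tested (with large p) for FDR purposes
    df["q"] = bh_qvalues(df["p"].to_numpy(), m=sum(n_examined_total))
    df = df[df["q"] < fdr].reset_index(drop=True)
    df["sample"] = sample
    return LoopSet(df, params)


def merge_master(loop_sets: list[LoopSet], radius_bp: int = 25_000, bin_size: int | None = None) -> LoopSet:
    """Merge per-sample loop calls into a master list.

    Single-linkage clustering: two loops join when both anchors lie within
    ``radius_bp``; each cluster is represented by its highest-z member.
    Idempotent, and the master size never exceeds the input total.
    """
    frames = [s.loops for s in loop_sets if len(s.loops)]
    if not frames:
        return LoopSet(pd.DataFrame(columns=["chrom", "bin1", "bin2", "z", "p", "q", "sample"]))
    df = pd.concat(frames, ignore_index=True)
    if bin_size is None:
        bin_size = loop_sets[0].params.get("bin_size", 10_000)
    radius = radius_bp / bin_size
    keep_rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        b1 = grp["bin1"].to_numpy()
        b2 = grp["bin2"].to_numpy()
        m = len(idx)
        parent = np.arange(m)

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in range(m):
            near = (np.abs(b1 - b1[a]) * bin_size <= radius_bp) & (
                np.abs(b2 - b2[a]) * bin_size <= radius_bp
            )
            for b in np.nonzero(near)[0]:
                ra, rb = find(a), find(int(b))
                if ra != rb:
                    parent[rb] = ra
        roots = np.array([find(a) for a in range(m)])
        zvals = grp["z"].to_numpy()
        for root in np.unique(roots):
            members = np.nonzero(roots == root)[0]
            best = members[np.argmax(zvals[members])]
            keep_rows.append(idx[best])
    out = df.loc[keep_rows].reset_index(drop=True)
    return LoopSet(out, {"merged": True, "radius_bp": radius_bp, "bin_size": bin_size})


def diff_loops(
    master: LoopSet,
    z_a: DistNormMap,
    z_b: DistNormMap,
    min_z: float = 2.0,
    min_fold: float = 2.5,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Differential loops: signal > 2 in the stronger condition and fold
    between conditions >= 2.5, reading each master pixel as the 3x3 max."""
    rows_a, rows_b = [], []
    for _, row in master.loops.iterrows():
        za = z_a.z[row["chrom"]]
        zb = z_b.z[row["chrom"]]
        rows_a.append(peak_z(za, int(row["bin1"]), int(row["bin2"])))
        rows_b.append(peak_z(zb, int(row["bin1"]), int(row["bin2"])))
    out = master.loops.copy()
    out[f"z_{labels[0]}"] = rows_a
    out[f"z_{labels[1]}"] = rows_b
    fold, flagged, direction = apply_differential_rule(
        np.array(rows_a), np.array(rows_b), min_z=min_z, min_fold=min_fold
    )
    out["fold"] = fold
    out["flagged"] = flagged
    out["direction"] = np.where(
        direction == "A-specific", f"{labels[0]}-specific", f"{labels[1]}-specific"
    )
    return out


# ---------------------------------------------------------------------------
# Anchor annotation
# ---------------------------------------------------------------------------

def annotate_anchors(
    loops: pd.DataFrame,
    bins,
    atac: list[Interval],
    ctcf: list[Interval],
) -> pd.DataFrame:
    """Annotate each loop with anchor ATAC/CTCF composition and motif
    orientation.

    Category is the conjunction over both anchors: "both" (each anchor has
    an ATAC peak and a CTCF motif), "CTCF-only", "ATAC-only", "neither".
    Convergence reads motif strands at the two anchors: + at the left and
    - at the right is convergent; equal strands tandem; - then +
    divergent; anything unresolved is ambiguous.
    """
    def anchor_interval(chrom: str, b: int) -> Interval:
        o = bins.offset(chrom)
        return Interval(chrom, int(bins.start[o + b]), int(bins.end[o + b]))

    anchors1 = [anchor_interval(r["chrom"], int(r["bin1"])) for _, r in loops.iterrows()]
    anchors2 = [anchor_interval(r["chrom"], int(r["bin2"])) for _, r in loops.iterrows()]
    has_atac1 = overlaps_any(anchors1, atac) if atac else np.zeros(len(anchors1), bool)
    has_atac2 = overlaps_any(anchors2, atac) if atac else np.zeros(len(anchors2), bool)
    plus = [m for m in ctcf if m.strand == "+"]
    minus = [m for m in ctcf if m.strand == "-"]
    has_p1 = overlaps_any(anchors1, plus) if plus else np.zeros(len(anchors1), bool)
    has_m1 = overlaps_any(anchors1, minus) if minus else np.zeros(len(anchors1), bool)
    has_p2 = overlaps_any(anchors2, plus) if plus else np.zeros(len(anchors2), bool)
    has_m2 = overlaps_any(anchors2, minus) if minus else np.zeros(len(anchors2), bool)
    has_ctcf1 = has_p1 | has_m1
    has_ctcf2 = has_p2 | has_m2

    atac_both = has_atac1 & has_atac2
    ctcf_both = has_ctcf1 & has_ctcf2
    category = np.select(
        [atac_both & ctcf_both, ctcf_both, atac_both],
        ["both", "CTCF-only", "ATAC-only"],
        default="neither",
    )
    convergence = []
    for k in range(len(loops)):
        if not (has_ctcf1[k] and has_ctcf2[k]):
            convergence.append("ambiguous")
        elif has_p1[k] and has_m2[k]:
            convergence.append("convergent")
        elif has_m1[k] and has_p2[k]:
            convergence.append("divergent")
        elif (has_p1[k] and has_p2[k]) or (has_m1[k] and has_m2[k]):
            convergence.append("tandem")
        else:
            convergence.append("ambiguous")
    out = loops.copy()
    out["category"] = category
    out["convergence"] = convergence
    return out


def anchor_composition(annotated: pd.DataFrame) -> pd.Series:
    """Fraction of loops per category (the Fig-1f style composition)."""
    return annotated["category"].value_counts(normalize=True)


# ---------------------------------------------------------------------------
# APA / insulation / domain aggregates
# ---------------------------------------------------------------------------

def apa(
    z: DistNormMap,
    sites: pd.DataFrame,
    half_window: int = 10,
) -> dict:
    """Aggregate peak analysis: mean z window around each site pair.

    Sites within ``half_window`` of the diagonal or the matrix edge are
    excluded. Returns the aggregate matrix, the APA score (centre pixel)
    and a secondary centre/lower-left-corner ratio.
    """
    h = half_window
    windows = []
    for _, row in sites.iterrows():
        zc = z.z[row["chrom"]]
        n = zc.shape[0]
        i, j = int(row["bin1"]), int(row["bin2"])
        if j - i <= h or i - h < 0 or j + h + 1 > n or i + h + 1 > n or j - h < 0:
            continue
        win = zc[i - h : i + h + 1, j - h : j + h + 1]
        if np.isfinite(win).all():
            windows.append(win)
    if not windows:
        raise ValueError("all sites excluded (too near diagonal or edges)")
    agg = np.mean(windows, axis=0)
    score = float(agg[h, h])
    corner = float(agg[2 * h - h // 2 :, : h // 2 + 1].mean())  # lower-left corner block
    return {
        "aggregate": agg,
        "score": score,
        "corner_ratio": score / corner if corner > 0 else np.nan,
        "n_sites": len(windows),
    }


def insulation(cmap: ContactMap, window: int = 20) -> dict[str, np.ndarray]:
    """Sliding-square insulation on the balanced map, log2 vs chromosome mean.

    insulation(i) = log2( mean(balanced[i-w..i-1, i+1..i+w]) / mean over i ).
    Bins whose square leaves the chromosome get NaN.
    """
    if cmap.weights is None:
        raise ValueError("insulation requires a balanced map")
    out: dict[str, np.ndarray] = {}
    for chrom in cmap.bins.sizes.names:
        m = cmap.cis_dense(chrom, balanced=True)
        n = m.shape[0]
        if window >= n:
            raise ValueError(f"window {window} exceeds chromosome span {n} bins")
        raw = np.full(n, np.nan)
        for i in range(window, n - window):
            sq = m[i - window : i, i + 1 : i + window + 1]
            raw[i] = sq.mean()
        valid = np.isfinite(raw) & (raw > 0)
        chrom_mean = raw[valid].mean() if valid.any() else np.nan
        track = np.full(n, np.nan)
        if np.isfinite(chrom_mean) and chrom_mean > 0:
            track[valid] = np.log2(raw[valid] / chrom_mean)
        out[chrom] = track
    return out


def aggregate_domains(
    z: DistNormMap, regions: list[tuple[str, int, int]], out_size: int = 60
) -> np.ndarray:
    """Aggregate domain analysis: coordinate-rescaled mean of z-submatrices.

    Each region (chrom, start_bin, end_bin) is expanded by half its length
    on each side and rescaled to ``out_size`` pixels, so the domain body
    occupies the central half of the aggregate.
    """
    mats = []
    for chrom, lo, hi in regions:
        zc = z.z[chrom]
        n = zc.shape[0]
        span = hi - lo
        flank = span // 2
        a, b = lo - flank, hi + flank
        if a < 0 or b > n or span < 2:
            continue
        sub = zc[a:b, a:b]
        if not np.isfinite(sub).all():
            continue
        zoom = out_size / sub.shape[0]
        mats.append(ndimage.zoom(sub, zoom, order=1)[:out_size, :out_size])
    if not mats:
        raise ValueError("no usable regions")
    return np.mean(mats, axis=0)
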