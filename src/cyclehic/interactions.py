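"""Distance-model significant interactions, loop exclusion, enhancer /
promoter classification, differential calls and gene connectivity.

The significance model is a one-pass Fit-Hi-C-style binomial: cis bin
pairs are grouped into equal-contact-occupancy distance strata; each
stratum's per-pair contact probability is estimated from its contact sum;
each pair's observed count is tested upper-tail Binomial(N_total, p_hat)
and Benjamini-Hochberg corrected across all tested pairs. Interactions
that could be CTCF loops (both anchors within 20 kb of a called loop's
anchors) are removed before classification.

"Enhancer" uses an accessibility proxy: an ATAC peak whose closest edge
is more than 10 kb from every TSS; a 10-kb bin is an enhancer bin when it
holds such a peak and no TSS, a promoter bin when it holds >= 1 TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactMap, DistNormMap
from .genome import BinTable, Interval, intervals_per_bin, point_distance_to_nearest
from .loops import LoopSet, apply_differential_rule, bh_qvalues, peak_z


# ---------------------------------------------------------------------------
# Bin annotation (enhancer / promoter proxy)
# ---------------------------------------------------------------------------

@dataclass
class BinAnnotation:
    """Per-bin promoter / enhancer flags (mutually exclusive by rule)."""

    bins: BinTable
    has_promoter: np.ndarray
    has_enhancer: np.ndarray


def build_bin_annotation(
    bins: BinTable,
    atac: list[Interval],
    tss: list[Interval],
    enhancer_min_dist: int = 10_000,
) -> BinAnnotation:
    """Build the promoter/enhancer bin annotation.

    Promoter bin: contains >= 1 TSS. Enhancer bin: overlaps >= 1 ATAC peak
    lying strictly more than ``enhancer_min_dist`` (edge distance) from
    every TSS, and is itself TSS-free.
    """
    has_promoter = intervals_per_bin(tss, bins) > 0
    tss_points = [(t.chrom, t.start) for t in tss]
    dist = point_distance_to_nearest(atac, tss_points)
    distal_peaks = [p for p, d in zip(atac, dist) if d > enhancer_min_dist]
    has_distal = intervals_per_bin(distal_peaks, bins) > 0
    has_enhancer = has_distal & ~has_promoter
    return BinAnnotation(bins, has_promoter, has_enhancer)


# ---------------------------------------------------------------------------
# Significance calling
# ---------------------------------------------------------------------------

def call_significant(
    cmap: ContactMap,
    q_max: float = 0.05,
    n_strata: int = 100,
    min_dist: int = 2,
    max_dist: int = 2000,
) -> pd.DataFrame:
    """Binomial distance-model significant cis interactions (q < q_max).

    Pairs at separations in [min_dist, max_dist] are stratified into up to
    ``n_strata`` equal-occupancy distance bands (by contact sum; bands
    with zero pairs collapse into their neighbour). All pairs in range are
    tested (zero-count pairs contribute p = 1) so BH is over the full
    family.
    """
    rows = []
    for chrom in cmap.bins.sizes.names:
        m = cmap.cis_dense(chrom, balanced=False)
        n = m.shape[0]
        iu, ju = np.triu_indices(n, k=min_dist)
        d = ju - iu
        keep = d <= max_dist
        iu, ju, d = iu[keep], ju[keep], d[keep]
        if iu.size == 0:
            continue
        obs = m[iu, ju]
        total = obs.sum()
        if total == 0:
            continue
        # per-distance contact sums and pair counts
        max_d = d.max()
        sums = np.bincount(d, weights=obs, minlength=max_d + 1)
        npairs = np.bincount(d, minlength=max_d + 1)
        # equal-occupancy strata over distances: split cumulative contacts
        dist_vals = np.nonzero(npairs)[0]
        cum = np.cumsum(sums[dist_vals])
        if cum[-1] <= 0:
            continue
        edges = np.searchsorted(cum, np.linspace(0, cum[-1], n_strata + 1)[1:-1], side="left")
        # duplicate cut points mean empty strata; uniquing collapses them into neighbours
        stratum_ids = np.searchsorted(np.unique(edges), np.arange(dist_vals.size), side="right")
        # map back: distance -> stratum id
        dist_to_stratum = np.full(max_d + 1, -1, dtype=np.int64)
        dist_to_stratum[dist_vals] = stratum_ids
        strat = dist_to_stratum[d]
        # per-stratum contact probability
        n_str = stratum_ids.max() + 1
        s_sums = np.bincount(strat, weights=obs, minlength=n_str)
        s_pairs = np.bincount(strat, minlength=n_str)
        p_hat = s_sums / (total * np.maximum(s_pairs, 1))
        p_pair = p_hat[strat]
        pvals = stats.binom.sf(obs - 1, int(total), p_pair)
        pvals = np.where(obs > 0, pvals, 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom, "bin1": iu, "bin2": ju,
                    "observed": obs, "p_hat": p_pair, "p": pvals,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "bin1", "bin2", "observed", "p_hat", "p", "q"]
        )
    df = pd.concat(rows, ignore_index=True)
    df["q"] = bh_qvalues(df["p"].to_numpy())
    out = df[df["q"] < q_max].reset_index(drop=True)
    out.attrs["n_tested"] = len(df)
    return out


def exclude_loops(
    interactions: pd.DataFrame,
    loops: LoopSet | pd.DataFrame,
    bins: BinTable,
    radius_bp: int = 20_000,
) -> pd.DataFrame:
    """Drop interactions that could be CTCF loops instead.

    An interaction is removed when some loop on the same chromosome has
    both anchors within ``radius_bp`` of the interaction's anchors
    (anchor-pair distance, sorted orientation). With radius 0 only exact
    loop pixels are removed.
    """
    loop_df = loops.loops if isinstance(loops, LoopSet) else loops
    if len(interactions) == 0 or len(loop_df) == 0:
        return interactions.copy()
    bs = bins.bin_size
    keep = np.ones(len(interactions), dtype=bool)
    for chrom, lgrp in loop_df.groupby("chrom", sort=False):
        sel = interactions["chrom"] == chrom
        if not sel.any():
            continue
        i1 = interactions.loc[sel, "bin1"].to_numpy() * bs
        i2 = interactions.loc[sel, "bin2"].to_numpy() * bs
        l1 = lgrp["bin1"].to_numpy() * bs
        l2 = lgrp["bin2"].to_numpy() * bs
        d1 = np.abs(i1[:, None] - l1[None, :])
        d2 = np.abs(i2[:, None] - l2[None, :])
        near = ((d1 <= radius_bp) & (d2 <= radius_bp)).any(axis=1)
        keep[np.nonzero(sel.to_numpy())[0][near]] = False
    return interactions.loc[keep].reset_index(drop=True)


def classify(interactions: pd.DataFrame, ann: BinAnnotation) -> pd.DataFrame:
    """Assign each interaction exactly one category: E-P, E-E, P-P, other."""
    out = interactions.copy()
    if len(out) == 0:
        out["category"] = pd.Series(dtype=object)
        return out
    off = np.array([ann.bins.offset(c) for c in out["chrom"]])
    g1 = off + out["bin1"].to_numpy()
    g2 = off + out["bin2"].to_numpy()
    e1, e2 = ann.has_enhancer[g1], ann.has_enhancer[g2]
    p1, p2 = ann.has_promoter[g1], ann.has_promoter[g2]
    category = np.select(
        [e1 & e2, p1 & p2, (e1 & p2) | (p1 & e2)],
        ["E-E", "P-P", "E-P"],
        default="other",
    )
    out["category"] = category
    return out


def diff_interactions(
    interactions: pd.DataFrame,
    z_a: DistNormMap,
    z_b: DistNormMap,
    min_z: float = 2.0,
    min_fold: float = 2.5,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Differential interactions under the same z>2 & fold>=2.5 rule as
    loops, reading the 3x3 max z per condition at each pixel."""
    za_vals, zb_vals = [], []
    for _, row in interactions.iterrows():
        za_vals.append(peak_z(z_a.z[row["chrom"]], int(row["bin1"]), int(row["bin2"])))
        zb_vals.append(peak_z(z_b.z[row["chrom"]], int(row["bin1"]), int(row["bin2"])))
    out = interactions.copy()
    out[f"z_{labels[0]}"] = za_vals
    out[f"z_{labels[1]}"] = zb_vals
    fold, flagged, direction = apply_differential_rule(
        np.array(za_vals), np.array(zb_vals), min_z=min_z, min_fold=min_fold
    )
    out["fold"] = fold
    out["flagged"] = flagged
    out["direction"] = np.where(
        direction == "A-specific", f"{labels[0]}-specific", f"{labels[1]}-specific"
    )
    return out


# ---------------------------------------------------------------------------
# Gene-level summaries
# ---------------------------------------------------------------------------

def gene_connectivity(
    interactions: pd.DataFrame,
    promoter_bins: dict[str, list[tuple[str, int]]],
    expression: pd.DataFrame | None = None,
    expr_group: str | None = None,
) -> pd.DataFrame:
    """Count distinct enhancer bins linked to each gene's promoter bin(s).

    ``promoter_bins`` maps gene -> list of (chrom, chrom-local bin).
    E-P interactions only. Genes are binned into {0,1,2,3,4,5,>5}
    connectivity classes; with an expression table the per-gene TPM of
    ``expr_group`` is joined so class means can be reported.
    """
    ep = interactions[interactions["category"] == "E-P"] if "category" in interactions else interactions
    # promoter side is whichever bin is a promoter; build bin -> partners
    partners: dict[tuple[str, int], set[tuple[str, int]]] = {}
    for _, row in ep.iterrows():
        key1 = (row["chrom"], int(row["bin1"]))
        key2 = (row["chrom"], int(row["bin2"]))
        partners.setdefault(key1, set()).add(key2)
        partners.setdefault(key2, set()).add(key1)
    rows = []
    for gene, pbins in promoter_bins.items():
        enh = set()
        for key in pbins:
            enh |= partners.get(tuple(key), set())
        count = len(enh)
        cls = ">5" if count > 5 else str(count)
        row = {"gene": gene, "n_enhancers": count, "class": cls}
        if expression is not None and expr_group is not None and gene in expression.index:
            row["tpm"] = float(expression.loc[gene, expr_group])
        rows.append(row)
    return pd.DataFrame(rows)


def connectivity_expression_summary(conn: pd.DataFrame) -> pd.DataFrame:
    """Mean TPM per connectivity class, ordered 0..5, >5."""
    order = ["0", "1", "2", "3", "4", "5", ">5"]
    g = conn.groupby("class")["tpm"].agg(["mean", "count"])
    return g.reindex([c for c in order if c in g.index])


def overlap_test(
    set1: set[str], set2: set[str], universe: set[str]
) -> dict:
    """Overlap size and upper-tail hypergeometric p given a gene universe."""
    if not universe:
        raise ValueError("empty universe")
    if not (set1 <= universe and set2 <= universe):
        raise ValueError("sets must be subsets of the universe")
    k = len(set1 & set2)
    n = len(universe)
    p = stats.hypergeom.sf(k - 1, n, len(set1), len(set2))
    return {
        "overlap": k,
        "p_value": float(p),
        "expected": len(set1) * len(set2) / n,
        "fraction_of_set2": k / len(set2) if set2 else np.nan,
    }


def overlap_percentage(n_overlap: int, n_total: int) -> float:
    """Shared elements as a percentage of a comparison set (e.g. the
    fraction of condition-specific loops also changed in a second
    contrast)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_overlap / n_total
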