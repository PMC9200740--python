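"""Synthetic replicated two-condition Hi-C with planted, recoverable truth.

The generator draws each replicate's contacts by multinomial sampling of a
fixed total depth over cell probabilities

    p(i,j)  proportional to  d^-alpha * (1 + gamma * e_i * e_j) * m(i,j)

where d = |i-j| bins (d=0 treated as d=1), e is a per-bin compartment
latent in [-1, 1] (a square wave of configurable period, optionally
jittered), and m(i,j) multiplies in planted loop and interaction folds.
Trans cells receive a uniform probability sized to a requested trans
fraction. Condition effects are sign flips of e over windows and per-
element fold overrides; replicate-to-replicate variation is sampling only.

The fixed-total multinomial (rather than independent Poisson cells) makes
equal-depth comparisons exact by construction, mirroring the equal-depth
random downsampling applied to real libraries before any comparison.

Matching annotation files are emitted alongside: TSS at promoter bins,
ATAC peaks at enhancer bins and loop anchors, CTCF motifs at loop anchors
with convergent strands, and a TPM table with planted X escapees and with
expression scaled by planted enhancer connectivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinTable, ChromSizes, Interval, write_bed
from .contacts import ContactMap, write_contacts


@dataclass
class ConditionEffect:
    """Per-condition modifications of the base truth."""

    compartment_flips: list[tuple[str, int, int]] = field(default_factory=list)
    # chrom-local half-open bin windows whose latent e is sign-flipped
    loop_folds: dict[int, float] = field(default_factory=dict)
    # loop index -> fold override in this condition
    interaction_folds: dict[int, float] = field(default_factory=dict)


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic dataset.

    Defaults are the package's toy stated world: 2 chromosomes (one
    autosome, one X) of 500 bins at 10 kb, depth 2e6 contacts per
    replicate, distance-decay exponent alpha=1, checkerboard strength
    gamma=0.4 with a 40-bin square-wave period, cis-only, 3 replicates
    per condition.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chrX": 5_000_000}
    )
    bin_size: int = 10_000
    depth: int = 2_000_000
    decay_exponent: float = 1.0
    gamma: float = 0.4
    compartment_period: int = 40
    compartment_jitter: float = 0.0
    loops: list[tuple[str, int, int, float]] = field(default_factory=list)
    # (chrom, bin_i, bin_j, fold) with chrom-local bin ids, bin_i < bin_j
    interactions: list[tuple[str, int, int, float]] = field(default_factory=list)
    interaction_spread: int = 1
    # half-width of the enriched patch around each interaction: loops are
    # punctate single pixels, enhancer-promoter contacts are diffuse
    trans_rate: float = 0.0
    conditions: list[str] = field(default_factory=lambda: ["A", "B"])
    condition_effects: dict[str, ConditionEffect] = field(default_factory=dict)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not (0 <= self.trans_rate < 1):
            raise ValueError("trans_rate must be in [0, 1)")
        for rec in list(self.loops) + list(self.interactions):
            if rec[3] < 1:
                raise ValueError("planted folds must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth as realised per condition; what recovery tests read."""

    bins: BinTable
    compartments: dict[str, dict[str, np.ndarray]]  # condition -> chrom -> e
    loops: pd.DataFrame        # chrom, bin1, bin2, gid1, gid2, fold_<cond>, differential
    interactions: pd.DataFrame  # same layout + category
    promoter_bins: np.ndarray   # global bin ids
    enhancer_bins: np.ndarray
    genes: pd.DataFrame         # gene, chrom, tss, promoter_gid, n_enhancers
    escapees: list[str]
    trans_rate: float


@dataclass
class SyntheticDataset:
    bins: BinTable
    maps: dict[str, list[ContactMap]]  # condition -> replicates
    atac: list[Interval]
    tss: list[Interval]
    ctcf: list[Interval]
    expression: pd.DataFrame
    truth: SyntheticTruth | None = None


def _square_wave(n: int, period: int, jitter: float, rng: np.random.Generator) -> np.ndarray:
    e = np.where((np.arange(n) // (period // 2)) % 2 == 0, 1.0, -1.0)
    if jitter > 0:
        e = np.clip(e + rng.normal(0, jitter, n), -1, 1)
    return e


def _condition_profiles(spec: SyntheticSpec, bins: BinTable) -> dict[str, dict[str, np.ndarray]]:
    rng = np.random.default_rng([spec.seed, 7])
    base = {
        chrom: _square_wave(
            bins.n_bins_of(chrom), spec.compartment_period, spec.compartment_jitter, rng
        )
        for chrom in bins.sizes.names
    }
    out: dict[str, dict[str, np.ndarray]] = {}
    for cond in spec.conditions:
        prof = {c: e.copy() for c, e in base.items()}
        eff = spec.condition_effects.get(cond)
        if eff:
            for chrom, lo, hi in eff.compartment_flips:
                prof[chrom][lo:hi] *= -1
        out[cond] = prof
    return out


def _cell_grid(bins: BinTable, spec: SyntheticSpec):
    """Global upper-triangle cell index arrays: cis per chromosome + trans."""
    ii, jj, cis_flag = [], [], []
    for chrom in bins.sizes.names:
        o = bins.offset(chrom)
        n = bins.n_bins_of(chrom)
        iu, ju = np.triu_indices(n)
        ii.append(iu + o)
        jj.append(ju + o)
        cis_flag.append(np.ones(iu.size, dtype=bool))
    if spec.trans_rate > 0:
        names = bins.sizes.names
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                oa, ob = bins.offset(names[a]), bins.offset(names[b])
                na, nb = bins.n_bins_of(names[a]), bins.n_bins_of(names[b])
                gi, gj = np.meshgrid(np.arange(na) + oa, np.arange(nb) + ob, indexing="ij")
                ii.append(gi.ravel())
                jj.append(gj.ravel())
                cis_flag.append(np.zeros(gi.size, dtype=bool))
    return np.concatenate(ii), np.concatenate(jj), np.concatenate(cis_flag)


def _cell_probs(
    spec: SyntheticSpec,
    bins: BinTable,
    profile: dict[str, np.ndarray],
    loop_folds: np.ndarray,
    inter_folds: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    cis: np.ndarray,
) -> np.ndarray:
    w = np.zeros(ii.size)
    e_global = np.concatenate([profile[c] for c in bins.sizes.names])
    d = (jj - ii).astype(float)
    wcis = np.maximum(d[cis], 1.0) ** (-spec.decay_exponent)
    wcis *= 1.0 + spec.gamma * e_global[ii[cis]] * e_global[jj[cis]]
    w[cis] = wcis
    # loops/interactions are few; locate their cells by key search
    keys = ii.astype(np.int64) * bins.n_bins + jj
    order = np.argsort(keys)
    sorted_keys = keys[order]

    def locate(g1: int, g2: int, what: str) -> int:
        k = np.searchsorted(sorted_keys, g1 * bins.n_bins + g2)
        if k >= sorted_keys.size or sorted_keys[k] != g1 * bins.n_bins + g2:
            raise ValueError(f"planted {what} cell ({g1},{g2}) not in grid")
        return int(order[k])

    for (g1, g2), f in _iter_folds(spec.loops, bins, loop_folds):
        w[locate(g1, g2, "loop")] *= f
    s = spec.interaction_spread
    for (g1, g2), f in _iter_folds(spec.interactions, bins, inter_folds):
        for di in range(-s, s + 1):
            for dj in range(-s, s + 1):
                a, b = g1 + di, g2 + dj
                if a < b:
                    w[locate(min(a, b), max(a, b), "interaction")] *= f
    cis_total = w[cis].sum()
    if spec.trans_rate > 0:
        n_trans = (~cis).sum()
        w[~cis] = spec.trans_rate / (1 - spec.trans_rate) * cis_total / n_trans
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("probability normalisation failure")
    return w / total


def _iter_folds(elements, bins: BinTable, folds: np.ndarray):
    for k, (chrom, b1, b2, _f) in enumerate(elements):
        o = bins.offset(chrom)
        yield (o + min(b1, b2), o + max(b1, b2)), folds[k]


def _element_folds(elements, overrides: dict[int, float]) -> np.ndarray:
    f = np.array([rec[3] for rec in elements], dtype=float)
    for k, v in overrides.items():
        f[k] = v
    return f


def _annotations(spec: SyntheticSpec, bins: BinTable, rng: np.random.Generator):
    """Place TSS/ATAC/CTCF and the expression table consistently with truth.

    Promoter bins host one gene TSS each; enhancer bins host one ATAC peak
    placed so it sits > 10 kb from every TSS (its own bin and neighbours
    are TSS-free by construction). Loop anchors get an ATAC peak and a
    CTCF motif, convergent by default.
    """
    bs = bins.bin_size
    promoter_gids: list[int] = []
    enhancer_gids: list[int] = []
    genes: list[dict] = []
    tss: list[Interval] = []
    atac: list[Interval] = []
    ctcf: list[Interval] = []

    inter_cells = {(c, b1): "enh" for c, b1, b2, f in spec.interactions}
    # promoter side of each planted interaction is bin2; enhancer side bin1
    pro_bins: dict[str, set[int]] = {c: set() for c in bins.sizes.names}
    enh_bins: dict[str, set[int]] = {c: set() for c in bins.sizes.names}
    for chrom, b1, b2, _f in spec.interactions:
        enh_bins[chrom].add(min(b1, b2))
        pro_bins[chrom].add(max(b1, b2))
    anchor_bins: dict[str, set[int]] = {c: set() for c in bins.sizes.names}
    for chrom, b1, b2, _f in spec.loops:
        anchor_bins[chrom].update((b1, b2))

    # extra genes for expression summaries: every chromosome gets a ladder of
    # promoters away from planted elements
    for chrom in bins.sizes.names:
        n = bins.n_bins_of(chrom)
        used = pro_bins[chrom] | enh_bins[chrom] | anchor_bins[chrom]
        forbidden = set()
        for b in used:
            forbidden.update((b - 1, b, b + 1))
        extra = [b for b in range(5, n - 5, max(n // 12, 1)) if b not in forbidden][:8]
        pro_bins[chrom].update(extra)

    gid_counter = 0
    for chrom in bins.sizes.names:
        o = bins.offset(chrom)
        for b in sorted(pro_bins[chrom]):
            gid_counter += 1
            name = f"gene_{chrom}_{b}"
            pos = int(bins.start[o + b]) + bs // 2
            tss.append(Interval(chrom, pos, pos + 1, name, "+"))
            # promoter-proximal accessibility
            atac.append(Interval(chrom, pos - 200, pos + 200, f"atac_pro_{name}"))
            genes.append(
                {"gene": name, "chrom": chrom, "tss": pos, "promoter_gid": o + b}
            )
            promoter_gids.append(o + b)
        for b in sorted(enh_bins[chrom]):
            pos = int(bins.start[o + b]) + bs // 2
            atac.append(Interval(chrom, pos - 300, pos + 300, f"atac_enh_{chrom}_{b}"))
            enhancer_gids.append(o + b)
        for b in sorted(anchor_bins[chrom]):
            pos = int(bins.start[o + b]) + bs // 2
            atac.append(Interval(chrom, pos - 250, pos + 250, f"atac_anchor_{chrom}_{b}"))
    # convergent CTCF motifs: + at the left anchor, - at the right
    for chrom, b1, b2, _f in spec.loops:
        o = bins.offset(chrom)
        lo, hi = min(b1, b2), max(b1, b2)
        p1 = int(bins.start[o + lo]) + bs // 2
        p2 = int(bins.start[o + hi]) + bs // 2
        ctcf.append(Interval(chrom, p1 - 10, p1 + 9, f"ctcf_{chrom}_{lo}", "+"))
        ctcf.append(Interval(chrom, p2 - 10, p2 + 9, f"ctcf_{chrom}_{hi}", "-"))

    genes_df = pd.DataFrame(genes)
    return (
        np.array(sorted(set(promoter_gids)), dtype=np.int64),
        np.array(sorted(set(enhancer_gids)), dtype=np.int64),
        genes_df,
        tss,
        atac,
        ctcf,
    )


def _expression(
    spec: SyntheticSpec,
    bins: BinTable,
    genes: pd.DataFrame,
    truth_inter: pd.DataFrame,
    rng: np.random.Generator,
    n_escapees: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """TPM table: expression scales with planted enhancer connectivity;
    the first female condition carries planted X escapees vs a Male column."""
    conn = {g: 0 for g in genes["gene"]}
    pro_to_gene = dict(zip(genes["promoter_gid"], genes["gene"]))
    for _, row in truth_inter.iterrows():
        g = pro_to_gene.get(row["gid2"])
        if g is not None:
            conn[g] += 1
    genes = genes.assign(n_enhancers=[conn[g] for g in genes["gene"]])
    groups = list(spec.conditions)
    if "Male" not in groups:
        groups.append("Male")
    base = 0.5 + 2.0 * genes["n_enhancers"].to_numpy(dtype=float)
    tpm = {}
    for g in groups:
        noise = rng.lognormal(0, 0.1, len(genes))
        tpm[g] = base * noise
    expr = pd.DataFrame(tpm, index=genes["gene"]).rename_axis("gene")
    # plant escapees among X genes: female TPM >= 1 and >= 1.5x male
    x_names = [c for c in bins.sizes.names if bins.sizes.is_sex[c]]
    x_genes = genes.loc[genes["chrom"].isin(x_names), "gene"].tolist()
    female = spec.conditions[0]
    escapees = x_genes[:n_escapees]
    for k, g in enumerate(escapees):
        f_tpm = 2.0 + k
        expr.loc[g, female] = f_tpm
        expr.loc[g, "Male"] = f_tpm / (2.0 + 0.2 * k)
    for g in x_genes[n_escapees:]:
        # non-escapees: either low female expression or near-equal ratio
        expr.loc[g, "Male"] = expr.loc[g, female] * float(rng.uniform(0.9, 1.1))
    return expr, genes, escapees


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Realise a full replicated dataset plus its ground truth."""
    sizes = ChromSizes(list(spec.chrom_sizes.items()))
    bins = BinTable(sizes, spec.bin_size)
    profiles = _condition_profiles(spec, bins)
    ii, jj, cis = _cell_grid(bins, spec)

    loop_rows, inter_rows = [], []
    fold_cols_l: dict[str, np.ndarray] = {}
    fold_cols_i: dict[str, np.ndarray] = {}
    for cond in spec.conditions:
        eff = spec.condition_effects.get(cond, ConditionEffect())
        fold_cols_l[cond] = _element_folds(spec.loops, eff.loop_folds)
        fold_cols_i[cond] = _element_folds(spec.interactions, eff.interaction_folds)

    maps: dict[str, list[ContactMap]] = {}
    for c_idx, cond in enumerate(spec.conditions):
        p = _cell_probs(
            spec, bins, profiles[cond], fold_cols_l[cond], fold_cols_i[cond],
            ii, jj, cis,
        )
        reps = []
        for r in range(spec.n_replicates):
            rng = np.random.default_rng([spec.seed, 11, c_idx, r])
            counts = rng.multinomial(spec.depth, p)
            nz = counts > 0
            reps.append(
                ContactMap.from_triplets(bins, ii[nz], jj[nz], counts[nz].astype(float))
            )
        maps[cond] = reps

    for k, (chrom, b1, b2, f) in enumerate(spec.loops):
        o = bins.offset(chrom)
        row = {
            "chrom": chrom, "bin1": min(b1, b2), "bin2": max(b1, b2),
            "gid1": o + min(b1, b2), "gid2": o + max(b1, b2),
        }
        for cond in spec.conditions:
            row[f"fold_{cond}"] = fold_cols_l[cond][k]
        row["differential"] = len({round(fold_cols_l[c][k], 9) for c in spec.conditions}) > 1
        loop_rows.append(row)
    for k, (chrom, b1, b2, f) in enumerate(spec.interactions):
        o = bins.offset(chrom)
        row = {
            "chrom": chrom, "bin1": min(b1, b2), "bin2": max(b1, b2),
            "gid1": o + min(b1, b2), "gid2": o + max(b1, b2),
        }
        for cond in spec.conditions:
            row[f"fold_{cond}"] = fold_cols_i[cond][k]
        row["differential"] = len({round(fold_cols_i[c][k], 9) for c in spec.conditions}) > 1
        inter_rows.append(row)
    loops_df = pd.DataFrame(loop_rows)
    inter_df = pd.DataFrame(
        inter_rows,
        columns=["chrom", "bin1", "bin2", "gid1", "gid2"]
        + [f"fold_{c}" for c in spec.conditions] + ["differential"],
    )

    ann_rng = np.random.default_rng([spec.seed, 13])
    promoter_gids, enhancer_gids, genes_df, tss, atac, ctcf = _annotations(
        spec, bins, ann_rng
    )
    expr, genes_df, escapees = _expression(spec, bins, genes_df, inter_df, ann_rng)

    truth = SyntheticTruth(
        bins=bins,
        compartments=profiles,
        loops=loops_df,
        interactions=inter_df,
        promoter_bins=promoter_gids,
        enhancer_bins=enhancer_gids,
        genes=genes_df,
        escapees=escapees,
        trans_rate=spec.trans_rate,
    )
    return SyntheticDataset(bins, maps, atac, tss, ctcf, expr, truth)


def null_pair(spec: SyntheticSpec | None = None, seed: int = 0) -> SyntheticDataset:
    """Two conditions with identical parameters: zero planted differences.

    Any differential call made on this pair is a false positive; the
    calibration tests run the callers across seeds on its output.
    """
    base = spec or SyntheticSpec()
    null_spec = SyntheticSpec(
        chrom_sizes=dict(base.chrom_sizes),
        bin_size=base.bin_size,
        depth=base.depth,
        decay_exponent=base.decay_exponent,
        gamma=base.gamma,
        compartment_period=base.compartment_period,
        compartment_jitter=base.compartment_jitter,
        loops=list(base.loops),
        interactions=list(base.interactions),
        trans_rate=base.trans_rate,
        conditions=["A", "B"],
        condition_effects={},
        n_replicates=base.n_replicates,
        seed=seed,
    )
    ds = generate(null_spec)
    assert not bool(ds.truth.loops["differential"].any()) if len(ds.truth.loops) else True
    return ds


def demo_spec(seed: int = 0, depth: int = 2_000_000, n_replicates: int = 3) -> SyntheticSpec:
    """The standard three-group demo world used by the examples and the
    end-to-end pipeline run.

    Groups mirror a dioestrus/proestrus/male design: "Pro" carries a
    compartment sign-flip window on chrX plus loop and enhancer-promoter
    interaction losses relative to "Die"; "Male" carries the same chrX
    flip window plus a second one (so the Pro-Die and Male-Die contrasts
    are concordant in direction on the shared window).
    """
    # anchors are centred within compartment blocks (bin = 10 mod 20 for
    # the default 40-bin period) so the planted punctate signal is not
    # confounded with block edges; parities are mixed on purpose. On chrX
    # the anchors avoid the condition flip windows [200,240) and [320,360)
    # so compartment effects and loop/interaction effects stay separable,
    # and the differential elements sit on same-parity (within-compartment)
    # anchor pairs where the fold-change read-out is cleanest.
    chr1_loops = [(10, 50), (90, 150), (170, 230), (250, 330), (350, 410), (430, 470)]
    chrx_loops = [(10, 50), (90, 150), (110, 170), (30, 130), (370, 430), (410, 470)]
    chr1_inter = [(30, 70), (110, 190), (210, 270), (290, 370), (390, 450)]
    chrx_inter = [(70, 190), (250, 290), (270, 310), (390, 450)]
    loops = [("chr1", a, b, 5.0) for a, b in chr1_loops] + [
        ("chrX", a, b, 5.0) for a, b in chrx_loops
    ]
    interactions = [("chr1", a, b, 5.0) for a, b in chr1_inter] + [
        ("chrX", a, b, 5.0) for a, b in chrx_inter
    ]
    effects = {
        "Pro": ConditionEffect(
            compartment_flips=[("chrX", 200, 240)],
            loop_folds={0: 1.0, 6: 1.0},          # loops lost in Pro (AA anchors)
            interaction_folds={1: 1.0, 6: 1.0},   # interactions lost in Pro
        ),
        "Male": ConditionEffect(
            compartment_flips=[("chrX", 200, 240), ("chrX", 320, 360)],
        ),
    }
    return SyntheticSpec(
        depth=depth,
        loops=loops,
        interactions=interactions,
        conditions=["Die", "Pro", "Male"],
        condition_effects=effects,
        n_replicates=n_replicates,
        seed=seed,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict:
    """Emit triplet contacts, BED annotations, TPM TSV and truth JSON.

    Returns the manifest (also written as ``manifest.json``)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"bin_size": ds.bins.bin_size, "contacts": {}}
    with open(out / "chrom.sizes", "w") as fh:
        for name in ds.bins.sizes.names:
            fh.write(f"{name}\t{ds.bins.sizes[name]}\n")
    manifest["chromsizes"] = "chrom.sizes"
    for cond, reps in ds.maps.items():
        paths = []
        for r, cmap in enumerate(reps):
            p = f"contacts_{cond}_rep{r}.txt"
            write_contacts(cmap, out / p)
            paths.append(p)
        manifest["contacts"][cond] = paths
    write_bed(ds.atac, out / "atac_peaks.bed")
    write_bed(ds.tss, out / "tss.bed")
    write_bed(ds.ctcf, out / "ctcf_motifs.bed")
    ds.expression.to_csv(out / "expression_tpm.tsv", sep="\t")
    manifest.update(
        atac="atac_peaks.bed", tss="tss.bed", ctcf="ctcf_motifs.bed",
        expression="expression_tpm.tsv",
    )
    truth = {
        "escapees": ds.truth.escapees,
        "trans_rate": ds.truth.trans_rate,
        "loops": ds.truth.loops.to_dict(orient="list"),
        "interactions": ds.truth.interactions.to_dict(orient="list"),
        "promoter_bins": ds.truth.promoter_bins.tolist(),
        "enhancer_bins": ds.truth.enhancer_bins.tolist(),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    manifest["truth"] = "truth.json"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_dataset(indir: str | Path) -> SyntheticDataset:
    """Load a dataset directory written by :func:`write_dataset`.

    The truth object is reconstructed from ``truth.json`` where present
    (without the per-condition compartment profiles, which are not
    serialised); otherwise ``truth`` is None.
    """
    from .genome import read_bed, read_chromsizes, read_expression
    from .contacts import load_contacts

    ind = Path(indir)
    with open(ind / "manifest.json") as fh:
        manifest = json.load(fh)
    sizes = read_chromsizes(ind / manifest["chromsizes"])
    bins = BinTable(sizes, manifest["bin_size"])
    maps = {
        cond: [load_contacts(ind / p, bins) for p in paths]
        for cond, paths in manifest["contacts"].items()
    }
    atac = read_bed(ind / manifest["atac"], sizes)
    tss = read_bed(ind / manifest["tss"], sizes)
    ctcf = read_bed(ind / manifest["ctcf"], sizes)
    expr = read_expression(ind / manifest["expression"])
    truth = None
    truth_path = ind / manifest.get("truth", "truth.json")
    if truth_path.exists():
        with open(truth_path) as fh:
            t = json.load(fh)
        truth = SyntheticTruth(
            bins=bins,
            compartments={},
            loops=pd.DataFrame(t["loops"]),
            interactions=pd.DataFrame(t["interactions"]),
            promoter_bins=np.asarray(t["promoter_bins"], dtype=np.int64),
            enhancer_bins=np.asarray(t["enhancer_bins"], dtype=np.int64),
            genes=pd.DataFrame(),
            escapees=list(t["escapees"]),
            trans_rate=float(t["trans_rate"]),
        )
    return SyntheticDataset(bins, maps, atac, tss, ctcf, expr, truth)
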