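"""End-to-end orchestration: replicate QC, equal-depth combination, and
the three analysis levels (compartments, loops, enhancer-promoter
interactions) with their differential calls, tied together into one
machine-readable report.

Defaults equal the published analysis parameters: compartment threshold
tau=0.42, loop FDR 0.01 with a 25-kb master merge, differential rule
z > 2 and fold >= 2.5, interaction q < 0.05 with 20-kb loop exclusion,
>10-kb enhancer proxy, escapee rule TPM >= 1 and >= 1.5-fold. The
differential stages compare the first two conditions; with a third
condition present the direction-concordance of the second and third
contrasts against the first condition is also reported.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartments as comp
from . import contacts as ct
from . import expression as xp
from . import interactions as ia
from . import loops as lp
from .genome import BinTable, intervals_per_bin, write_bedgraph, write_bedpe
from .simulate import SyntheticDataset, load_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults are the published values."""

    data_dir: str | None = None          # dataset directory (manifest.json), or
    dataset: SyntheticDataset | None = None  # an in-memory dataset
    out_dir: str | None = None
    tau: float | str = 0.42
    loop_fdr: float = 0.01
    merge_radius_bp: int = 25_000
    min_z: float = 2.0
    min_fold: float = 2.5
    q_max: float = 0.05
    exclusion_radius_bp: int = 20_000
    enhancer_min_dist: int = 10_000
    escapee_min_tpm: float = 1.0
    escapee_min_fold: float = 1.5
    female_group: str | None = None      # defaults to the first condition
    male_group: str = "Male"
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = [
            self.loop_fdr, self.merge_radius_bp, self.min_z, self.min_fold,
            self.q_max, self.exclusion_radius_bp, self.enhancer_min_dist,
            self.escapee_min_tpm, self.escapee_min_fold,
        ]
        if isinstance(self.tau, (int, float)):
            numeric.append(float(self.tau))
        if any(v <= 0 for v in numeric):
            raise ValueError("all thresholds must be positive")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return (and optionally write) the report.

    Deterministic given ``config.seed``. Differential stages are skipped
    with a notice when only one condition is present; any stage failure
    raises with the stage name attached.
    """
    t0 = time.time()
    stage = "load"
    report: dict = {"config": {k: v for k, v in asdict(config).items() if k != "dataset"}}
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    try:
        ds = config.dataset if config.dataset is not None else load_dataset(config.data_dir)
        bins = ds.bins
        conditions = list(ds.maps.keys())
        report["conditions"] = conditions
        report["bin_size"] = bins.bin_size

        # -- replicate QC ------------------------------------------------
        stage = "replicate_qc"
        rep_maps, rep_labels = [], []
        cap = None
        for cond in conditions:
            for r, m in enumerate(ds.maps[cond]):
                b, e, z = ct.prepare(m)
                cap = ct.informative_max_dist(e) if cap is None else cap
                rep_maps.append(z)
                rep_labels.append(f"{cond}_rep{r}")
        if len(rep_maps) >= 2:
            D, emb = ct.replicate_distances(rep_maps, max_dist_bins=cap)
            groups = [lab.rsplit("_rep", 1)[0] for lab in rep_labels]
            within, between = [], []
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    (within if groups[i] == groups[j] else between).append(D[i, j])
            report["replicates"] = {
                "labels": rep_labels,
                "within_group_mean_distance": float(np.mean(within)) if within else None,
                "between_group_mean_distance": float(np.mean(between)) if between else None,
                "embedding": emb.tolist(),
            }

        # -- equal-depth combination ------------------------------------
        stage = "combine"
        combined: dict[str, ct.ContactMap] = {
            cond: ct.sum_maps(ds.maps[cond]) for cond in conditions
        }
        target = int(min(m.total_contacts for m in combined.values()))
        for k, cond in enumerate(conditions):
            combined[cond] = ct.downsample(combined[cond], target, seed=config.seed + k)
        report["equal_depth_total"] = target

        stage = "normalize"
        balanced = {c: ct.balance(m) for c, m in combined.items()}
        expected = {c: ct.expected_by_distance(balanced[c]) for c in conditions}
        zmaps = {c: ct.distance_normalize(balanced[c], expected[c]) for c in conditions}

        stage = "trans_fraction"
        trans = {}
        for cond in conditions:
            g, per = ct.trans_fraction(combined[cond], by_chromosome=True)
            trans[cond] = {"global_trans": g, "cis_fraction": 1 - g, "per_chromosome": per}
        report["trans_fractions"] = trans

        # -- compartments -------------------------------------------------
        stage = "compartments"
        atac_density = intervals_per_bin(ds.atac, bins)
        tracks = {
            c: comp.call_eigenvector(balanced[c], orient_track=atac_density)
            for c in conditions
        }
        sex = set(bins.sizes.sex_chromosomes())
        contrasts: dict[str, dict[str, comp.DiffCompartmentResult]] = {}
        if len(conditions) >= 2:
            ref = conditions[0]
            for other in conditions[1:]:
                diffs = {
                    chrom: comp.diff_compartments(tracks[other][chrom], tracks[ref][chrom], tau=config.tau)
                    for chrom in tracks[ref]
                    if chrom in tracks[other]
                }
                contrasts[f"{other}_vs_{ref}"] = diffs
            report["diff_compartments"] = {
                name: comp.diff_summary(d, bins.bin_size).to_dict(orient="records")
                for name, d in contrasts.items()
            }
            if sex and (set(tracks[conditions[0]]) - sex):
                report["x_vs_autosome"] = {
                    name: comp.compare_groups(d, sex) for name, d in contrasts.items()
                }
            if len(contrasts) >= 2:
                names = list(contrasts)
                report["direction_concordance"] = {
                    f"{names[0]}|{names[1]}": comp.direction_concordance(
                        contrasts[names[0]], contrasts[names[1]]
                    )
                }
        else:
            report["diff_compartments"] = "skipped: single condition"
        if out:
            for c in conditions:
                e = np.full(bins.n_bins, np.nan)
                for chrom, tr in tracks[c].items():
                    e[bins.chrom_slice(chrom)] = tr.e
                write_bedgraph(bins, e, out / f"eigenvector_{c}.bedgraph")

        # -- loops ---------------------------------------------------------
        stage = "loops"
        loop_sets = {
            c: lp.call_loops(
                zmaps[c], combined[c], expected[c], fdr=config.loop_fdr, sample=c
            )
            for c in conditions
        }
        master = lp.merge_master(
            list(loop_sets.values()), radius_bp=config.merge_radius_bp, bin_size=bins.bin_size
        )
        annotated = lp.annotate_anchors(master.loops, bins, ds.atac, ds.ctcf)
        composition = lp.anchor_composition(annotated)
        report["loops"] = {
            "per_sample_counts": {c: len(s) for c, s in loop_sets.items()},
            "master_count": len(master),
            "n_anchors": len(master.anchors()),
            "anchor_composition": composition.to_dict(),
            "convergence": annotated["convergence"].value_counts().to_dict(),
        }
        if len(conditions) >= 2:
            a, b = conditions[0], conditions[1]
            dl = lp.diff_loops(
                master, zmaps[a], zmaps[b],
                min_z=config.min_z, min_fold=config.min_fold, labels=(a, b),
            )
            report["diff_loops"] = {
                "flagged": int(dl["flagged"].sum()),
                "by_direction": dl.loc[dl["flagged"], "direction"].value_counts().to_dict(),
            }
            if out:
                _write_pairs_bedpe(dl, bins, out / "diff_loops.bedpe")
        if len(master) and out:
            _write_pairs_bedpe(annotated, bins, out / "master_loops.bedpe")
        if len(master):
            try:
                ap = lp.apa(zmaps[conditions[0]], master.loops)
                report["loops"]["apa_score"] = ap["score"]
            except ValueError:
                report["loops"]["apa_score"] = None

        stage = "insulation"
        ins = lp.insulation(balanced[conditions[0]])
        if out:
            track = np.full(bins.n_bins, np.nan)
            for chrom, v in ins.items():
                track[bins.chrom_slice(chrom)] = v
            write_bedgraph(bins, track, out / f"insulation_{conditions[0]}.bedgraph")

        # -- interactions --------------------------------------------------
        stage = "interactions"
        pooled = ct.sum_maps(list(combined.values()))
        sig = ia.call_significant(pooled, q_max=config.q_max)
        sig = ia.exclude_loops(sig, master, bins, radius_bp=config.exclusion_radius_bp)
        ann = ia.build_bin_annotation(
            bins, ds.atac, ds.tss, enhancer_min_dist=config.enhancer_min_dist
        )
        sig = ia.classify(sig, ann)
        report["interactions"] = {
            "n_significant": len(sig),
            "by_category": sig["category"].value_counts().to_dict(),
        }
        if len(conditions) >= 2:
            a, b = conditions[0], conditions[1]
            di = ia.diff_interactions(
                sig, zmaps[a], zmaps[b],
                min_z=config.min_z, min_fold=config.min_fold, labels=(a, b),
            )
            ep = di[di["category"] == "E-P"]
            report["diff_interactions"] = {
                "flagged": int(di["flagged"].sum()),
                "flagged_ep": int(ep["flagged"].sum()),
                "by_direction": di.loc[di["flagged"], "direction"].value_counts().to_dict(),
            }
            if out:
                _write_pairs_bedpe(di, bins, out / "interactions.bedpe")

        # -- gene-level integration ---------------------------------------
        stage = "gene_connectivity"
        promoter_bins: dict[str, list[tuple[str, int]]] = {}
        for t in ds.tss:
            b = t.start // bins.bin_size
            promoter_bins.setdefault(t.name, []).append((t.chrom, int(b)))
        expr_group = conditions[0] if conditions[0] in ds.expression.columns else ds.expression.columns[0]
        conn = ia.gene_connectivity(sig, promoter_bins, ds.expression, expr_group)
        report["gene_connectivity"] = {
            "by_class": ia.connectivity_expression_summary(conn).to_dict(orient="index")
            if "tpm" in conn else conn["class"].value_counts().to_dict(),
        }
        if out:
            conn.to_csv(out / "gene_connectivity.tsv", sep="\t", index=False)

        stage = "escapees"
        female = config.female_group or conditions[0]
        if female in ds.expression.columns and config.male_group in ds.expression.columns:
            x_names = set(bins.sizes.sex_chromosomes())
            x_genes = sorted(
                {t.name for t in ds.tss if t.chrom in x_names} & set(ds.expression.index)
            )
            if x_genes:
                esc = xp.call_escapees(
                    ds.expression, female, config.male_group, x_genes,
                    min_tpm=config.escapee_min_tpm, min_fold=config.escapee_min_fold,
                )
                report["escapees"] = {
                    "n_flagged": int(esc["flagged"].sum()),
                    "top5": esc.loc[esc["flagged"], "gene"].head(5).tolist(),
                }
                if out:
                    esc.to_csv(out / "escapees.tsv", sep="\t", index=False)
        else:
            report["escapees"] = "skipped: missing female/male expression groups"

        report["runtime_s"] = round(time.time() - t0, 2)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = _jsonable(report)
    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _write_pairs_bedpe(df: pd.DataFrame, bins: BinTable, path: Path) -> None:
    if not len(df):
        return
    off = np.array([bins.offset(c) for c in df["chrom"]])
    g1 = off + df["bin1"].to_numpy()
    g2 = off + df["bin2"].to_numpy()
    rec = pd.DataFrame(
        {
            "chrom1": df["chrom"], "start1": bins.start[g1], "end1": bins.end[g1],
            "chrom2": df["chrom"], "start2": bins.start[g2], "end2": bins.end[g2],
        }
    )
    for c in df.columns:
        if c not in ("chrom", "bin1", "bin2"):
            rec[c] = df[c].to_numpy()
    write_bedpe(rec, path)
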