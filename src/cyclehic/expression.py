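"""Expression-table utilities: X-escapee calling and expression-matched
control selection.

An X escapee is operationally a gene expressed from the inactive X:
female TPM >= 1 and female/male ratio >= 1.5 (escape direction only). A
male TPM of 0 would make the ratio undefined; a 0.01 TPM pseudocount is
substituted and declared in the output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MALE_TPM_PSEUDOCOUNT = 0.01


def call_escapees(
    expr: pd.DataFrame,
    female_group: str,
    male_group: str,
    x_genes: list[str],
    min_tpm: float = 1.0,
    min_fold: float = 1.5,
) -> pd.DataFrame:
    """Rank X-linked genes by female/male TPM ratio and flag escapees.

    flagged <=> female TPM >= min_tpm and ratio >= min_fold. Returns the
    table sorted by descending ratio; select the top k rows for a
    "top escapees" panel.
    """
    for g in (female_group, male_group):
        if g not in expr.columns:
            raise ValueError(f"missing expression group {g!r}")
    missing = [g for g in x_genes if g not in expr.index]
    if missing:
        raise ValueError(f"x_genes absent from table: {missing[:5]}")
    female = expr.loc[x_genes, female_group].to_numpy(dtype=float)
    male = expr.loc[x_genes, male_group].to_numpy(dtype=float)
    male_adj = np.where(male > 0, male, MALE_TPM_PSEUDOCOUNT)
    ratio = female / male_adj
    out = pd.DataFrame(
        {
            "gene": x_genes,
            "female_tpm": female,
            "male_tpm": male,
            "ratio": ratio,
            "flagged": (female >= min_tpm) & (ratio >= min_fold),
        }
    )
    return out.sort_values("ratio", ascending=False).reset_index(drop=True)


def match_controls(
    targets: list[str],
    pool: list[str],
    expr: pd.DataFrame,
    group: str,
    k: int = 1,
) -> dict[str, list[str]]:
    """Expression-matched controls: the k pool genes nearest in log-TPM.

    Sampling is without replacement across targets, assigned greedily in
    target order (ties and contested neighbours go to the earlier target,
    the later one takes the next-nearest). A target is never its own
    control because the pool must be disjoint from the targets.
    """
    if set(targets) & set(pool):
        raise ValueError("pool must be disjoint from targets")
    if len(pool) < k * len(targets):
        raise ValueError("pool too small for k controls per target")
    eps = 1e-3  # log floor for zero TPM
    log_t = {g: np.log10(max(float(expr.loc[g, group]), eps)) for g in targets}
    avail = {g: np.log10(max(float(expr.loc[g, group]), eps)) for g in pool}
    out: dict[str, list[str]] = {}
    for g in targets:
        chosen = []
        for _ in range(k):
            best = min(avail, key=lambda c: (abs(avail[c] - log_t[g]), c))
            chosen.append(best)
            del avail[best]
        out[g] = chosen
    return out
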