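"""qRT-PCR relative quantification: reference-gene stability, geometric-
mean normalization, delta-delta-Ct ratios and significance tests.

Reference genes are ranked by a geNorm-style stability value M (the mean
standard deviation, over partner candidates, of pairwise log expression
ratios across samples; smaller = more stable). The per-sample
normalization factor is the arithmetic mean of the chosen reference
genes' Ct values — the geometric mean of their expression levels in
linear space. Relative expression of a target between a condition and the
control is efficiency^(-ddCt) with ddCt the difference of mean normalized
Cts, tested across biological replicates with a two-sided Student test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rank_reference_stability",
    "normalization_factor",
    "compute_ddct",
    "DdctResult",
    "standardize_log_ratios",
]


def rank_reference_stability(
    ct: pd.DataFrame, candidates: list[str] | None = None
) -> pd.DataFrame:
    """geNorm stability value M per candidate reference gene, most stable
    first. Candidates missing from any sample are excluded with a warning.

    Expression is taken as -Ct * log2(efficiency); for a candidate pair
    the pairwise variation is the SD across samples of the difference of
    their log2 expressions, and M is the mean over partners.
    """
    candidates = candidates or sorted(ct["gene"].unique())
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate reference genes")
    if ct["condition"].nunique() < 2:
        raise ValueError("need at least 2 conditions to assess stability")
    samples = sorted(ct["sample_id"].unique())
    eff = ct.groupby("gene")["efficiency"].mean()
    usable = []
    for g in candidates:
        present = set(ct.loc[ct["gene"] == g, "sample_id"])
        if present >= set(samples):
            usable.append(g)
        else:
            warnings.warn(
                f"reference candidate {g!r} missing in sample(s) "
                f"{sorted(set(samples) - present)[:3]}; excluded", stacklevel=2
            )
    if len(usable) < 3:
        raise ValueError("fewer than 3 usable candidates after exclusions")
    expr = ct[ct["gene"].isin(usable)].pivot_table(
        index="sample_id", columns="gene", values="ct", aggfunc="mean"
    )
    log_expr = -expr * np.log2(eff[expr.columns])
    m_values = {}
    for g in usable:
        sds = [
            float((log_expr[g] - log_expr[h]).std(ddof=1))
            for h in usable
            if h != g
        ]
        m_values[g] = float(np.mean(sds))
    out = pd.DataFrame(
        {"gene": list(m_values), "m_value": list(m_values.values())}
    ).sort_values(["m_value", "gene"], kind="stable").reset_index(drop=True)
    return out


def normalization_factor(ct: pd.DataFrame, reference_genes: list[str]) -> pd.Series:
    """Per-sample normalization factor: the arithmetic mean of the
    reference genes' Cts (geometric mean of expression in linear space)."""
    ref = ct[ct["gene"].isin(reference_genes)]
    missing = set(reference_genes) - set(ref["gene"])
    if missing:
        raise ValueError(f"reference gene(s) absent from the Ct table: {sorted(missing)}")
    per_sample = ref.pivot_table(
        index="sample_id", columns="gene", values="ct", aggfunc="mean"
    )
    if per_sample.isna().any().any():
        raise ValueError("reference genes must be measured in every sample")
    return per_sample.mean(axis=1)


@dataclass
class DdctResult:
    gene: str
    condition: str
    control: str
    delta_ct: np.ndarray  # per-replicate normalized Ct in `condition`
    delta_ct_control: np.ndarray
    ddct: float
    ddct_sd: float
    ratio: float
    efficiency: float
    p_value: float
    n: int
    log2_ratio_replicates: np.ndarray


def compute_ddct(
    ct: pd.DataFrame,
    reference_genes: list[str],
    target_genes: list[str],
    control_condition: str,
    efficiency: float | None = 2.0,
) -> list[DdctResult]:
    """Delta-delta-Ct relative quantification against a control condition.

    dCt = Ct_target - NF per replicate; ddCt = mean dCt(condition) -
    mean dCt(control); ratio = E^(-ddCt). Efficiency defaults to perfect
    doubling (2) but a per-gene value from the Ct table is used when
    ``efficiency=None``. Significance by two-sided Student t across
    replicates. Missing replicates reduce n, which is recorded.
    """
    if control_condition not in set(ct["condition"]):
        raise ValueError(f"control condition {control_condition!r} not in table")
    nf = normalization_factor(ct, reference_genes)
    work = ct.assign(dct=ct["ct"] - ct["sample_id"].map(nf))
    results = []
    for gene in target_genes:
        sub = work[work["gene"] == gene]
        if len(sub) == 0:
            warnings.warn(f"target gene {gene!r} absent; skipped", stacklevel=2)
            continue
        eff = float(efficiency) if efficiency is not None else float(sub["efficiency"].mean())
        ctrl = sub.loc[sub["condition"] == control_condition, "dct"].to_numpy()
        if len(ctrl) == 0:
            warnings.warn(f"{gene!r}: no control replicates; skipped", stacklevel=2)
            continue
        for cond in sorted(set(sub["condition"]) - {control_condition}):
            cd = sub.loc[sub["condition"] == cond, "dct"].to_numpy()
            ddct = float(cd.mean() - ctrl.mean())
            # per-replicate ddCt spread in the test condition
            ddct_reps = cd - ctrl.mean()
            sd = float(ddct_reps.std(ddof=1)) if len(cd) > 1 else float("nan")
            if len(cd) > 1 and len(ctrl) > 1:
                p = float(stats.ttest_ind(cd, ctrl).pvalue)
            else:
                p = float("nan")
            results.append(
                DdctResult(
                    gene=gene,
                    condition=cond,
                    control=control_condition,
                    delta_ct=cd,
                    delta_ct_control=ctrl,
                    ddct=ddct,
                    ddct_sd=sd,
                    ratio=float(eff ** (-ddct)),
                    efficiency=eff,
                    p_value=p,
                    n=len(cd),
                    log2_ratio_replicates=-ddct_reps * np.log2(eff),
                )
            )
    return results


def standardize_log_ratios(results: list[DdctResult]) -> pd.DataFrame:
    """Standardized expression values: per gene, the replicate-level log2
    ratios across all conditions are mean-centered and autoscaled (unit
    SD). Returns one row per (gene, condition, replicate index)."""
    rows = []
    for r in results:
        for i, v in enumerate(r.log2_ratio_replicates):
            rows.append(
                {"gene": r.gene, "condition": r.condition, "replicate": i + 1,
                 "log2_ratio": float(v)}
            )
    df = pd.DataFrame(rows)
    if len(df) == 0:
        return df.assign(standardized=[])

    def z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    df["standardized"] = df.groupby("gene")["log2_ratio"].transform(z)
    return df


def ddct_to_frame(results: list[DdctResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "condition": [r.condition for r in results],
            "control": [r.control for r in results],
            "ddct": [r.ddct for r in results],
            "ddct_sd": [r.ddct_sd for r in results],
            "ratio": [r.ratio for r in results],
            "efficiency": [r.efficiency for r in results],
            "p_value": [r.p_value for r in results],
            "n": [r.n for r in results],
        }
    )
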