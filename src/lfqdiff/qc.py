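"""Peptide-level quality filters applied before per-protein modeling.

The ladder runs in a fixed order, each stage consuming the previous
stage's survivors:

1. retention-time stability — drop peptide-charges whose across-sample RT
   standard deviation exceeds 20 s;
2. shared peptides — drop peptides mapping to more than one protein;
3. reproducibility — keep a peptide-charge only if it is quantified in at
   least 2 replicates of every strain x medium x time combination;
4. intra-protein correlation — per protein, keep the reference peptide
   (the one with the most significant pairwise Pearson correlations) and
   the peptides correlated to it with r > 0.75.

Each stage returns a :class:`FilterReport` so the full audit trail
reconciles input and output row counts exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

KEY = ["peptide", "charge"]


@dataclass
class FilterReport:
    stage: str
    n_in: int
    n_removed: int
    removed_ids: list = field(default_factory=list)

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


def _drop_keys(table: pd.DataFrame, bad_keys: pd.DataFrame, stage: str) -> tuple[pd.DataFrame, FilterReport]:
    if len(bad_keys):
        merged = table.merge(bad_keys.assign(_bad=True), on=KEY, how="left")
        keep = merged["_bad"].isna().to_numpy()
    else:
        keep = np.ones(len(table), dtype=bool)
    out = table.loc[keep].reset_index(drop=True)
    removed = sorted(map(tuple, bad_keys[KEY].itertuples(index=False)))
    return out, FilterReport(stage, len(table), int((~keep).sum()), removed)


def filter_rt_stability(
    table: pd.DataFrame, max_sd_seconds: float = 20.0
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove peptide-charges whose across-sample RT standard deviation
    (sample SD, ddof=1) exceeds ``max_sd_seconds``. Peptide-charges seen
    in a single sample have SD 0 and are kept."""
    sd = table.groupby(KEY)["rt_seconds"].std(ddof=1).fillna(0.0)
    bad = sd[sd > max_sd_seconds].reset_index()[KEY]
    return _drop_keys(table, bad, "rt_stability")


def remove_shared_peptides(
    table: pd.DataFrame, delimiter: str = ";"
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove peptides mapping to two or more distinct protein accessions.

    Multi-protein mappings may be encoded within the ``protein`` field
    (delimiter-separated) or as the same peptide appearing under several
    accessions; both are handled.
    """
    n_inline = table["protein"].str.split(delimiter).map(
        lambda xs: len({x.strip() for x in xs if x.strip()})
    )
    per_pep = (
        table.assign(_n=n_inline)
        .groupby("peptide")
        .agg(n_acc=("protein", "nunique"), n_inline=("_n", "max"))
    )
    shared = per_pep[(per_pep["n_acc"] > 1) | (per_pep["n_inline"] > 1)].index
    bad = table.loc[table["peptide"].isin(shared), KEY].drop_duplicates()
    return _drop_keys(table, bad, "shared_peptides")


def filter_reproducibility(
    table: pd.DataFrame,
    design: pd.DataFrame,
    min_reps: int = 2,
    require_all_combinations: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep a peptide-charge only if it is quantified in at least
    ``min_reps`` replicates of every strain x medium x time combination of
    the design (all 12 of 12 in the full study layout). With
    ``require_all_combinations=False`` only the combinations where the
    peptide-charge appears at all must reach ``min_reps``."""
    combos = design[["strain", "medium", "time"]].drop_duplicates()
    n_combos = len(combos)
    merged = table.merge(
        design[["sample_id", "strain", "medium", "time", "replicate"]], on="sample_id"
    )
    reps = (
        merged.groupby(KEY + ["strain", "medium", "time"])["replicate"]
        .nunique()
        .reset_index(name="n_reps")
    )
    per_key = reps.groupby(KEY).agg(
        n_ok=("n_reps", lambda x: int((x >= min_reps).sum())),
        n_present=("n_reps", "size"),
    )
    if require_all_combinations:
        good = per_key[per_key["n_ok"] == n_combos].index
    else:
        good = per_key[per_key["n_ok"] == per_key["n_present"]].index
    all_keys = table[KEY].drop_duplicates()
    good_set = set(good)
    bad = all_keys[~all_keys.apply(tuple, axis=1).isin(good_set)]
    return _drop_keys(table, bad, "reproducibility")


def _pairwise_complete_corr(profiles: pd.DataFrame):
    """Pearson r and two-sided t-test p for every peptide pair of one
    protein, on pairwise-complete sample profiles. Pairs with fewer than
    3 complete observations are undefined (NaN) and logged."""
    keys = list(profiles.index)
    n = len(keys)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    values = profiles.to_numpy()
    for i in range(n):
        r[i, i] = 1.0
        for j in range(i + 1, n):
            mask = ~np.isnan(values[i]) & ~np.isnan(values[j])
            if mask.sum() < 3:
                logger.info(
                    "correlation undefined for pair %s / %s (<3 complete obs)",
                    keys[i], keys[j],
                )
                continue
            xi, xj = values[i, mask], values[j, mask]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            rr, pp = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    return keys, r, p


def correlation_filter(
    table: pd.DataFrame, alpha: float = 0.05, r_min: float = 0.75
) -> tuple[pd.DataFrame, FilterReport]:
    """Per protein, remove peptides whose intensity profile deviates from
    the protein consensus.

    The reference peptide is the one with the most significant pairwise
    correlations (two-sided test at ``alpha``); ties break to the highest
    mean pairwise r, then to the lexicographically smallest (peptide,
    charge). Survivors are the reference plus every peptide correlated to
    it with r > ``r_min``. Single-peptide proteins pass unchanged.
    """
    bad_rows = []
    for protein, sub in table.groupby("protein"):
        profiles = sub.pivot_table(
            index=KEY, columns="sample_id", values="log10_intensity", aggfunc="mean"
        )
        if len(profiles) < 2:
            continue
        keys, r, p = _pairwise_complete_corr(profiles)
        n_sig = np.nansum((p < alpha).astype(int) * ~np.eye(len(keys), dtype=bool), axis=1)
        with np.errstate(invalid="ignore"):
            mean_r = np.array([
                np.nanmean(np.delete(r[i], i)) if len(keys) > 1 else np.nan
                for i in range(len(keys))
            ])
        order = sorted(
            range(len(keys)),
            key=lambda i: (-n_sig[i], -(mean_r[i] if np.isfinite(mean_r[i]) else -np.inf), keys[i]),
        )
        ref = order[0]
        for i in range(len(keys)):
            if i == ref:
                continue
            if not (np.isfinite(r[i, ref]) and r[i, ref] > r_min):
                bad_rows.append(keys[i])
    bad = pd.DataFrame(bad_rows, columns=KEY) if bad_rows else pd.DataFrame(columns=KEY)
    return _drop_keys(table, bad, "correlation")


def apply_filter_ladder(
    table: pd.DataFrame,
    design: pd.DataFrame,
    max_rt_sd: float = 20.0,
    min_reps: int = 2,
    alpha: float = 0.05,
    r_min: float = 0.75,
) -> tuple[pd.DataFrame, list[FilterReport]]:
    """Run the full filter ladder in its declared order:
    RT stability -> shared peptides -> reproducibility -> correlation."""
    reports = []
    table, rep = filter_rt_stability(table, max_rt_sd)
    reports.append(rep)
    table, rep = remove_shared_peptides(table)
    reports.append(rep)
    table, rep = filter_reproducibility(table, design, min_reps=min_reps)
    reports.append(rep)
    table, rep = correlation_filter(table, alpha=alpha, r_min=r_min)
    reports.append(rep)
    return table, reports


def reports_to_frame(reports: list[FilterReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stage": [r.stage for r in reports],
            "n_in": [r.n_in for r in reports],
            "n_removed": [r.n_removed for r in reports],
            "n_out": [r.n_out for r in reports],
            "removed_peptide_charges": [
                ";".join(f"{p}/{c}" for p, c in r.removed_ids) for r in reports
            ],
        }
    )
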