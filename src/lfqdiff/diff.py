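"""Per-protein differential-abundance inference.

Two routes, sharing one full-factorial fixed-effect structure
(strain, medium, time, all their interactions, and a replicate blocking
factor, all in sum-to-zero coding):

* spectral counts — Poisson GLM with log link; per-term p-values from
  Type-II analysis of deviance (likelihood-ratio chi-square, dropping
  each term while respecting marginality);
* XIC log10 peptide intensities — linear mixed model with a fixed
  per-peptide ionization offset and a random intercept per sample
  (the technical effect theta shared by a protein's peptides within one
  run); variance components by REML, per-term p-values by Type-II
  F-tests in the between-sample stratum, which are exact classical
  ANOVA under the balanced factorial layout.

Raw p-values are Benjamini-Hochberg adjusted per term across proteins,
separately within each method; a protein is called significant when any
adjusted p < 0.05. When a protein is significant by both methods the XIC
fit is the one reported, XIC being the finer quantification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lmm import fit_random_intercept

__all__ = [
    "TERMS",
    "ProteinFitResult",
    "sc_prefilter",
    "fit_poisson_glm",
    "fit_xic_mixed_model",
    "fit_all_sc",
    "fit_all_xic",
    "adjust_bh",
    "adjust_fit_results",
    "merge_methods",
    "results_to_frame",
    "significant_proteins",
]

FACTORS = ("strain", "medium", "time")
#: tested model terms, ordered by interaction depth
TERMS: tuple[tuple[str, ...], ...] = (
    ("strain",),
    ("medium",),
    ("time",),
    ("strain", "medium"),
    ("strain", "time"),
    ("medium", "time"),
    ("strain", "medium", "time"),
)
#: terms involving the strain factor ("change between strains")
STRAIN_TERMS = tuple(t for t in TERMS if "strain" in t)


def term_name(term: tuple[str, ...]) -> str:
    return ":".join(term)


# -- sum-to-zero design coding ---------------------------------------------


def _sum_code(values: pd.Series, levels: list) -> np.ndarray:
    """n x (L-1) sum-to-zero ("effect") coding; the last level codes -1."""
    idx = values.map({v: i for i, v in enumerate(levels)}).to_numpy()
    L = len(levels)
    if L < 2:
        return np.empty((len(values), 0))
    C = np.zeros((len(values), L - 1))
    for j in range(L - 1):
        C[idx == j, j] = 1.0
    C[idx == L - 1, :] = -1.0
    return C


def _interaction(blocks: list[np.ndarray]) -> np.ndarray:
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(len(out), -1)
    return out


def build_design_matrix(
    data: pd.DataFrame,
    terms: tuple[tuple[str, ...], ...],
    levels: dict[str, list],
    extra_factors: tuple[str, ...] = (),
) -> np.ndarray:
    """Intercept + sum-coded blocks for each factorial term, then each
    extra blocking factor (replicate, peptide). Level sets are passed in
    so reduced models and prediction grids share one coding."""
    main = {f: _sum_code(data[f], levels[f]) for f in set(itertools.chain(*terms)) | set(extra_factors)}
    cols = [np.ones((len(data), 1))]
    for term in terms:
        cols.append(_interaction([main[f] for f in term]))
    for f in extra_factors:
        cols.append(main[f])
    return np.hstack(cols)


def _levels_of(data: pd.DataFrame, factors) -> dict[str, list]:
    return {f: sorted(data[f].unique()) for f in factors}


def _type2_model_sets(term: tuple[str, ...]):
    """Type-II comparison for ``term``: models (without, with), where
    'without' holds every factorial term not containing ``term``."""
    ts = set(term)
    base = tuple(t for t in TERMS if t != term and not ts.issubset(set(t)))
    return base, base + (term,)


# -- effect-size decomposition from cell means ------------------------------


def _cell_mean_decomposition(cell: np.ndarray) -> dict[tuple[str, ...], np.ndarray]:
    """Classical sum-to-zero ANOVA decomposition of a (strain, medium,
    time) cell-mean array into per-term effect arrays."""
    grand = cell.mean()
    S = cell.mean(axis=(1, 2)) - grand
    M = cell.mean(axis=(0, 2)) - grand
    T = cell.mean(axis=(0, 1)) - grand
    SM = cell.mean(axis=2) - grand - S[:, None] - M[None, :]
    ST = cell.mean(axis=1) - grand - S[:, None] - T[None, :]
    MT = cell.mean(axis=0) - grand - M[:, None] - T[None, :]
    SMT = (
        cell
        - grand
        - S[:, None, None]
        - M[None, :, None]
        - T[None, None, :]
        - SM[:, :, None]
        - ST[:, None, :]
        - MT[None, :, :]
    )
    return {
        ("strain",): S,
        ("medium",): M,
        ("time",): T,
        ("strain", "medium"): SM,
        ("strain", "time"): ST,
        ("medium", "time"): MT,
        ("strain", "medium", "time"): SMT,
    }


def _estimates_from_cells(cell: np.ndarray) -> dict[str, float]:
    """Per-term effect summaries on the model (linear-predictor) scale.

    Main effects are reported signed, first level minus last level (for
    two levels this is the log/log10 difference between them);
    interactions as the unsigned range of the effect array.
    """
    decomp = _cell_mean_decomposition(cell)
    out = {}
    for term, arr in decomp.items():
        if len(term) == 1:
            out[term_name(term)] = float(arr[0] - arr[-1]) if arr.size > 1 else 0.0
        else:
            out[term_name(term)] = float(arr.max() - arr.min())
    return out


def _prediction_cells(
    predict, levels: dict[str, list], extra_levels: dict[str, list]
) -> np.ndarray:
    """Average model predictions over replicate (and peptide) levels for
    every strain x medium x time combination; returns the cell-mean array.
    ``predict`` maps a factor DataFrame to linear-predictor values."""
    factors = list(FACTORS) + list(extra_levels)
    grid = pd.DataFrame(
        list(itertools.product(*(levels[f] for f in FACTORS),
                               *(extra_levels[f] for f in extra_levels))),
        columns=factors,
    )
    pred = predict(grid)
    grid = grid.assign(_pred=pred)
    cells = grid.groupby(list(FACTORS), sort=True)["_pred"].mean()
    shape = tuple(len(levels[f]) for f in FACTORS)
    return cells.to_numpy().reshape(shape)


# -- fit results ------------------------------------------------------------


@dataclass
class ProteinFitResult:
    protein: str
    method: str  # "SC" or "XIC"
    estimates: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    padj: dict[str, float] = field(default_factory=dict)
    sigma_theta2: float | None = None
    sigma_eps2: float | None = None
    loglik: float | None = None
    converged: bool = True
    note: str = ""

    def significant(self, alpha: float = 0.05, terms: tuple[str, ...] | None = None) -> bool:
        src = self.padj if self.padj else {}
        keys = terms if terms is not None else tuple(src)
        return any(
            (k in src and np.isfinite(src[k]) and src[k] < alpha) for k in keys
        )


def _null_result(protein: str, method: str, note: str) -> ProteinFitResult:
    return ProteinFitResult(
        protein=protein,
        method=method,
        estimates={term_name(t): 0.0 for t in TERMS},
        pvalues={term_name(t): 1.0 for t in TERMS},
        sigma_theta2=0.0 if method == "XIC" else None,
        sigma_eps2=0.0 if method == "XIC" else None,
        note=note,
    )


# -- spectral-count route ---------------------------------------------------


def sc_prefilter(
    counts: pd.DataFrame, design: pd.DataFrame, min_avg_diff: float = 10.0
) -> set[str]:
    """Proteins whose strain x medium x time combination means of spectral
    counts span a range of at least ``min_avg_diff`` (10 spectra by
    default) — the coarse pre-selection before GLM fitting."""
    merged = counts.merge(design[["sample_id", *FACTORS]], on="sample_id")
    means = merged.groupby(["protein", *FACTORS])["count"].mean()
    rng = means.groupby("protein").agg(lambda x: x.max() - x.min())
    return set(rng[rng >= min_avg_diff].index)


def fit_poisson_glm(
    counts: pd.DataFrame, design: pd.DataFrame, protein: str | None = None
) -> ProteinFitResult:
    """Poisson log-linear model for one protein's spectral counts with the
    full factorial + replicate fixed terms; Type-II analysis of deviance."""
    if protein is None:
        uniq = counts["protein"].unique()
        if len(uniq) != 1:
            raise ValueError("pass counts for a single protein (or name one)")
        protein = uniq[0]
        sub = counts
    else:
        sub = counts[counts["protein"] == protein]
    data = sub.merge(design[["sample_id", *FACTORS, "replicate"]], on="sample_id")
    levels = _levels_of(design, FACTORS + ("replicate",))
    present = data[list(FACTORS)].drop_duplicates()
    expected = design[list(FACTORS)].drop_duplicates()
    missing = expected.merge(present, how="left", indicator=True)
    missing = missing[missing["_merge"] == "left_only"].drop(columns="_merge")
    if len(missing):
        cells = [
            "x".join(str(v) for v in row)
            for row in missing.itertuples(index=False)
        ]
        raise ValueError(f"design cell(s) without counts: {', '.join(cells)}")

    y = data["count"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return _null_result(protein, "SC", "all counts equal")

    def glm_fit(terms):
        X = build_design_matrix(data, terms, levels, extra_factors=("replicate",))
        model = sm.GLM(y, X, family=sm.families.Poisson())
        return model.fit(maxiter=200, tol=1e-10)

    full = glm_fit(TERMS)
    result = ProteinFitResult(
        protein=protein, method="SC", loglik=float(full.llf),
        converged=bool(full.converged),
    )

    def predict_linear(grid: pd.DataFrame) -> np.ndarray:
        Xg = build_design_matrix(grid, TERMS, levels, extra_factors=("replicate",))
        return Xg @ full.params

    cell = _prediction_cells(predict_linear, levels, {"replicate": levels["replicate"]})
    result.estimates = _estimates_from_cells(cell)

    cache: dict[tuple, object] = {TERMS: full}
    for term in TERMS:
        base, with_term = _type2_model_sets(term)
        fits = []
        ok = True
        for ts in (base, with_term):
            if ts not in cache:
                cache[ts] = glm_fit(ts)
            fit = cache[ts]
            ok = ok and bool(fit.converged)
            fits.append(fit)
        if not ok:
            result.pvalues[term_name(term)] = float("nan")
            result.converged = False
            continue
        lr = 2.0 * (fits[1].llf - fits[0].llf)
        df = int(fits[1].df_model - fits[0].df_model)
        result.pvalues[term_name(term)] = float(stats.chi2.sf(max(lr, 0.0), df))
    return result


# -- XIC route --------------------------------------------------------------


def fit_xic_mixed_model(
    peptides: pd.DataFrame,
    design: pd.DataFrame,
    protein: str | None = None,
    include_peptide_effect: bool = True,
) -> ProteinFitResult:
    """Mixed model for one protein's log10 peptide-charge intensities.

    Fixed: full factorial + replicate (+ per-peptide offset when the
    protein has more than one peptide-charge and the toggle is on).
    Random: intercept per sample. Variance components by REML; per-term
    Type-II F-tests computed in the between-sample stratum, weighted by
    the REML variance components when peptide counts differ across
    samples. Proteins with a single peptide-charge fall back to
    fixed-effects-only least squares (theta and the residual are then
    confounded), with a note.
    """
    if protein is None:
        uniq = peptides["protein"].unique()
        if len(uniq) != 1:
            raise ValueError("pass peptides for a single protein (or name one)")
        protein = uniq[0]
        sub = peptides
    else:
        sub = peptides[peptides["protein"] == protein]
    data = sub.merge(design[["sample_id", *FACTORS, "replicate"]], on="sample_id")
    data = data.assign(
        peptide_charge=data["peptide"].astype(str) + "/" + data["charge"].astype(str)
    )
    n_pep = data["peptide_charge"].nunique()
    y = data["log10_intensity"].to_numpy(dtype=float)
    if np.ptp(y) < 1e-12:
        return _null_result(protein, "XIC", "all intensities identical")

    levels = _levels_of(design, FACTORS + ("replicate",))
    extra: tuple[str, ...] = ("replicate",)
    extra_levels = {"replicate": levels["replicate"]}
    use_pep = include_peptide_effect and n_pep > 1
    if use_pep:
        levels["peptide_charge"] = sorted(data["peptide_charge"].unique())
        extra = ("replicate", "peptide_charge")
        extra_levels["peptide_charge"] = levels["peptide_charge"]
    single_peptide = n_pep < 2
    groups = data["sample_id"].to_numpy()

    X_full = build_design_matrix(data, TERMS, levels, extra_factors=extra)
    if single_peptide:
        # one observation per sample: theta inseparable from eps
        beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        resid = y - X_full @ beta
        n = len(y)
        rank = int(np.linalg.matrix_rank(X_full))
        dof = max(n - rank, 1)
        s2 = float(resid @ resid) / dof
        from .lmm import LMMFit

        reml_fit = LMMFit(beta, s2, 0.0, float("nan"), True, True, rank, n)
    else:
        reml_fit = fit_random_intercept(y, X_full, groups, reml=True)
    result = ProteinFitResult(
        protein=protein,
        method="XIC",
        sigma_theta2=reml_fit.sigma_theta2,
        sigma_eps2=reml_fit.sigma_eps2,
        loglik=reml_fit.loglik,
        converged=reml_fit.converged,
        note="single peptide: fixed-effects least squares" if single_peptide else "",
    )

    def predict(grid: pd.DataFrame) -> np.ndarray:
        Xg = build_design_matrix(grid, TERMS, levels, extra_factors=extra)
        return Xg @ reml_fit.beta

    cell = _prediction_cells(predict, levels, extra_levels)
    result.estimates = _estimates_from_cells(cell)

    # Per-term tests live in the between-sample stratum: every factorial
    # term and the replicate block are constant within a sample, and the
    # marginal model for the per-sample means is
    #     ybar_s ~ N(fixed_s, sigma_theta^2 + sigma_eps^2 / p_s).
    # Type-II F-tests on these means (weighted by the REML variance
    # components when peptide counts p_s differ) are exact classical
    # ANOVA in the balanced case, for any value of the variance ratio.
    if use_pep:
        # remove estimated peptide offsets so unbalanced sample means are
        # comparable; a constant shift in the balanced case
        pep_cols = X_full.shape[1] - (len(levels["peptide_charge"]) - 1)
        y_adj = y - X_full[:, pep_cols:] @ reml_fit.beta[pep_cols:]
    else:
        y_adj = y
    agg = (
        pd.DataFrame({"sample_id": data["sample_id"], "y": y_adj})
        .groupby("sample_id")
        .agg(ybar=("y", "mean"), n=("y", "size"))
        .reset_index()
    )
    sample_data = agg.merge(
        design[["sample_id", *FACTORS, "replicate"]], on="sample_id"
    )
    ybar = sample_data["ybar"].to_numpy()
    w = 1.0 / (
        reml_fit.sigma_theta2 + reml_fit.sigma_eps2 / sample_data["n"].to_numpy()
    )
    if not np.all(np.isfinite(w)):
        w = np.ones_like(ybar)
    sw = np.sqrt(w)

    def wrss(terms) -> tuple[float, int]:
        Xs = build_design_matrix(sample_data, terms, levels, extra_factors=("replicate",))
        Xw = Xs * sw[:, None]
        yw = ybar * sw
        beta, _res, rank, _sv = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        return float(r @ r), int(rank)

    rss_full, rank_full = wrss(TERMS)
    ddf = max(len(sample_data) - rank_full, 1)
    for term in TERMS:
        base, with_term = _type2_model_sets(term)
        rss_base, rank_base = wrss(base)
        rss_with, rank_with = wrss(with_term)
        q = max(rank_with - rank_base, 1)
        f_stat = max(rss_base - rss_with, 0.0) / q / (rss_full / ddf)
        result.pvalues[term_name(term)] = float(stats.f.sf(f_stat, q, ddf))
    return result


def fit_all_sc(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    min_avg_diff: float = 10.0,
    prefilter: bool = True,
) -> list[ProteinFitResult]:
    keep = sc_prefilter(counts, design, min_avg_diff) if prefilter else set(counts["protein"])
    fits = [
        fit_poisson_glm(counts, design, protein=p) for p in sorted(keep)
    ]
    adjust_fit_results(fits)
    return fits


def fit_all_xic(
    peptides: pd.DataFrame,
    design: pd.DataFrame,
    include_peptide_effect: bool = True,
) -> list[ProteinFitResult]:
    fits = [
        fit_xic_mixed_model(peptides, design, protein=p,
                            include_peptide_effect=include_peptide_effect)
        for p in sorted(peptides["protein"].unique())
    ]
    adjust_fit_results(fits)
    return fits


# -- multiplicity correction and merging ------------------------------------


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing values are excluded and reinserted as missing; values outside
    [0, 1] raise.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if ((pm < 0) | (pm > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pm)
    if m == 0:
        return out
    order = np.argsort(pm, kind="stable")
    ranked = pm[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def adjust_fit_results(fits: list[ProteinFitResult]) -> None:
    """BH-adjust raw p-values per term across proteins, in place,
    separately within each method family."""
    for method in sorted({f.method for f in fits}):
        group = [f for f in fits if f.method == method]
        for term in TERMS:
            name = term_name(term)
            raw = [f.pvalues.get(name, np.nan) for f in group]
            adj = adjust_bh(raw)
            for f, a in zip(group, adj):
                f.padj[name] = float(a) if np.isfinite(a) else float("nan")


def significant_proteins(
    fits: list[ProteinFitResult],
    alpha: float = 0.05,
    terms: tuple[str, ...] | None = None,
) -> set[str]:
    return {f.protein for f in fits if f.significant(alpha, terms)}


def merge_methods(
    sc_fits: list[ProteinFitResult],
    xic_fits: list[ProteinFitResult],
    alpha: float = 0.05,
) -> tuple[list[ProteinFitResult], dict[str, int]]:
    """Combine the two routes over the significant proteins.

    Returns the merged per-protein results (XIC fits reported wherever a
    protein is significant by both methods, XIC being the finer approach)
    and the partition counts: both / SC-only / XIC-only / union plus the
    per-method totals.
    """
    for fits, label in ((sc_fits, "SC"), (xic_fits, "XIC")):
        names = [f.protein for f in fits]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate protein within the {label} fits")
    sc_sig = significant_proteins(sc_fits, alpha)
    xic_sig = significant_proteins(xic_fits, alpha)
    both = sc_sig & xic_sig
    sc_only = sc_sig - xic_sig
    xic_only = xic_sig - sc_sig
    union = sc_sig | xic_sig
    sc_by = {f.protein: f for f in sc_fits}
    xic_by = {f.protein: f for f in xic_fits}
    merged = []
    for protein in sorted(union):
        merged.append(xic_by[protein] if protein in xic_sig else sc_by[protein])
    partition = {
        "both": len(both),
        "sc_only": len(sc_only),
        "xic_only": len(xic_only),
        "union": len(union),
        "sc_total": len(sc_sig),
        "xic_total": len(xic_sig),
    }
    return merged, partition


def results_to_frame(fits: list[ProteinFitResult]) -> pd.DataFrame:
    """One row per (protein, term): estimate, raw and adjusted p, method."""
    rows = []
    for f in fits:
        for term in TERMS:
            name = term_name(term)
            rows.append(
                {
                    "protein": f.protein,
                    "term": name,
                    "method": f.method,
                    "estimate": f.estimates.get(name, np.nan),
                    "p_raw": f.pvalues.get(name, np.nan),
                    "p_adj": f.padj.get(name, np.nan) if f.padj else np.nan,
                }
            )
    return pd.DataFrame(rows)
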