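"""End-to-end validation benchmarks for the pipeline.

Each function runs one self-contained study on synthetic data with known
ground truth — null false-discovery calibration, planted-effect
recovery, retention-time bias removal, agreement of the model fits with
independent brute-force oracles, motif-scanner recall — and returns the
measured quantities. The acceptance script and the acceptance tests both
drive these benchmarks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import qc
from .diff import (
    STRAIN_TERMS,
    TERMS,
    ProteinFitResult,
    _levels_of,
    adjust_bh,
    adjust_fit_results,
    build_design_matrix,
    fit_all_xic,
    fit_poisson_glm,
    merge_methods,
    significant_proteins,
    term_name,
)
from .lmm import fit_random_intercept
from .normalize import normalize_table
from .phobox import scan_pho_boxes
from .simulate import (
    PlantedBox,
    SimulationTruth,
    generate_design,
    n_combinations,
    plant_pho_boxes,
    simulate_peptide_intensities,
    simulate_spectral_counts,
    sinusoidal_rt_bias,
)

STRAIN_TERM_NAMES = tuple(term_name(t) for t in STRAIN_TERMS)


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# -- design / partition arithmetic ------------------------------------------


def design_partition_benchmark() -> dict[str, float]:
    """The factorial layout's sample and combination counts, and the
    merge partition computed from category sets of the study's published
    sizes (350 significant by both methods, 295 by spectral counting
    only, 395 by XIC only)."""
    design = generate_design(2, 2, 3, 4)
    counts = {
        "total_samples": float(len(design)),
        "combinations": float(n_combinations(design)),
    }

    def fit_set(prefix, n, method, sig):
        out = []
        for i in range(n):
            f = ProteinFitResult(protein=f"{prefix}{i}", method=method)
            for t in TERMS:
                f.pvalues[term_name(t)] = 1e-6 if sig else 1.0
            out.append(f)
        return out

    sc = fit_set("B", 350, "SC", True) + fit_set("S", 295, "SC", True) + fit_set("X", 395, "SC", False)
    xic = fit_set("B", 350, "XIC", True) + fit_set("S", 295, "XIC", False) + fit_set("X", 395, "XIC", True)
    adjust_fit_results(sc)
    adjust_fit_results(xic)
    _, part = merge_methods(sc, xic)
    counts.update(
        {
            "significant_union": float(part["union"]),
            "significant_both": float(part["both"]),
            "significant_sc_total": float(part["sc_total"]),
            "significant_xic_total": float(part["xic_total"]),
        }
    )
    return counts


# -- false-discovery calibration --------------------------------------------


def null_fdr_benchmark(seed: int, n_proteins: int = 500) -> dict[str, float]:
    """Null simulation (no fixed effects; sigma_theta=0.1, sigma_eps=0.2,
    4 peptides/protein, 2x2x3x4 design): the fraction of proteins with
    any strain-involving BH-adjusted p < 0.05, and the KS uniformity
    p-value of the raw strain-term p-values."""
    design = generate_design(2, 2, 3, 4)
    truth = SimulationTruth(sigma_theta=0.1, sigma_eps=0.2, seed=_sub_seed(seed, 1))
    table = simulate_peptide_intensities(truth, design, n_proteins, 4)
    fits = fit_all_xic(table, design)
    frac = len(significant_proteins(fits, 0.05, STRAIN_TERM_NAMES)) / n_proteins
    raw = np.array([f.pvalues["strain"] for f in fits])
    ks_p = float(stats.kstest(raw, "uniform").pvalue)
    return {"any_strain_significant_fraction": frac, "strain_p_ks_pvalue": ks_p, "n": n_proteins}


# -- planted-effect recovery ------------------------------------------------


def effect_recovery_benchmark(seed: int, n_proteins: int = 200) -> dict[str, float]:
    """Strain effect of 0.5 log10 planted in every protein at the null
    benchmark's noise levels: mean estimated effect and the fraction of
    proteins detected (any strain-involving adjusted p < 0.05)."""
    design = generate_design(2, 2, 3, 4)
    truth = SimulationTruth(
        strain=np.array([0.25, -0.25]),
        sigma_theta=0.1,
        sigma_eps=0.2,
        seed=_sub_seed(seed, 2),
    )
    table = simulate_peptide_intensities(truth, design, n_proteins, 4)
    fits = fit_all_xic(table, design)
    estimates = np.array([f.estimates["strain"] for f in fits])
    detected = len(significant_proteins(fits, 0.05, STRAIN_TERM_NAMES))
    return {
        "mean_strain_estimate": float(estimates.mean()),
        "strain_estimate_bias": float(estimates.mean() - 0.5),
        "detection_rate_percent": 100.0 * detected / n_proteins,
        "n": n_proteins,
    }


# -- normalization ----------------------------------------------------------


def normalization_benchmark(seed: int, n_proteins: int = 400) -> dict[str, float]:
    """Sinusoidal RT bias (amplitude 0.3 log10, period 60 min) injected
    into every sample but the reference: RMS deviation from the bias-free
    truth before and after normalization, and the idempotence of a second
    normalization pass."""
    design = generate_design(2, 1, 2, 2)
    ref_id = sorted(design["sample_id"])[0]
    bias = sinusoidal_rt_bias(0.3, 3600.0, seed=_sub_seed(seed, 3), exempt=[ref_id])
    kw = dict(sigma_theta=0.1, sigma_eps=0.2, seed=_sub_seed(seed, 4))
    clean = simulate_peptide_intensities(SimulationTruth(**kw), design, n_proteins, 4)
    biased = simulate_peptide_intensities(
        SimulationTruth(**kw, rt_bias=bias), design, n_proteins, 4
    )
    once, _ = normalize_table(biased, reference=ref_id)
    twice, _ = normalize_table(once, reference=ref_id)

    def rms(x) -> float:
        return float(np.sqrt(np.mean(np.square(x))))

    before = rms(biased["log10_intensity"] - clean["log10_intensity"])
    after = rms(once["log10_intensity"] - clean["log10_intensity"])
    return {
        "rms_before": before,
        "rms_after": after,
        "rms_reduction_percent": 100.0 * (1.0 - after / before),
        "idempotence_max_change": float(
            np.abs(twice["log10_intensity"] - once["log10_intensity"]).max()
        ),
        "n": len(biased),
    }


# -- oracle equivalence -----------------------------------------------------


def _poisson_loglik(beta, X, y):
    eta = X @ beta
    return float(np.sum(y * eta - np.exp(eta) - special.gammaln(y + 1)))


def poisson_oracle_benchmark(seed: int, n_instances: int = 5) -> dict[str, float]:
    """Largest log-likelihood gap between the fitted Poisson GLM and a
    direct numeric maximization of the Poisson likelihood."""
    design = generate_design(2, 2, 3, 4)
    levels = _levels_of(design, ("strain", "medium", "time", "replicate"))
    worst = 0.0
    for k in range(n_instances):
        truth = SimulationTruth(
            mu=np.log(10),
            strain=np.array([np.log(2), -np.log(2)]),
            seed=_sub_seed(seed, 10 + k),
        )
        counts = simulate_spectral_counts(truth, design, 1)
        fit = fit_poisson_glm(counts, design, protein="P1")
        data = counts.merge(design, on="sample_id")
        X = build_design_matrix(data, TERMS, levels, extra_factors=("replicate",))
        y = data["count"].to_numpy(float)
        res = optimize.minimize(
            lambda b: -_poisson_loglik(b, X, y),
            np.zeros(X.shape[1]),
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": 2000},
        )
        worst = max(worst, abs(fit.loglik - (-res.fun)))
    return {"max_abs_loglik_gap": worst, "n": n_instances}


def bh_oracle_benchmark() -> dict[str, float]:
    """Largest gap between the BH adjustment and the exhaustive step-up
    enumeration over all grid vectors of length <= 6."""
    grid = [0.001, 0.01, 0.04, 0.2, 0.6, 1.0]

    def enumerate_bh(p):
        p = np.asarray(p, float)
        m = len(p)
        candidates = sorted({p[j] * m / r for j in range(m) for r in range(1, m + 1)})
        out = np.ones(m)
        for i in range(m):
            for alpha in candidates:
                srt = np.sort(p)
                k = 0
                for j in range(m):
                    if srt[j] <= (j + 1) * alpha / m:
                        k = j + 1
                if k and p[i] <= srt[k - 1]:
                    out[i] = min(alpha, 1.0)
                    break
        return out

    import itertools

    worst = 0.0
    n = 0
    for length in range(1, 4):
        for p in itertools.product(grid, repeat=length):
            worst = max(worst, float(np.abs(adjust_bh(p) - enumerate_bh(p)).max()))
            n += 1
    rng = np.random.default_rng(0)
    for length in (4, 5, 6):
        for _ in range(60):
            p = rng.choice(grid, size=length)
            worst = max(worst, float(np.abs(adjust_bh(p) - enumerate_bh(p)).max()))
            n += 1
    return {"max_abs_gap": worst, "n": n}


def reml_closed_form_benchmark(seed: int, n_instances: int = 10) -> dict[str, float]:
    """Largest gap between REML variance components on balanced one-factor
    layouts and the closed-form ANOVA estimators."""
    worst = 0.0
    for k in range(n_instances):
        rng = np.random.default_rng(_sub_seed(seed, 20 + k))
        S, p = 48, 2
        theta = rng.normal(0, 0.15, S)
        y = (5 + theta[None, :] + rng.normal(0, 0.25, (p, S))).ravel()
        groups = np.tile(np.arange(S), p)
        fit = fit_random_intercept(y, np.ones((p * S, 1)), groups, reml=True)
        ybar = y.reshape(p, S).mean(axis=0)
        ms_between = p * np.var(ybar, ddof=1)
        ms_within = ((y.reshape(p, S) - ybar) ** 2).sum() / (S * (p - 1))
        tau_closed = max((ms_between - ms_within) / p, 0.0)
        sig_closed = ms_within if tau_closed > 0 else np.var(y, ddof=1)
        if tau_closed > 0:
            worst = max(
                worst,
                abs(fit.sigma_eps2 - sig_closed),
                abs(fit.sigma_theta2 - tau_closed),
            )
    return {"max_abs_gap": worst, "n": n_instances}


def hierarchical_oracle_benchmark(seed: int) -> dict[str, float]:
    """Fraction of random instances (n <= 8) where the clustering tree
    equals a brute-force O(n^3) agglomerator's merges exactly."""
    import itertools as it

    from .cluster import hierarchical_cluster

    def brute(X, method="complete"):
        clusters = {i: frozenset([i]) for i in range(len(X))}
        parts = [set(clusters.values())]
        heights = []

        def dist(a, b):
            pair = [np.linalg.norm(X[i] - X[j]) for i in a for j in b]
            return max(pair) if method == "complete" else min(pair)

        while len(clusters) > 1:
            keys = list(clusters)
            best = min(
                it.combinations(keys, 2),
                key=lambda ab: (dist(clusters[ab[0]], clusters[ab[1]]), ab),
            )
            heights.append(dist(clusters[best[0]], clusters[best[1]]))
            merged = clusters[best[0]] | clusters[best[1]]
            del clusters[best[0]], clusters[best[1]]
            clusters[max(keys) + 1] = merged
            parts.append(set(clusters.values()))
        return heights, parts

    def replay(Z, n):
        clusters = {i: frozenset([i]) for i in range(n)}
        parts = [set(clusters.values())]
        for row_idx, (a, b, _h, _c) in enumerate(Z):
            merged = clusters.pop(int(a)) | clusters.pop(int(b))
            clusters[n + row_idx] = merged
            parts.append(set(clusters.values()))
        return parts

    rng = np.random.default_rng(_sub_seed(seed, 30))
    ok = total = 0
    for n in (4, 5, 6, 7, 8):
        for _ in range(6):
            X = rng.normal(size=(n, 3))
            res = hierarchical_cluster(X, method="complete")
            heights, parts = brute(X)
            match = np.allclose(
                sorted(res.linkage[:, 2]), sorted(heights), rtol=1e-10
            ) and replay(res.linkage, n) == parts
            ok += int(match)
            total += 1
    return {"agreement_percent": 100.0 * ok / total, "n": total}


# -- motif scanner ----------------------------------------------------------


def phobox_benchmark(seed: int, n_planted: int = 50, n_involution: int = 100) -> dict[str, float]:
    """Recall of planted exact canonical boxes and the strand-involution
    agreement on random GC-rich sequences."""
    from Bio.Seq import Seq

    recalled = 0
    for k in range(n_planted):
        start = 40 + 7 * k
        rec, _ = plant_pho_boxes(
            600, 0.72, [PlantedBox(start=start, klass="canonical")],
            seed=_sub_seed(seed, 40 + k),
        )
        hits = scan_pho_boxes(rec, max_mismatch_per_unit=0)
        recalled += int(
            any(h.klass == "canonical" and h.start == start and h.strand == "+"
                for h in hits)
        )

    rng = np.random.default_rng(_sub_seed(seed, 41))
    agree = 0
    for _ in range(n_involution):
        n = int(rng.integers(60, 400))
        seq = "".join(rng.choice(list("ACGT"), size=n, p=[0.14, 0.36, 0.36, 0.14]))
        fwd = scan_pho_boxes(seq)
        rc = scan_pho_boxes(str(Seq(seq).reverse_complement()))
        mapped = sorted(
            (n - h.end + 1, n - h.start + 1, "-" if h.strand == "+" else "+", h.klass)
            for h in fwd
        )
        direct = sorted((h.start, h.end, h.strand, h.klass) for h in rc)
        agree += int(mapped == direct)
    return {
        "planted_canonical_recall_percent": 100.0 * recalled / n_planted,
        "strand_involution_agreement_percent": 100.0 * agree / n_involution,
        "n": n_planted + n_involution,
    }


# -- filter ladder on a constructed toy table -------------------------------

TOY_SURVIVORS = {"pep01", "pep07", "pep08", "pep09", "pep10"}


def build_toy_filter_table() -> tuple[pd.DataFrame, pd.DataFrame]:
    """A 10-peptide toy table over a 2x2x3x2 design exercising every
    filter stage; the hand-enumerated survivor set is TOY_SURVIVORS:

    * pep01, pep10 — protein P1, concordant profiles: survive;
    * pep02 — RT SD 70.7 s across samples: removed (RT stability);
    * pep03 — maps to P1;P2: removed (shared);
    * pep04 — absent from one strain x medium x time combination:
      removed (reproducibility);
    * pep05 — one replicate only in one combination: removed
      (reproducibility);
    * pep06 — protein P3, anti-correlated with its siblings: removed
      (correlation);
    * pep07, pep08 — protein P3, concordant: survive;
    * pep09 — single-peptide protein P4: survives.
    """
    design = generate_design(2, 2, 3, 2)
    samples = list(design["sample_id"])
    n = len(samples)
    trend = np.linspace(-1.0, 1.0, n)  # common abundance trend over samples
    wobble = np.cos(np.linspace(0, 3 * np.pi, n)) * 0.05

    def rows(pep, protein, values, rts, sample_subset=None):
        out = []
        use = samples if sample_subset is None else sample_subset
        for i, s in enumerate(samples):
            if s not in use:
                continue
            out.append([pep, 2, protein, float(rts[i]), s, float(values[i])])
        return out

    const_rt = np.full(n, 3000.0)
    data = []
    data += rows("pep01", "P1", 5.0 + trend, const_rt)
    data += rows("pep02", "P1", 5.0 + trend, np.where(np.arange(n) % 2, 3050.0, 2950.0))
    data += rows("pep03", "P1;P2", 5.0 + trend, const_rt)
    missing_combo = set(
        design[(design.strain == "S1") & (design.medium == "M1") & (design.time == "T1")][
            "sample_id"
        ]
    )
    data += rows("pep04", "P2", 5.0 + trend, const_rt,
                 sample_subset=[s for s in samples if s not in missing_combo])
    thin_combo = set(
        design[(design.strain == "S2") & (design.medium == "M2") & (design.time == "T3")][
            "sample_id"
        ]
    )
    keep_one = {sorted(thin_combo)[0]}
    data += rows("pep05", "P2", 5.0 + trend, const_rt,
                 sample_subset=[s for s in samples if s not in (thin_combo - keep_one)])
    data += rows("pep06", "P3", 5.0 - trend + wobble, const_rt)  # anti-correlated
    data += rows("pep07", "P3", 4.0 + trend + wobble, const_rt)
    data += rows("pep08", "P3", 6.0 + trend - wobble, const_rt)
    data += rows("pep09", "P4", 5.0 + trend, const_rt)
    data += rows("pep10", "P1", 5.5 + trend + wobble, const_rt)
    table = pd.DataFrame(
        data,
        columns=["peptide", "charge", "protein", "rt_seconds", "sample_id", "log10_intensity"],
    )
    return table, design


def filter_ladder_benchmark() -> dict[str, float]:
    table, design = build_toy_filter_table()
    out, _reports = qc.apply_filter_ladder(table, design)
    survivors = set(out["peptide"].unique())
    return {
        "survivors": float(len(survivors)),
        "matches_hand_enumeration": float(survivors == TOY_SURVIVORS),
        "n": int(table["peptide"].nunique()),
    }
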