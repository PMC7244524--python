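"""Synthetic data generators for the label-free proteomics pipeline.

Every stage of the analysis (normalization, peptide QC, per-protein
modeling, clustering, motif scanning) is exercised on data produced here,
with known ground truth. The generators emulate the statistical structure
the downstream models assume:

* log10 peptide ion-current (XIC) intensities built from a factorial
  design (strain x medium x time x replicate) with peptide-specific
  ionization offsets, a per-(protein, sample) technical random effect
  theta, a smooth retention-time-dependent bias per sample, residual
  noise, and missing observations;
* per-protein spectral counts drawn from a Poisson law whose log rate
  carries the same factorial fixed effects;
* promoter sequences with PhoP binding sites (Pho boxes) planted at known
  coordinates on either strand.

All generators are bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FACTORIAL_TERMS",
    "SimulationTruth",
    "PlantedBox",
    "PlantedMotifTruth",
    "generate_design",
    "simulate_peptide_intensities",
    "simulate_spectral_counts",
    "plant_pho_boxes",
    "sinusoidal_rt_bias",
]

#: Factorial fixed-effect terms shared by the intensity and count models,
#: ordered by interaction depth.
FACTORIAL_TERMS = (
    "strain",
    "medium",
    "time",
    "strain:medium",
    "strain:time",
    "medium:time",
    "strain:medium:time",
)

PHO_BOX_UNIT = "GTTCACCC"  # consensus direct-repeat unit; CA at offsets 4-5
PHO_BOX_PERIOD = 9  # CA-start to CA-start spacing of the two units


def _levels(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_design(
    n_strains: int,
    n_media: int,
    n_times: int,
    n_replicates: int,
    *,
    strains: Sequence[str] | None = None,
    media: Sequence[str] | None = None,
    times: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full factorial design table (strain x medium x time x replicate).

    Returns a DataFrame with columns ``strain, medium, time, replicate,
    sample_id``; one row per sample, ``n_strains * n_media * n_times *
    n_replicates`` rows in total.
    """
    for name, v in (
        ("n_strains", n_strains),
        ("n_media", n_media),
        ("n_times", n_times),
        ("n_replicates", n_replicates),
    ):
        if not isinstance(v, (int, np.integer)) or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    strains = list(strains) if strains is not None else _levels("S", n_strains)
    media = list(media) if media is not None else _levels("M", n_media)
    times = list(times) if times is not None else _levels("T", n_times)
    if len(strains) != n_strains or len(media) != n_media or len(times) != n_times:
        raise ValueError("custom level names must match the requested counts")
    reps = _levels("R", n_replicates)
    rows = [
        {
            "strain": s,
            "medium": m,
            "time": t,
            "replicate": r,
            "sample_id": f"{s}_{m}_{t}_{r}",
        }
        for s, m, t, r in itertools.product(strains, media, times, reps)
    ]
    return pd.DataFrame(rows)


def n_combinations(design: pd.DataFrame) -> int:
    """Number of distinct strain x medium x time combinations in a design."""
    return len(design[["strain", "medium", "time"]].drop_duplicates())


def _zeros(*shape: int) -> np.ndarray:
    return np.zeros(shape)


@dataclass
class SimulationTruth:
    """Ground-truth parameters of the factorial intensity/count models.

    Fixed effects use sum-to-zero coding: each effect array sums to zero
    over every one of its axes, so ``mu`` is the grand mean and effects
    are directly identifiable for recovery tests. Arrays left as ``None``
    default to zeros sized from the design at simulation time.

    Units: ``mu`` and the effects are log10 intensities for the XIC
    generator and natural-log rates for the spectral-count generator.
    ``sigma_theta`` is the SD of the per-(protein, sample) technical
    effect; ``sigma_eps`` the residual SD; ``peptide_offset_sd`` the SD
    of per-peptide ionization offsets; retention times are in seconds.
    """

    mu: float = 5.0
    strain: np.ndarray | None = None
    medium: np.ndarray | None = None
    time: np.ndarray | None = None
    strain_medium: np.ndarray | None = None
    strain_time: np.ndarray | None = None
    medium_time: np.ndarray | None = None
    strain_medium_time: np.ndarray | None = None
    replicate: np.ndarray | None = None
    sigma_theta: float = 0.1
    sigma_eps: float = 0.2
    peptide_offset_sd: float = 0.3
    peptide_offsets: np.ndarray | None = None
    rt_bias: Callable[[str, np.ndarray], np.ndarray] | None = None
    rt_window: tuple[float, float] = (0.0, 10800.0)  # 180-min gradient
    rt_jitter_sd: float = 3.0  # seconds, per-sample
    missing_rate: float = 0.0
    mnar: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_theta < 0:
            raise ValueError("sigma_theta must be >= 0")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for name in (
            "strain",
            "medium",
            "time",
            "strain_medium",
            "strain_time",
            "medium_time",
            "strain_medium_time",
            "replicate",
        ):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            setattr(self, name, arr)
            for axis in range(arr.ndim):
                sums = arr.sum(axis=axis)
                if not np.allclose(sums, 0.0, atol=1e-8):
                    raise ValueError(
                        f"effect '{name}' must sum to zero over every axis "
                        f"(sum-to-zero coding); axis {axis} sums to {sums!r}"
                    )

    # -- deterministic part -------------------------------------------------

    def fixed_effects(self, design: pd.DataFrame) -> np.ndarray:
        """Per-sample deterministic effect sum mu + S + M + T + interactions + R."""
        s_levels = sorted(design["strain"].unique())
        m_levels = sorted(design["medium"].unique())
        t_levels = sorted(design["time"].unique())
        r_levels = sorted(design["replicate"].unique())
        S = self.strain if self.strain is not None else _zeros(len(s_levels))
        M = self.medium if self.medium is not None else _zeros(len(m_levels))
        T = self.time if self.time is not None else _zeros(len(t_levels))
        SM = (
            self.strain_medium
            if self.strain_medium is not None
            else _zeros(len(s_levels), len(m_levels))
        )
        ST = (
            self.strain_time
            if self.strain_time is not None
            else _zeros(len(s_levels), len(t_levels))
        )
        MT = (
            self.medium_time
            if self.medium_time is not None
            else _zeros(len(m_levels), len(t_levels))
        )
        SMT = (
            self.strain_medium_time
            if self.strain_medium_time is not None
            else _zeros(len(s_levels), len(m_levels), len(t_levels))
        )
        R = self.replicate if self.replicate is not None else _zeros(len(r_levels))
        j = design["strain"].map({v: i for i, v in enumerate(s_levels)}).to_numpy()
        k = design["medium"].map({v: i for i, v in enumerate(m_levels)}).to_numpy()
        l = design["time"].map({v: i for i, v in enumerate(t_levels)}).to_numpy()
        m = design["replicate"].map({v: i for i, v in enumerate(r_levels)}).to_numpy()
        return (
            self.mu
            + S[j]
            + M[k]
            + T[l]
            + SM[j, k]
            + ST[j, l]
            + MT[k, l]
            + SMT[j, k, l]
            + R[m]
        )


def sinusoidal_rt_bias(
    amplitude: float,
    period_seconds: float = 3600.0,
    *,
    per_sample_phase: bool = True,
    seed: int = 0,
    exempt: Sequence[str] = (),
) -> Callable[[str, np.ndarray], np.ndarray]:
    """Smooth per-sample RT-dependent intensity bias, ``a*sin(2*pi*rt/p + phi)``.

    ``exempt`` samples get zero bias — useful to keep the normalization
    reference bias-free, since relative normalization can only align
    samples to the reference.
    """
    rng = np.random.default_rng(seed)
    phases: dict[str, float] = {}
    exempt_set = set(exempt)

    def bias(sample_id: str, rt: np.ndarray) -> np.ndarray:
        rt = np.asarray(rt, dtype=float)
        if sample_id in exempt_set:
            return np.zeros_like(rt)
        if sample_id not in phases:
            phases[sample_id] = (
                float(rng.uniform(0, 2 * np.pi)) if per_sample_phase else 0.0
            )
        return amplitude * np.sin(2 * np.pi * rt / period_seconds + phases[sample_id])

    return bias


def simulate_peptide_intensities(
    truth: SimulationTruth,
    design: pd.DataFrame,
    n_proteins: int,
    peptides_per_protein: int,
) -> pd.DataFrame:
    """Simulate a long-format log10 peptide-charge intensity table.

    Each observed intensity is the deterministic effect sum for its sample
    plus a per-peptide ionization offset, one technical draw theta per
    (protein, sample), the sample's smooth RT bias evaluated at the
    peptide's retention time, and residual noise per (peptide, sample).
    Retention times are assigned once per peptide-charge, with small
    Gaussian per-sample jitter. Rows are dropped at ``missing_rate``
    (completely at random, or intensity-dependent when ``truth.mnar``).

    Returns columns ``peptide, charge, protein, rt_seconds, sample_id,
    log10_intensity``.
    """
    if n_proteins < 1 or peptides_per_protein < 1:
        raise ValueError("n_proteins and peptides_per_protein must be >= 1")
    rng = np.random.default_rng(truth.seed)
    n_samples = len(design)
    n_pep = n_proteins * peptides_per_protein

    fixed = truth.fixed_effects(design)  # (n_samples,)
    sample_ids = design["sample_id"].to_numpy()

    if truth.peptide_offsets is not None:
        offsets = np.asarray(truth.peptide_offsets, dtype=float)
        if offsets.shape != (n_pep,):
            raise ValueError(
                f"peptide_offsets must have length {n_pep}, got {offsets.shape}"
            )
    else:
        offsets = (
            rng.normal(0.0, truth.peptide_offset_sd, size=n_pep)
            if truth.peptide_offset_sd > 0
            else np.zeros(n_pep)
        )

    lo, hi = truth.rt_window
    rt_base = rng.uniform(lo, hi, size=n_pep)
    theta = (
        rng.normal(0.0, truth.sigma_theta, size=(n_proteins, n_samples))
        if truth.sigma_theta > 0
        else np.zeros((n_proteins, n_samples))
    )

    pw = len(str(n_proteins))
    qw = len(str(peptides_per_protein))
    prot_of_pep = np.repeat(np.arange(n_proteins), peptides_per_protein)
    proteins = np.array([f"P{i + 1:0{pw}d}" for i in range(n_proteins)])
    peptide_names = np.array(
        [
            f"{proteins[prot_of_pep[i]]}_pep{(i % peptides_per_protein) + 1:0{qw}d}"
            for i in range(n_pep)
        ]
    )

    # expand to (n_pep, n_samples)
    jitter = (
        rng.normal(0.0, truth.rt_jitter_sd, size=(n_pep, n_samples))
        if truth.rt_jitter_sd > 0
        else np.zeros((n_pep, n_samples))
    )
    rt = rt_base[:, None] + jitter
    np.clip(rt, lo, hi, out=rt)
    eps = (
        rng.normal(0.0, truth.sigma_eps, size=(n_pep, n_samples))
        if truth.sigma_eps > 0
        else np.zeros((n_pep, n_samples))
    )
    intensity = fixed[None, :] + offsets[:, None] + theta[prot_of_pep, :] + eps
    if truth.rt_bias is not None:
        for s in range(n_samples):
            intensity[:, s] += truth.rt_bias(sample_ids[s], rt[:, s])

    table = pd.DataFrame(
        {
            "peptide": np.repeat(peptide_names, n_samples),
            "charge": 2,
            "protein": np.repeat(proteins[prot_of_pep], n_samples),
            "rt_seconds": rt.ravel(),
            "sample_id": np.tile(sample_ids, n_pep),
            "log10_intensity": intensity.ravel(),
        }
    )
    if truth.missing_rate > 0:
        if truth.mnar:
            # missing-not-at-random: drop probability decreases with the
            # intensity's rank, averaging to missing_rate
            ranks = table["log10_intensity"].rank(pct=True).to_numpy()
            p_miss = np.clip(2.0 * truth.missing_rate * (1.0 - ranks), 0.0, 1.0)
        else:
            p_miss = np.full(len(table), truth.missing_rate)
        keep = rng.uniform(size=len(table)) >= p_miss
        table = table.loc[keep].reset_index(drop=True)
    return table


def simulate_spectral_counts(
    truth: SimulationTruth, design: pd.DataFrame, n_proteins: int
) -> pd.DataFrame:
    """Simulate per-protein spectral counts, Poisson with log rate
    mu + fixed effects + replicate effect (natural-log scale).

    ``mu = -inf`` is honored as rate zero (all-zero counts). Returns
    columns ``protein, sample_id, count``.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(truth.seed)
    log_rate = truth.fixed_effects(design)
    rate = np.exp(log_rate)  # exp(-inf) -> 0.0
    if not np.all(np.isfinite(rate)):
        raise ValueError("count rates must be finite (log-rate effects too large?)")
    pw = len(str(n_proteins))
    counts = rng.poisson(rate, size=(n_proteins, len(design)))
    return pd.DataFrame(
        {
            "protein": np.repeat(
                [f"P{i + 1:0{pw}d}" for i in range(n_proteins)], len(design)
            ),
            "sample_id": np.tile(design["sample_id"].to_numpy(), n_proteins),
            "count": counts.ravel(),
        }
    )


# -- promoter sequences with planted Pho boxes ------------------------------


@dataclass
class PlantedBox:
    """Request to plant one Pho box.

    ``start`` is the 1-based forward-strand coordinate of the leftmost
    base of the planted span. A canonical box is two direct-repeat units
    at the consensus CA-CA period (span 17 bp); a half box is a single
    8-bp unit. ``mismatches`` gives, per unit, how many non-CA positions
    to mutate away from the consensus.
    """

    start: int
    strand: str = "+"
    klass: str = "canonical"
    mismatches: tuple[int, ...] = (0, 0)

    def span(self) -> int:
        return 2 * len(PHO_BOX_UNIT) + (PHO_BOX_PERIOD - len(PHO_BOX_UNIT)) \
            if self.klass == "canonical" else len(PHO_BOX_UNIT)


@dataclass
class PlantedMotifTruth:
    sequence_id: str
    positions: list[tuple[int, str, str]] = field(default_factory=list)
    mismatches: list[tuple[int, ...]] = field(default_factory=list)


_CA_OFFSETS = (4, 5)  # positions within the 8-mer unit that must stay exact


def _mutate_unit(unit: str, n_mismatch: int, rng: np.random.Generator) -> str:
    if n_mismatch == 0:
        return unit
    mutable = [i for i in range(len(unit)) if i not in _CA_OFFSETS]
    if n_mismatch > len(mutable):
        raise ValueError("cannot request more mismatches than non-CA positions")
    picks = rng.choice(len(mutable), size=n_mismatch, replace=False)
    out = list(unit)
    for p in sorted(mutable[i] for i in picks):
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def plant_pho_boxes(
    seq_length: int,
    gc: float,
    boxes: Sequence[PlantedBox | Mapping],
    seed: int,
    *,
    sequence_id: str = "promoter",
) -> tuple[SeqRecord, PlantedMotifTruth]:
    """Generate an i.i.d. background sequence with given GC content and
    write the requested Pho boxes into it exactly.

    Planted boxes must lie within bounds and must not overlap. Returns the
    sequence as a Biopython record together with the planted truth.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = list(rng.choice(list("ACGT"), size=seq_length, p=probs))

    parsed: list[PlantedBox] = []
    for b in boxes:
        if isinstance(b, Mapping):
            b = PlantedBox(**b)
        if b.klass not in ("canonical", "half"):
            raise ValueError(f"unknown box class {b.klass!r}")
        if b.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {b.strand!r}")
        n_units = 2 if b.klass == "canonical" else 1
        mism = tuple(b.mismatches)[:n_units]
        if len(mism) < n_units:
            mism = mism + (0,) * (n_units - len(mism))
        b = PlantedBox(b.start, b.strand, b.klass, mism)
        if b.start < 1 or b.start + b.span() - 1 > seq_length:
            raise ValueError(
                f"box at {b.start} (span {b.span()}) exceeds sequence of "
                f"length {seq_length}"
            )
        parsed.append(b)

    intervals = sorted((b.start, b.start + b.span() - 1) for b in parsed)
    for (a1, b1), (a2, _b2) in zip(intervals, intervals[1:]):
        if a2 <= b1:
            raise ValueError("planted boxes overlap")

    truth = PlantedMotifTruth(sequence_id=sequence_id)
    for b in parsed:
        units = [_mutate_unit(PHO_BOX_UNIT, m, rng) for m in b.mismatches]
        if b.klass == "canonical":
            spacer = "ACGT"[rng.integers(4)]
            motif = units[0] + spacer + units[1]
        else:
            motif = units[0]
        if b.strand == "-":
            motif = str(Seq(motif).reverse_complement())
        seq[b.start - 1 : b.start - 1 + len(motif)] = list(motif)
        truth.positions.append((b.start, b.strand, b.klass))
        truth.mismatches.append(b.mismatches)

    record = SeqRecord(Seq("".join(seq)), id=sequence_id, description="")
    return record, truth
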