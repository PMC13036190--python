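"""Synthetic data with planted structure for the two-tumor-suppressor workflow.

Two generators:

``simulate_contrasts``
    Three differential-expression tables (single mutants L and S, double
    mutant LS, each against the wild-type control) over a shared gene
    universe, with planted class proportions (L-only, S-only, shared LS,
    null), a tunable Pearson correlation between the LS genes' effect
    sizes in the L and S contrasts, and a planted fraction of
    inversely-regulated LS genes (sign-discordant, both magnitudes beyond
    the fold-change floor).

``simulate_cohort``
    A TPM-like samples x genes cohort with genotype x stage subgroups
    carrying planted group-specific expression shifts.

Both return the planted truth (:class:`SimulationTruth`), which is the
oracle for every recovery test downstream.

Effect-pair model
-----------------
Effect magnitudes are truncated normals bounded below by ``effect_floor``
(so every planted effect clears the fold-change detection threshold),
coupled across the L and S contrasts through a Gaussian copula.  The
copula correlation is calibrated numerically — via the Hermite expansion
of the magnitude transform — so that the *population* Pearson correlation
of the full LS effect-pair scatter (sign-concordant pairs plus the planted
inverse fraction) equals ``rho_LS``.  With an inverse fraction f the
scatter correlation factorizes as

    r = (1 - 2 f) * (m^2 + c(rho_g)) / (m^2 + v)

where m, v are the magnitude mean and variance and c(rho_g) the magnitude
covariance induced by copula correlation rho_g; the generator solves this
for rho_g and raises if ``rho_LS`` is unreachable for the configured
magnitude distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss, hermeval
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import truncnorm

from .io import DETable, ExpressionCohort, GeneSetCollection, GENOTYPE_FLAGS

logger = logging.getLogger(__name__)

CLASS_LABELS = ("L", "S", "LS", "null")

#: DEG class proportions of the reference single-cell study:
#: 911 L, 814 S, 5528 LS of 11002 detected genes; remainder unclassified.
DEFAULT_PROPORTIONS = (911 / 11002, 814 / 11002, 5528 / 11002, 3749 / 11002)

#: genotype x stage subgroup sizes of the reference LUAD bulk cohort
DEFAULT_GROUP_SIZES = {
    ("WT", "early"): 237,
    ("LKB1", "early"): 7,
    ("SMARCA4", "early"): 3,
    ("TP53", "early"): 51,
    ("WT", "late"): 61,
    ("LKB1", "late"): 2,
    ("SMARCA4", "late"): 2,
    ("TP53", "late"): 18,
}

TPM_TOTAL = 1e6


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PValueModel:
    """Calibrated significance generator.

    True effects receive raw p ~ U(0, alpha/10) and adjusted p below
    ``alpha``; nulls receive raw p ~ U(0, 1) and adjusted p above
    ``alpha``.  ``false_negative_rate`` / ``false_positive_rate`` inject
    threshold misses on the adjusted scale.  Adjusted p-values are drawn
    directly on either side of ``alpha`` (not re-derived by BH from the
    raw p), which makes the noise-free regime exactly separable.
    """

    alpha: float = 0.05
    false_negative_rate: float = 0.0
    false_positive_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for rate in (self.false_negative_rate, self.false_positive_rate):
            if not 0 <= rate <= 1:
                raise ValueError("error rates must lie in [0, 1]")


@dataclass(frozen=True)
class ContrastSimulationConfig:
    """Planted structure for the three mutant-vs-WT DE tables."""

    n_genes: int = 11002
    class_proportions: tuple = DEFAULT_PROPORTIONS
    effect_magnitude_mean: float = 1.0
    effect_magnitude_sd: float = 0.8
    rho_LS: float = 0.69
    inverse_fraction: float = 0.082
    null_noise_sd: float = 0.15
    effect_floor: float = 0.5
    p_value_model: PValueModel = field(default_factory=PValueModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.class_proportions) != 4:
            raise ValueError("class_proportions must have 4 entries (L, S, LS, null)")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("class proportions must be non-negative")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1 within 1e-9")
        if not -1 <= self.rho_LS <= 1:
            raise ValueError("rho_LS must lie in [-1, 1]")
        if not 0 <= self.inverse_fraction <= 1:
            raise ValueError("inverse_fraction must lie in [0, 1]")
        if self.effect_magnitude_mean <= 0:
            raise ValueError("effect_magnitude_mean must be > 0")
        if self.effect_magnitude_sd < 0 or self.null_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.effect_floor <= 0:
            raise ValueError("effect_floor must be > 0")
        if self.effect_magnitude_sd == 0 and self.effect_magnitude_mean < self.effect_floor:
            raise ValueError("degenerate magnitudes (sd=0) fall below effect_floor")


@dataclass(frozen=True)
class GroupShift:
    """A planted expression shift: n_genes shifted by log2_shift in one subgroup."""

    genotype: str
    stage: str
    n_genes: int
    log2_shift: float

    def key(self) -> tuple:
        return (self.genotype, self.stage)


@dataclass(frozen=True)
class CohortSimulationConfig:
    """Planted structure for the TPM-like genotype x stage cohort."""

    genes: int = 2000
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    group_shifts: tuple = ()
    dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes < 1:
            raise ValueError("genes must be positive")
        if not self.group_sizes:
            raise ValueError("group_sizes must be non-empty")
        for key, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {key} has < 1 sample")
            if n < 2:
                logger.warning("group %s has %d sample(s); too small for a DEA", key, n)
        if self.dispersion < 0 or self.baseline_log2_sd < 0:
            raise ValueError("dispersion and baseline sd must be >= 0")
        for shift in self.group_shifts:
            if shift.key() not in self.group_sizes:
                raise ValueError(f"shift targets unknown group {shift.key()}")
            if shift.n_genes < 1 or shift.n_genes > self.genes:
                raise ValueError("shift n_genes out of range")


@dataclass
class SimulationTruth:
    """Planted ground truth: per-gene class labels, effect sizes and flags.

    ``table`` is indexed by gene with columns ``label`` (L/S/LS/null),
    ``beta_L``, ``beta_S``, ``beta_LS`` and ``inverse``.  For cohort
    simulations, ``group_shifts`` maps (genotype, stage) to a
    {gene: log2 shift} dict.
    """

    table: pd.DataFrame | None = None
    group_shifts: dict = field(default_factory=dict)

    def class_counts(self) -> dict:
        if self.table is None:
            return {}
        counts = self.table["label"].value_counts()
        return {lab: int(counts.get(lab, 0)) for lab in CLASS_LABELS}

    def affected_genes(self, contrast_id: str) -> set:
        """Genes carrying a true effect in the given contrast's table."""
        if self.table is None:
            raise ValueError("no contrast truth available")
        carriers = {"L": ("L", "LS"), "S": ("S", "LS"), "LS": ("L", "S", "LS")}
        if contrast_id not in carriers:
            raise ValueError(f"unknown contrast {contrast_id!r}")
        mask = self.table["label"].isin(carriers[contrast_id])
        return set(self.table.index[mask])

    def genes_of_class(self, label: str) -> set:
        if self.table is None:
            raise ValueError("no contrast truth available")
        return set(self.table.index[self.table["label"] == label])

    def shifted_genes(self, genotype: str, stage: str) -> set:
        return set(self.group_shifts.get((genotype, stage), {}))


# ---------------------------------------------------------------------------
# Allocation and magnitude machinery
# ---------------------------------------------------------------------------

def largest_remainder_counts(n: int, proportions) -> np.ndarray:
    """Apportion n items to classes by the largest-remainder rule.

    Deterministic: exact quotas floored, leftovers to the largest
    fractional parts, ties broken by class position.
    """
    quotas = np.asarray(proportions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    if remainder:
        frac = quotas - counts
        order = np.lexsort((np.arange(len(frac)), -frac))
        counts[order[:remainder]] += 1
    return counts


def _magnitude_dist(mean: float, sd: float, floor: float):
    a = (floor - mean) / sd
    return truncnorm(a, np.inf, loc=mean, scale=sd)


def _hermite_cov_coeffs(mean: float, sd: float, floor: float,
                        kmax: int = 12, nquad: int = 64) -> np.ndarray:
    """Hermite coefficients of the Gaussian-copula magnitude covariance.

    Returns ``coeffs`` such that Cov(M1, M2) = sum_k coeffs[k-1] * rho^k for
    copula correlation rho, where M = F^{-1}(Phi(Z)) with F the truncated
    normal magnitude CDF.
    """
    x, w = hermegauss(nquad)
    w = w / np.sqrt(2.0 * np.pi)
    u = np.clip(ndtr(x), 1e-15, 1 - 1e-15)
    h = _magnitude_dist(mean, sd, floor).ppf(u)
    coeffs = np.empty(kmax)
    factorial = 1.0
    for k in range(1, kmax + 1):
        factorial *= k
        he_k = hermeval(x, [0.0] * k + [1.0])
        b_k = float(np.sum(w * h * he_k)) / factorial
        coeffs[k - 1] = b_k * b_k * factorial
    return coeffs


def calibrate_copula_rho(config: ContrastSimulationConfig) -> float:
    """Copula correlation giving population LS-scatter Pearson r = rho_LS.

    Raises ``ValueError`` with the feasible rho_LS interval when the target
    is unreachable for the configured magnitude distribution and inverse
    fraction.
    """
    if config.effect_magnitude_sd == 0:
        return 0.0  # magnitudes are constant; correlation is sign-driven
    dist = _magnitude_dist(config.effect_magnitude_mean, config.effect_magnitude_sd,
                           config.effect_floor)
    m, v = dist.mean(), dist.var()
    coeffs = _hermite_cov_coeffs(config.effect_magnitude_mean,
                                 config.effect_magnitude_sd, config.effect_floor)
    f = config.inverse_fraction
    shrink = 1.0 - 2.0 * f

    powers = np.arange(1, len(coeffs) + 1)

    def cov_of(rho: float) -> float:
        return float(np.sum(coeffs * np.power(rho, powers)))

    def overall_r(rho: float) -> float:
        return shrink * (m * m + cov_of(rho)) / (m * m + v)

    lo, hi = overall_r(-1.0), overall_r(1.0)
    if shrink < 0:
        lo, hi = hi, lo
    if not lo - 1e-9 <= config.rho_LS <= hi + 1e-9:
        raise ValueError(
            f"rho_LS={config.rho_LS} unreachable; feasible interval is "
            f"[{lo:.3f}, {hi:.3f}] for this magnitude distribution and "
            f"inverse_fraction={f}"
        )
    target = min(max(config.rho_LS, lo), hi)
    return float(brentq(lambda r: overall_r(r) - target, -1.0, 1.0, xtol=1e-12))


def _draw_magnitude_pairs(rng: np.random.Generator, n: int, rho_g: float,
                          config: ContrastSimulationConfig) -> tuple:
    """n magnitude pairs, truncated-normal marginals, Gaussian copula rho_g."""
    if n == 0:
        empty = np.empty(0)
        return empty, empty
    if config.effect_magnitude_sd == 0:
        m = np.full(n, config.effect_magnitude_mean)
        return m, m.copy()
    z1 = rng.standard_normal(n)
    z2 = rho_g * z1 + np.sqrt(max(0.0, 1.0 - rho_g * rho_g)) * rng.standard_normal(n)
    dist = _magnitude_dist(config.effect_magnitude_mean, config.effect_magnitude_sd,
                           config.effect_floor)
    u1 = np.clip(ndtr(z1), 1e-15, 1 - 1e-15)
    u2 = np.clip(ndtr(z2), 1e-15, 1 - 1e-15)
    return dist.ppf(u1), dist.ppf(u2)


def _draw_magnitudes(rng: np.random.Generator, n: int,
                     config: ContrastSimulationConfig) -> np.ndarray:
    if config.effect_magnitude_sd == 0:
        return np.full(n, config.effect_magnitude_mean)
    dist = _magnitude_dist(config.effect_magnitude_mean, config.effect_magnitude_sd,
                           config.effect_floor)
    u = np.clip(rng.uniform(size=n), 1e-15, 1 - 1e-15)
    return dist.ppf(u)


# ---------------------------------------------------------------------------
# Contrast simulation
# ---------------------------------------------------------------------------

def _significance(rng: np.random.Generator, is_true: np.ndarray,
                  model: PValueModel) -> tuple:
    """Raw and adjusted p-values for one table given true-effect indicators."""
    n = len(is_true)
    p = rng.uniform(1e-12, 1.0, size=n)
    p[is_true] = rng.uniform(1e-12, model.alpha / 10.0, size=int(is_true.sum()))

    adj = rng.uniform(model.alpha, 1.0, size=n)            # nulls: fail threshold
    adj[is_true] = rng.uniform(1e-12, model.alpha, size=int(is_true.sum()))
    # inject threshold misses on the adjusted scale
    if model.false_negative_rate > 0:
        miss = is_true & (rng.uniform(size=n) < model.false_negative_rate)
        adj[miss] = rng.uniform(model.alpha, 1.0, size=int(miss.sum()))
    if model.false_positive_rate > 0:
        hit = ~is_true & (rng.uniform(size=n) < model.false_positive_rate)
        adj[hit] = rng.uniform(1e-12, model.alpha, size=int(hit.sum()))
    return p, adj


def simulate_contrasts(config: ContrastSimulationConfig) -> tuple:
    """Simulate the three mutant-vs-WT DE tables plus the planted truth.

    Returns ``(table_L, table_S, table_LS, truth)``.  Class labels are
    allocated exactly by largest-remainder rounding of the configured
    proportions; L-class genes carry their effect in the L and LS tables,
    S-class genes in S and LS, LS-class genes in all three (the LS-table
    effect being the mean of the two single-mutant effects plus noise —
    dominant-signed mean of magnitudes for inverse genes); null genes carry
    only noise everywhere.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = pd.Index([f"G{i:05d}" for i in range(n)], name="gene")

    counts = largest_remainder_counts(n, config.class_proportions)
    labels = np.repeat(np.array(CLASS_LABELS, dtype=object), counts)
    labels = labels[rng.permutation(n)]

    beta_L = np.zeros(n)
    beta_S = np.zeros(n)
    beta_LS = np.zeros(n)
    inverse = np.zeros(n, dtype=bool)

    idx_L = np.flatnonzero(labels == "L")
    idx_S = np.flatnonzero(labels == "S")
    idx_LS = np.flatnonzero(labels == "LS")

    # single-loss classes: one effect, carried into the double-mutant table
    for idx, target in ((idx_L, beta_L), (idx_S, beta_S)):
        mags = _draw_magnitudes(rng, len(idx), config)
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        target[idx] = signs * mags
        beta_LS[idx] = target[idx]

    # shared LS class: copula-coupled magnitude pairs, planted inverse subset
    n_ls = len(idx_LS)
    if n_ls:
        rho_g = calibrate_copula_rho(config)
        m_l, m_s = _draw_magnitude_pairs(rng, n_ls, rho_g, config)
        shared_sign = rng.choice([-1.0, 1.0], size=n_ls)
        inv = rng.uniform(size=n_ls) < config.inverse_fraction
        sign_s = np.where(inv, -shared_sign, shared_sign)
        beta_L[idx_LS] = shared_sign * m_l
        beta_S[idx_LS] = sign_s * m_s
        inverse[idx_LS] = inv

        mean_mag = 0.5 * (m_l + m_s)
        dominant = np.where(m_l >= m_s, shared_sign, sign_s)
        ls_center = np.where(inv, dominant * mean_mag,
                             0.5 * (beta_L[idx_LS] + beta_S[idx_LS]))
        beta_LS[idx_LS] = ls_center + rng.normal(
            0.0, config.effect_magnitude_sd / 2.0, size=n_ls)

    truth = SimulationTruth(table=pd.DataFrame(
        {"label": labels, "beta_L": beta_L, "beta_S": beta_S,
         "beta_LS": beta_LS, "inverse": inverse}, index=genes))

    tables = {}
    effects = {"L": beta_L, "S": beta_S, "LS": beta_LS}
    for contrast in ("L", "S", "LS"):
        affected = truth.affected_genes(contrast)
        is_true = np.asarray(genes.isin(list(affected)))
        lfc = effects[contrast].copy()
        noise = rng.normal(0.0, config.null_noise_sd, size=n)
        lfc[~is_true] = noise[~is_true]
        p, adj = _significance(rng, is_true, config.p_value_model)
        tables[contrast] = DETable(
            contrast_id=contrast,
            data=pd.DataFrame({"log2fc": lfc, "p_value": p, "adj_p": adj}, index=genes),
            provenance={"simulated": True, "seed": config.seed},
        )
    return tables["L"], tables["S"], tables["LS"], truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def genotype_to_flags(genotype: str) -> dict:
    """Map a genotype label (e.g. 'LKB1', 'LKB1+SMARCA4', 'WT') to flag dict."""
    flags = {flag: False for flag in GENOTYPE_FLAGS}
    if genotype != "WT":
        for part in genotype.split("+"):
            flag = f"{part}_mut"
            if flag not in flags:
                raise ValueError(f"unknown genotype component {part!r}")
            flags[flag] = True
    return flags


def simulate_cohort(config: CohortSimulationConfig) -> tuple:
    """Simulate a TPM-like cohort with planted group shifts.

    Log2 expression is a per-gene log-normal baseline plus the planted
    group shift plus Gaussian dispersion; samples are then renormalized to
    a constant library size (1e6, TPM convention).  Returns
    ``(cohort, truth)`` where truth records the shifted-gene sets per
    (genotype, stage) group.
    """
    rng = np.random.default_rng(config.seed)
    genes = pd.Index([f"G{i:05d}" for i in range(config.genes)], name="gene")
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          size=config.genes)

    # disjoint shifted-gene sets per shift entry, drawn from a common pool
    pool = list(rng.permutation(config.genes))
    shift_vectors: dict = {}
    group_shift_genes: dict = {}
    for shift in config.group_shifts:
        if len(pool) < shift.n_genes:
            raise ValueError("not enough genes to allocate disjoint shift sets")
        chosen = [pool.pop() for _ in range(shift.n_genes)]
        vec = shift_vectors.setdefault(shift.key(), np.zeros(config.genes))
        vec[chosen] = shift.log2_shift
        entry = group_shift_genes.setdefault(shift.key(), {})
        entry.update({genes[i]: shift.log2_shift for i in chosen})

    rows = []
    meta_rows = []
    sample_ids = []
    counter = 0
    for (genotype, stage), size in config.group_sizes.items():
        shift_vec = shift_vectors.get((genotype, stage), 0.0)
        flags = genotype_to_flags(genotype)
        for _ in range(size):
            sid = f"S{counter:04d}"
            counter += 1
            log2x = baseline + shift_vec + rng.normal(0.0, config.dispersion,
                                                      size=config.genes)
            rows.append(np.exp2(log2x))
            meta_rows.append({**flags, "stage": stage})
            sample_ids.append(sid)

    matrix = np.asarray(rows)
    matrix *= TPM_TOTAL / matrix.sum(axis=1, keepdims=True)
    cohort = ExpressionCohort(
        expression=pd.DataFrame(matrix, index=pd.Index(sample_ids, name="sample_id"),
                                columns=genes),
        metadata=pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id")),
    )
    return cohort, SimulationTruth(group_shifts=group_shift_genes)


# ---------------------------------------------------------------------------
# Gene-set simulation (for enrichment demos and tests)
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    universe,
    truth: SimulationTruth | None = None,
    n_sets: int = 30,
    set_size: tuple = (10, 50),
    n_enriched: int = 0,
    enriched_class: str = "LS",
    purity: float = 0.8,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets over a universe, optionally enriched for a planted class.

    The first ``n_enriched`` sets draw a ``purity`` fraction of their
    members from ``truth``'s genes of ``enriched_class``; the rest are
    uniform draws.  Term ids are ``SET0000``-style with self-describing
    names.
    """
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(universe), dtype=object)
    class_genes = None
    if truth is not None and truth.table is not None:
        class_genes = np.array(sorted(truth.genes_of_class(enriched_class)), dtype=object)
    if n_enriched > 0 and (class_genes is None or len(class_genes) == 0):
        raise ValueError("enriched sets requested but no truth/class genes available")

    sets: dict = {}
    names: dict = {}
    for i in range(n_sets):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        if i < n_enriched:
            n_core = min(int(round(purity * size)), len(class_genes))
            core = rng.choice(class_genes, size=n_core, replace=False)
            rest = rng.choice(universe, size=size - n_core, replace=False)
            members = set(core) | set(rest)
            label = f"enriched {enriched_class} set {i}"
        else:
            members = set(rng.choice(universe, size=min(size, len(universe)),
                                     replace=False))
            label = f"random set {i}"
        sets[f"SET{i:04d}"] = members
        names[f"SET{i:04d}"] = label
    return GeneSetCollection(sets=sets, names=names)


# ---------------------------------------------------------------------------
# Truth I/O
# ---------------------------------------------------------------------------

def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    """Write the planted truth as TSV (contrast table and/or group shifts)."""
    path = Path(path)
    if truth.table is not None:
        out = truth.table.sort_index().rename_axis("gene").reset_index()
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        rows = [
            {"genotype": g, "stage": s, "gene": gene, "log2_shift": shift}
            for (g, s), genes in sorted(truth.group_shifts.items())
            for gene, shift in sorted(genes.items())
        ]
        pd.DataFrame(rows, columns=["genotype", "stage", "gene", "log2_shift"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g")


def with_seed(config, seed: int):
    """Return a copy of a simulation config with a different seed."""
    return replace(config, seed=seed)
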