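"""Mutation-subgroup selection, correlation analysis and stage-stratified DEA.

Operates on TPM expression cohorts: select genotype-defined tumor
subgroups, reduce with PCA, correlate subgroup or sample profiles
(optionally against external contrast log2FC profiles), detect
stage-stratified marker genes of each mutant subgroup against
stage-matched wild-type samples (rank-sum test, BH within each
genotype x stage), and scale matrices for heatmap display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .classify import Thresholds
from .io import ExpressionCohort, GENOTYPE_FLAGS, bh_adjust

logger = logging.getLogger(__name__)

#: AJCC stage-string mapping: I/II early, III/IV late (sub-stages included)
DEFAULT_STAGE_MAP = {
    "i": "early", "ia": "early", "ib": "early",
    "ii": "early", "iia": "early", "iib": "early",
    "iii": "late", "iiia": "late", "iiib": "late", "iiic": "late",
    "iv": "late", "iva": "late", "ivb": "late",
}


def map_stage_tokens(raw, stage_map: dict | None = None) -> pd.Series:
    """Map raw AJCC stage strings (e.g. 'Stage IIIA') to early/late/unknown."""
    stage_map = stage_map or DEFAULT_STAGE_MAP
    out = []
    for value in raw:
        token = str(value).strip().lower().removeprefix("stage").strip()
        out.append(stage_map.get(token, "unknown"))
    index = raw.index if isinstance(raw, (pd.Series, pd.Index)) else None
    return pd.Series(out, index=index, name="stage")


# ---------------------------------------------------------------------------
# Subgroups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupDefinition:
    """A genotype-defined tumor subgroup.

    ``flags`` maps mutation-flag names to a required True/False; flags not
    listed are don't-care.  ``stage`` optionally restricts to one stage.
    """

    name: str
    flags: dict = field(default_factory=dict)
    stage: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.flags) - set(GENOTYPE_FLAGS)
        if unknown:
            raise ValueError(f"unknown mutation flags: {sorted(unknown)}")

    def matches(self, meta_row: pd.Series) -> bool:
        for flag, required in self.flags.items():
            if bool(meta_row[flag]) != required:
                return False
        if self.stage is not None and meta_row["stage"] != self.stage:
            return False
        return True


def exclusive_genotype_subgroups(genotypes=("WT", "LKB1", "SMARCA4", "TP53")):
    """Subgroup definitions where exactly the named gene (none for WT) is mutated.

    Mirrors the cell-line-matched cohort split: each subgroup requires its
    own flag True and the other three flags False (KRAS is left don't-care
    unless named).
    """
    core = ("LKB1_mut", "SMARCA4_mut", "TP53_mut")
    defs = []
    for genotype in genotypes:
        flags = {flag: False for flag in core}
        if genotype != "WT":
            flag = f"{genotype}_mut"
            if flag not in GENOTYPE_FLAGS:
                raise ValueError(f"unknown genotype {genotype!r}")
            flags[flag] = True
        defs.append(SubgroupDefinition(name=genotype, flags=flags))
    return defs


def select_subgroups(
    cohort: ExpressionCohort,
    defs: list,
    allow_overlap: bool = False,
) -> dict:
    """Assign samples to matching subgroups.

    Returns ``{name: [sample ids]}``.  A sample matching two or more
    definitions is an error unless ``allow_overlap``; an empty subgroup is
    a warning, not an error.
    """
    assignment: dict = {d.name: [] for d in defs}
    for sample, row in cohort.metadata.iterrows():
        matched = [d.name for d in defs if d.matches(row)]
        if len(matched) > 1 and not allow_overlap:
            raise ValueError(
                f"sample {sample!r} matches overlapping subgroups {matched}")
        for name in matched:
            assignment[name].append(sample)
    for name, samples in assignment.items():
        if not samples:
            logger.warning("subgroup %r is empty", name)
    return assignment


# ---------------------------------------------------------------------------
# PCA and correlation
# ---------------------------------------------------------------------------

def log2_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1) transform."""
    return np.log2(matrix + 1.0)


def pca_reduce(
    matrix: pd.DataFrame,
    variance_target: float = 0.8,
    max_components: int = 10,
) -> tuple:
    """PCA-reduce a samples x genes TPM matrix.

    Input is log2(TPM+1)-transformed and gene-centered.  The smallest
    number of components explaining at least ``variance_target`` of the
    variance is retained, capped at ``max_components``.  Returns
    ``(scores, explained_variance_ratio)``.
    """
    if matrix.shape[0] < 3:
        raise ValueError(f"PCA needs >= 3 samples, got {matrix.shape[0]}")
    x = log2_tpm(matrix)
    x = x - x.mean(axis=0)
    n_max = min(matrix.shape[0] - 1, matrix.shape[1], max_components)
    pca = PCA(n_components=n_max, svd_solver="full", random_state=0)
    scores = pca.fit_transform(x.to_numpy())
    evr = pca.explained_variance_ratio_
    cumulative = np.cumsum(evr)
    n_keep = int(np.searchsorted(cumulative, variance_target) + 1)
    n_keep = min(n_keep, n_max)
    cols = [f"PC{i + 1}" for i in range(n_keep)]
    return (pd.DataFrame(scores[:, :n_keep], index=matrix.index, columns=cols),
            evr[:n_keep])


def correlation_analysis(profiles: dict, zscore_display: bool = False) -> pd.DataFrame:
    """Pairwise Pearson correlation of named profiles over a shared index.

    A constant profile yields NaN for its pairs (reported missing with a
    warning).  With ``zscore_display`` the off-diagonal entries are
    z-scored across the matrix for heatmap display.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    names = list(profiles)
    frame = pd.DataFrame({name: pd.Series(vec) for name, vec in profiles.items()})
    if frame.isna().any().any():
        raise ValueError("profiles must share an identical index")
    mat = frame.corr(method="pearson")
    constant = frame.std(ddof=0) == 0
    if constant.any():
        logger.warning("constant profile(s) %s: correlations undefined",
                       list(frame.columns[constant]))
        mat.loc[constant, :] = np.nan
        mat.loc[:, constant] = np.nan
    np.fill_diagonal(mat.values, 1.0)
    mat = mat.loc[names, names]
    if zscore_display:
        mat = zscore_offdiagonal(mat)
    return mat


def zscore_offdiagonal(corr: pd.DataFrame) -> pd.DataFrame:
    """Z-score the off-diagonal entries of a square matrix (display convention)."""
    out = corr.copy().astype(float)
    mask = ~np.eye(len(out), dtype=bool)
    vals = out.to_numpy()[mask]
    vals = vals[~np.isnan(vals)]
    sd = vals.std(ddof=0)
    if sd == 0:
        out.values[mask] = 0.0
    else:
        out.values[mask] = (out.to_numpy()[mask] - vals.mean()) / sd
    return out


def cross_dataset_correlation(
    contrast_profiles: dict,
    subgroup_profiles: dict,
    min_shared_genes: int = 30,
) -> pd.DataFrame:
    """Pearson r between cell-line contrast profiles and cohort subgroup profiles.

    Both profile dicts map a name to a log2FC Series indexed by gene; the
    correlation is computed over the intersection of all gene indices,
    which must contain at least ``min_shared_genes`` genes.  Returns the
    rectangular block (cell lines in rows, subgroups in columns).
    """
    all_profiles = {**contrast_profiles, **subgroup_profiles}
    shared = None
    for vec in all_profiles.values():
        idx = pd.Series(vec).index
        shared = idx if shared is None else shared.intersection(idx)
    if shared is None or len(shared) < min_shared_genes:
        n = 0 if shared is None else len(shared)
        raise ValueError(f"only {n} shared gene(s); need >= {min_shared_genes}")
    shared = shared.sort_values()

    block = pd.DataFrame(index=list(contrast_profiles),
                         columns=list(subgroup_profiles), dtype=float)
    for cl, cvec in contrast_profiles.items():
        c = pd.Series(cvec).loc[shared].to_numpy(dtype=float)
        for sg, svec in subgroup_profiles.items():
            s = pd.Series(svec).loc[shared].to_numpy(dtype=float)
            if c.std(ddof=0) == 0 or s.std(ddof=0) == 0:
                block.loc[cl, sg] = np.nan
            else:
                block.loc[cl, sg] = float(np.corrcoef(c, s)[0, 1])
    return block


def subgroup_log2fc_profiles(
    cohort: ExpressionCohort,
    subgroups: dict,
    wt_name: str = "WT",
) -> dict:
    """Mean log2(TPM+1) difference of each subgroup vs the WT subgroup."""
    if wt_name not in subgroups:
        raise ValueError(f"subgroups must include the reference {wt_name!r}")
    logx = log2_tpm(cohort.expression)
    wt_mean = logx.loc[subgroups[wt_name]].mean(axis=0)
    return {
        name: logx.loc[samples].mean(axis=0) - wt_mean
        for name, samples in subgroups.items()
        if name != wt_name and samples
    }


# ---------------------------------------------------------------------------
# Stage-stratified DEA
# ---------------------------------------------------------------------------

class StageMarkerDetector(BaseEstimator):
    """Stage-stratified marker detection: mutant vs stage-matched WT.

    For each (genotype, stage) group with at least ``min_group_size``
    samples, per gene: log2FC is the mean log2(TPM+1) difference against
    the stage-matched WT group, significance from a two-sided
    Wilcoxon-Mann-Whitney rank-sum test, BH-adjusted across genes within
    the (genotype, stage) stratum.  The same thresholds as the contrast
    DEG calling (``lfc_min``, ``fdr_max``) define markers.

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : pd.DataFrame   all tested rows (genotype, stage, gene, log2fc, p, adj_p)
    markers_ : pd.DataFrame   the rows passing thresholds, with a direction column
    group_sizes_ : dict       (genotype, stage) -> n samples entering the DEA
    """

    def __init__(self, lfc_min: float = 0.5, fdr_max: float = 0.05,
                 min_group_size: int = 2,
                 genotypes=("LKB1", "SMARCA4", "TP53"), wt_name: str = "WT"):
        self.lfc_min = lfc_min
        self.fdr_max = fdr_max
        self.min_group_size = min_group_size
        self.genotypes = genotypes
        self.wt_name = wt_name

    def fit(self, cohort: ExpressionCohort, y=None) -> "StageMarkerDetector":
        defs = exclusive_genotype_subgroups((self.wt_name,) + tuple(self.genotypes))
        logx = log2_tpm(cohort.expression)
        meta = cohort.metadata
        frames = []
        self.group_sizes_ = {}
        for stage in ("early", "late"):
            stage_mask = meta["stage"] == stage
            groups = {
                d.name: meta.index[stage_mask & meta.apply(d.matches, axis=1)]
                for d in defs
            }
            wt = groups.pop(self.wt_name)
            if len(wt) < self.min_group_size:
                logger.warning("stage %s: WT group has %d sample(s); stage skipped",
                               stage, len(wt))
                continue
            wt_vals = logx.loc[wt]
            for genotype, samples in groups.items():
                if len(samples) < self.min_group_size:
                    logger.warning("group (%s, %s) has %d sample(s); skipped",
                                   genotype, stage, len(samples))
                    continue
                self.group_sizes_[(genotype, stage)] = len(samples)
                frames.append(self._test_group(genotype, stage,
                                               logx.loc[samples], wt_vals))
        if frames:
            self.results_ = pd.concat(frames, ignore_index=True)
        else:
            self.results_ = pd.DataFrame(
                columns=["genotype", "stage", "gene", "log2fc", "p_value", "adj_p"])
        passing = (self.results_["log2fc"].abs() >= self.lfc_min) & \
                  (self.results_["adj_p"] < self.fdr_max)
        markers = self.results_[passing].copy()
        markers["direction"] = np.where(markers["log2fc"] > 0, "up", "down")
        self.markers_ = markers
        return self

    def _test_group(self, genotype: str, stage: str,
                    mut_vals: pd.DataFrame, wt_vals: pd.DataFrame) -> pd.DataFrame:
        lfc = mut_vals.mean(axis=0) - wt_vals.mean(axis=0)
        with np.errstate(all="ignore"):
            stat = mannwhitneyu(mut_vals.to_numpy(), wt_vals.to_numpy(),
                                alternative="two-sided", axis=0)
        p = np.where(np.isnan(stat.pvalue), 1.0, stat.pvalue)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        return pd.DataFrame({
            "genotype": genotype,
            "stage": stage,
            "gene": mut_vals.columns,
            "log2fc": lfc.to_numpy(),
            "p_value": p,
            "adj_p": bh_adjust(p),
        })


def stage_stratified_dea(
    cohort: ExpressionCohort,
    thresholds: Thresholds | None = None,
    min_group_size: int = 2,
    genotypes=("LKB1", "SMARCA4", "TP53"),
) -> StageMarkerDetector:
    """Functional wrapper over :class:`StageMarkerDetector` (fitted)."""
    thresholds = thresholds or Thresholds()
    return StageMarkerDetector(
        lfc_min=thresholds.lfc_min, fdr_max=thresholds.fdr_max,
        min_group_size=min_group_size, genotypes=genotypes,
    ).fit(cohort)


# ---------------------------------------------------------------------------
# Heatmap scaling
# ---------------------------------------------------------------------------

def rowscale_for_heatmap(matrix: pd.DataFrame, mode: str = "minmax") -> pd.DataFrame:
    """Scale each row for heatmap display.

    ``minmax`` maps each row to [0, 1] (row min - row max convention);
    ``zscore`` centers and scales each row.  Constant rows map to all
    zeros in both modes.
    """
    if mode not in ("minmax", "zscore"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    vals = matrix.to_numpy(dtype=float)
    if mode == "minmax":
        lo = vals.min(axis=1, keepdims=True)
        hi = vals.max(axis=1, keepdims=True)
        span = hi - lo
        out = np.where(span == 0, 0.0, (vals - lo) / np.where(span == 0, 1.0, span))
    else:
        mean = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        out = np.where(sd == 0, 0.0, (vals - mean) / np.where(sd == 0, 1.0, sd))
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
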