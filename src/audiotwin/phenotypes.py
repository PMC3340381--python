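"""Scalar hearing phenotypes from per-frequency pure-tone thresholds.

Pipeline: choose the better ear (whole-ear rule), log-transform thresholds,
fit a correlation-matrix PCA, and assemble the per-subject phenotype table
(PTA, BEHL, PC1, PC2, PC1-PC2, optional SNR).  Phenotypes are ranked by two
criteria: absolute correlation with age and variance shared with the
audiogram-shape component (PC2) beyond age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from audiotwin.cohort import TwinCohort

logger = logging.getLogger(__name__)

BEHL_FREQS = (0.5, 1.0, 2.0, 4.0)
PHENOTYPE_COLUMNS = ("pta", "behl", "pc1", "pc2", "pc1_minus_pc2")


class PhenotypeError(ValueError):
    pass


def better_ear(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Whole-ear better-ear selection.

    Returns every frequency from the single ear whose across-frequency mean
    threshold is lower; ties go to the left ear.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise PhenotypeError("left and right ears must cover identical frequencies")
    if np.isnan(left).any() or np.isnan(right).any():
        raise PhenotypeError("missing threshold in one or both ears")
    return left if left.mean() <= right.mean() else right


def log_transform(
    thresholds: np.ndarray, offset: float = 25.0, base: float = 10.0
) -> np.ndarray:
    """``log_base(threshold + offset)`` per entry.

    The default 25 dB offset keeps the argument positive for audiometric
    thresholds down to just above -25 dB HL.
    """
    x = np.asarray(thresholds, dtype=float) + offset
    if np.any(x <= 0):
        bad = np.asarray(thresholds, dtype=float)[x <= 0]
        raise PhenotypeError(
            f"threshold + offset must be positive; offending thresholds: {bad.tolist()}"
        )
    return np.log(x) / np.log(base)


def scalar_averages(
    thresholds: np.ndarray,
    freqs: tuple[float, ...],
    behl_freqs: tuple[float, ...] = BEHL_FREQS,
) -> tuple[float, float]:
    """(PTA, BEHL) from raw better-ear thresholds in dB.

    PTA averages all configured frequencies; BEHL averages 0.5-4 kHz.
    """
    freqs = tuple(float(f) for f in freqs)
    if len(freqs) == 0:
        raise PhenotypeError("empty frequency configuration")
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (len(freqs),):
        raise PhenotypeError("thresholds must match the frequency list")
    idx = [i for i, f in enumerate(freqs) if f in behl_freqs]
    if not idx:
        raise PhenotypeError("no BEHL frequencies present in the configuration")
    return float(thresholds.mean()), float(thresholds[idx].mean())


@dataclass
class AudiogramMatrix:
    """Subjects x frequencies matrix of better-ear log-transformed thresholds."""

    subjects: list[str]
    freqs: tuple[float, ...]
    values: np.ndarray
    transform_params: tuple[float, float]  # (offset dB, log base)
    raw_values: np.ndarray | None = None  # better-ear thresholds in dB

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subjects), len(self.freqs)):
            raise PhenotypeError("values shape must be subjects x freqs")
        if np.isnan(self.values).any():
            raise PhenotypeError("missing cells after better-ear selection")


def audiogram_matrix(
    cohort: TwinCohort, offset: float = 25.0, base: float = 10.0
) -> AudiogramMatrix:
    """Better-ear selection + log transform for a whole cohort.

    Subjects with a missing threshold in both ears at any frequency are
    dropped with a log entry.
    """
    subjects, rows, raw_rows = [], [], []
    dropped = 0
    for rec in cohort.records:
        try:
            ear = better_ear(rec.thresholds_left, rec.thresholds_right)
        except PhenotypeError:
            dropped += 1
            logger.info("dropping subject %s: incomplete audiogram", rec.subject_id)
            continue
        subjects.append(rec.subject_id)
        raw_rows.append(ear)
        rows.append(log_transform(ear, offset=offset, base=base))
    if dropped:
        logger.warning("audiogram_matrix: dropped %d subjects with missing thresholds", dropped)
    return AudiogramMatrix(
        subjects=subjects,
        freqs=cohort.freqs,
        values=np.asarray(rows),
        transform_params=(offset, base),
        raw_values=np.asarray(raw_rows),
    )


@dataclass
class PCAResult:
    """Correlation-matrix PCA of transformed audiograms."""

    loadings: np.ndarray  # freqs x retained components
    eigenvalues: np.ndarray  # all components, non-increasing
    scores: np.ndarray  # subjects x retained components
    var_explained: np.ndarray  # per retained component
    sign_convention: str
    freqs: tuple[float, ...]
    center: np.ndarray = field(default=None)  # fitting-sample column means
    scale: np.ndarray = field(default=None)  # fitting-sample column SDs (ddof=1)

    @property
    def n_retained(self) -> int:
        return self.loadings.shape[1]

    def project(self, values: np.ndarray) -> np.ndarray:
        """Scores for new transformed audiograms using the fitted convention."""
        z = (np.asarray(values, dtype=float) - self.center) / self.scale
        return z @ self.loadings


def fit_pca(
    matrix: AudiogramMatrix,
    n_components: int | None = None,
    use_correlation: bool = True,
) -> PCAResult:
    """PCA of the correlation matrix of transformed thresholds.

    Components with eigenvalue > 1 are retained by default.  Signs are fixed
    so PC1 loadings are positive at every frequency and PC2's lowest-frequency
    loading is positive (PC2 then decreases toward high frequencies for
    down-sloping audiograms).
    """
    x = matrix.values
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise PhenotypeError("need at least 2 subjects and 2 frequencies")
    center = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [f for f, s in zip(matrix.freqs, sd) if s == 0]
        raise PhenotypeError(f"zero-variance frequency column(s): {bad}")
    if use_correlation:
        z = (x - center) / sd
    else:
        z = x - center
        sd = np.ones_like(sd)
    cov = z.T @ z / (x.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if n_components is None:
        n_keep = max(1, int(np.sum(eigvals > 1.0)))
    else:
        n_keep = int(n_components)
        if not 1 <= n_keep <= len(eigvals):
            raise PhenotypeError("n_components out of range")
    loadings = eigvecs[:, :n_keep].copy()
    # sign conventions
    if loadings[:, 0].sum() < 0:
        loadings[:, 0] *= -1
    if n_keep >= 2 and loadings[0, 1] < 0:
        loadings[:, 1] *= -1
    for j in range(2, n_keep):
        if loadings[:, j].sum() < 0:
            loadings[:, j] *= -1
    scores = z @ loadings
    total = eigvals.sum()
    return PCAResult(
        loadings=loadings,
        eigenvalues=eigvals,
        scores=scores,
        var_explained=eigvals[:n_keep] / total,
        sign_convention="PC1 loadings positive; PC2 positive at the lowest frequency",
        freqs=matrix.freqs,
        center=center,
        scale=sd,
    )


def build_phenotypes(
    cohort: TwinCohort,
    pca: PCAResult,
    offset: float | None = None,
    base: float | None = None,
) -> pd.DataFrame:
    """Per-subject phenotype table: pta, behl, pc1, pc2, pc1_minus_pc2, snr, age.

    PTA/BEHL use raw dB thresholds of the better ear; PC scores project the
    standardized log-transformed thresholds onto the fitted loadings.
    """
    if pca.n_retained < 2:
        raise PhenotypeError("PCA must retain at least 2 components for pc1/pc2 phenotypes")
    if offset is None or base is None:
        offset, base = 25.0, 10.0
    if tuple(pca.freqs) != tuple(cohort.freqs):
        raise PhenotypeError("frequency mismatch between cohort and PCA loadings")
    rows = []
    for rec in cohort.records:
        try:
            ear = better_ear(rec.thresholds_left, rec.thresholds_right)
        except PhenotypeError:
            continue
        pta, behl = scalar_averages(ear, cohort.freqs)
        scores = pca.project(log_transform(ear, offset=offset, base=base))
        pc1, pc2 = float(scores[0]), float(scores[1])
        rows.append(
            {
                "subject_id": rec.subject_id,
                "pair_id": rec.pair_id,
                "zygosity": rec.zygosity,
                "age": rec.age,
                "sex": rec.sex,
                "pta": pta,
                "behl": behl,
                "pc1": pc1,
                "pc2": pc2,
                "pc1_minus_pc2": pc1 - pc2,
                "snr": np.nan if rec.snr is None else rec.snr,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def _one_per_pair(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One randomly chosen member per pair (fixed seed) to respect relatedness."""
    rng = np.random.default_rng(seed)
    picks = []
    for _, grp in table.groupby("pair_id", sort=True):
        picks.append(grp.index[rng.integers(len(grp))])
    return table.loc[sorted(picks)]


def _ols_r2(y: np.ndarray, design: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return 1.0 - np.sum(resid**2) / tss if tss > 0 else 0.0


def compute_ranking_criteria(
    table: pd.DataFrame,
    phenotypes: tuple[str, ...] = PHENOTYPE_COLUMNS,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-phenotype (r_age, r2_pc2) criterion values.

    ``r_age`` is the Pearson correlation with age over all subjects.
    ``r2_pc2`` is the semi-partial R^2 of PC2 on the phenotype beyond age,
    computed on one twin per pair; PC2's own entry is set to 1 and excluded
    from ranking.
    """
    rows = []
    sub = _one_per_pair(table, seed=seed)
    age = table["age"].to_numpy(dtype=float)
    sub_age = sub["age"].to_numpy(dtype=float)
    sub_pc2 = sub["pc2"].to_numpy(dtype=float)
    base_design = np.column_stack([np.ones_like(sub_age), sub_age])
    r2_age_only = _ols_r2(sub_pc2, base_design)
    for name in phenotypes:
        vals = table[name].to_numpy(dtype=float)
        if np.std(vals) == 0:
            logger.warning("excluding zero-variance phenotype %r from ranking", name)
            continue
        r_age = float(np.corrcoef(vals, age)[0, 1])
        if name == "pc2":
            r2 = 1.0
        else:
            design = np.column_stack([base_design, sub[name].to_numpy(dtype=float)])
            r2 = _ols_r2(sub_pc2, design) - r2_age_only
        rows.append({"phenotype": name, "r_age": r_age, "r2_pc2": r2})
    return pd.DataFrame(rows)


def rank_criteria(criteria: pd.DataFrame) -> pd.DataFrame:
    """Rank phenotypes on precomputed criteria (minimum-rank tie convention).

    ``rank_age`` orders by |r_age| descending; ``rank_pc2`` orders by
    ``r2_pc2`` descending, excluding PC2 itself; ``overall_rank`` orders by
    the rank sum.
    """
    if len(criteria) < 2:
        raise PhenotypeError("need at least 2 candidate phenotypes to rank")
    out = criteria.copy().reset_index(drop=True)
    out["rank_age"] = stats.rankdata(-np.abs(out["r_age"]), method="min").astype(int)
    eligible = out["phenotype"] != "pc2"
    rank_pc2 = np.full(len(out), np.nan)
    rank_pc2[eligible.to_numpy()] = stats.rankdata(
        -out.loc[eligible, "r2_pc2"], method="min"
    )
    out["rank_pc2"] = rank_pc2
    out["rank_sum"] = out["rank_age"] + out["rank_pc2"]
    finite = np.isfinite(out["rank_sum"])
    overall = np.full(len(out), np.nan)
    overall[finite.to_numpy()] = stats.rankdata(out.loc[finite, "rank_sum"], method="min")
    out["overall_rank"] = overall
    return out.sort_values(["overall_rank", "phenotype"], na_position="last").reset_index(
        drop=True
    )


def rank_phenotypes(
    table: pd.DataFrame,
    phenotypes: tuple[str, ...] = PHENOTYPE_COLUMNS,
    seed: int = 0,
) -> pd.DataFrame:
    """Compute criteria and rank in one step."""
    return rank_criteria(compute_ranking_criteria(table, phenotypes=phenotypes, seed=seed))


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across groups.

    Degenerate all-identical samples return (0, 1) rather than an error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise PhenotypeError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise PhenotypeError("empty group")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
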