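"""Repeated-measures extensions of the one-level analyses.

The daily panel is first decomposed exactly into grand mean + between-subject
effects (subject means minus the grand mean) + within-subject effects (daily
deviations from the subject mean).  A multilevel PCA separates the two levels
of covariance and provides low-rank representations, on which the two-block
PLS and joint/individual decompositions are rerun per level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .domain_models import JIVEModel, PLSModel, jive_fit, jive_rank_select, pls_fit
from .errors import ValidationError
from .feature_models import flip_to_positive
from .panel import FeaturePanel, ScaledPanel

_EXACT = 1e-10


# ---------------------------------------------------------------------------
# between/within decomposition
# ---------------------------------------------------------------------------

@dataclass
class MultilevelDecomposition:
    """Exact split of every observation into mean + between + within effects."""

    grand_mean: pd.Series                 # (P+Q)
    between: pd.DataFrame                 # n x (P+Q), one row per subject
    within: pd.DataFrame                  # N x (P+Q)
    subject_index: np.ndarray             # N, integer codes into `subjects`
    subjects: list
    n_days: pd.Series                     # days per subject
    pa_features: list[str]
    gait_features: list[str]
    sums_of_squares: pd.DataFrame         # columns: between, within, total

    @property
    def feature_names(self) -> list[str]:
        return list(self.pa_features) + list(self.gait_features)

    def reconstruct(self) -> np.ndarray:
        """mu + between[subject of row] + within[row], row by row."""
        B = self.between.to_numpy()
        W = self.within.to_numpy()
        return self.grand_mean.to_numpy() + B[self.subject_index] + W


def anova_decompose(panel: FeaturePanel | ScaledPanel) -> MultilevelDecomposition:
    """Empirical two-way-ANOVA-like decomposition of a (scaled) daily panel."""
    if isinstance(panel, ScaledPanel):
        panel = panel.panel
    feats = panel.feature_names
    df = panel.data
    Z = df[feats]
    mu = Z.mean()
    subj_means = df.groupby("subject", sort=True)[feats].mean()
    n_days = df.groupby("subject", sort=True).size()
    between = subj_means - mu
    within = (Z - subj_means.loc[df["subject"]].to_numpy()).reset_index(drop=True)
    subject_index = panel.subject_index()

    w = n_days.to_numpy()[:, None]
    ss_between = (w * between.to_numpy() ** 2).sum(axis=0)
    ss_within = (within.to_numpy() ** 2).sum(axis=0)
    ss_total = ((Z - mu).to_numpy() ** 2).sum(axis=0)
    ss = pd.DataFrame(
        {"between": ss_between, "within": ss_within, "total": ss_total}, index=feats
    )
    return MultilevelDecomposition(
        grand_mean=mu,
        between=between,
        within=within,
        subject_index=subject_index,
        subjects=list(subj_means.index),
        n_days=n_days,
        pa_features=list(panel.pa_features),
        gait_features=list(panel.gait_features),
        sums_of_squares=ss,
    )


# ---------------------------------------------------------------------------
# multilevel PCA
# ---------------------------------------------------------------------------

@dataclass
class MPCAModel:
    between_components: pd.DataFrame      # (P+Q) x k_b, orthonormal
    within_components: pd.DataFrame       # (P+Q) x k_w
    between_scores: np.ndarray            # n x k_b
    within_scores: np.ndarray             # N x k_w
    between_eigenvalues: np.ndarray       # full spectrum (clipped >= 0)
    within_eigenvalues: np.ndarray
    retained_fraction: float
    level_variance_fractions: dict[str, float]
    method: str


def _psd_clip(K: np.ndarray):
    K = (K + K.T) / 2.0
    vals, vecs = np.linalg.eigh(K)
    vals = np.clip(vals, 0.0, None)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def mpca_fit(
    decomp: MultilevelDecomposition,
    retained_fraction: float = 0.9,
    method: str = "moments",
) -> MPCAModel:
    """Separate between- and within-level covariance and reduce each level.

    method="moments": the between covariance is estimated from cross-day
    products within subject (averaged over ordered pairs j != k), which is
    unbiased even in the presence of day-level noise; the within covariance
    is the total covariance minus it.  Both are symmetrised and projected to
    the nearest positive-semidefinite matrix (negative eigenvalues clipped).

    method="empirical": PCA directly on the between/within effect matrices.
    """
    feats = decomp.feature_names
    D = len(feats)
    B = decomp.between.to_numpy()
    W = decomp.within.to_numpy()
    subject_index = decomp.subject_index
    n_days = decomp.n_days.to_numpy()
    N = int(n_days.sum())
    dev = B[subject_index] + W  # z - mu per row

    if method == "moments":
        eligible = n_days >= 2
        if not eligible.any():
            raise ValidationError(
                "between/within covariances are not separable by moments: "
                "every subject has a single day"
            )
        K_T = dev.T @ dev / N
        K_B = np.zeros((D, D))
        n_elig = 0
        offset = np.concatenate([[0], np.cumsum(n_days)])
        for i, ok in enumerate(eligible):
            if not ok:
                continue
            Di = dev[offset[i]:offset[i + 1]]
            Si = Di.sum(axis=0)
            ni = n_days[i]
            K_B += (np.outer(Si, Si) - Di.T @ Di) / (ni * (ni - 1))
            n_elig += 1
        K_B /= n_elig
        K_W = K_T - K_B
    elif method == "empirical":
        K_B = (B * n_days[:, None]).T @ B / N
        K_W = W.T @ W / N
    else:
        raise ValidationError(f"unknown MPCA method {method!r}")

    vals_b, vecs_b = _psd_clip(K_B)
    vals_w, vecs_w = _psd_clip(K_W)
    tr_b, tr_w = vals_b.sum(), vals_w.sum()

    def retain(vals: np.ndarray) -> int:
        tot = vals.sum()
        if tot <= 0:
            return 0
        cum = np.cumsum(vals) / tot
        return int(np.searchsorted(cum, retained_fraction - 1e-12) + 1)

    k_b, k_w = retain(vals_b), retain(vals_w)
    Vb = flip_to_positive(vecs_b[:, :k_b])
    Vw = flip_to_positive(vecs_w[:, :k_w])

    return MPCAModel(
        between_components=pd.DataFrame(Vb, index=feats, columns=[f"B{i+1}" for i in range(k_b)]),
        within_components=pd.DataFrame(Vw, index=feats, columns=[f"W{i+1}" for i in range(k_w)]),
        between_scores=B @ Vb,
        within_scores=W @ Vw,
        between_eigenvalues=vals_b,
        within_eigenvalues=vals_w,
        retained_fraction=retained_fraction,
        level_variance_fractions={
            "between": float(tr_b / (tr_b + tr_w)) if tr_b + tr_w > 0 else 0.0,
            "within": float(tr_w / (tr_b + tr_w)) if tr_b + tr_w > 0 else 0.0,
        },
        method=method,
    )


# ---------------------------------------------------------------------------
# multilevel PLS
# ---------------------------------------------------------------------------

def _split_blocks(M: np.ndarray, P: int) -> tuple[np.ndarray, np.ndarray]:
    return M[:, :P], M[:, P:]

def ml_pls(
    decomp: MultilevelDecomposition, n_components: int = 2
) -> tuple[PLSModel, PLSModel | None]:
    """Two-block PLS fitted separately on the between and within effects.

    Returns (between_model, within_model); if the within matrix is
    degenerate (all subjects single-day), the within fit is skipped with a
    warning and None is returned in its place.
    """
    P = len(decomp.pa_features)
    B = decomp.between.to_numpy()
    B = B - B.mean(axis=0)
    Xb, Yb = _split_blocks(B, P)
    between_model = pls_fit(
        Xb, Yb, n_components,
        x_names=decomp.pa_features, y_names=decomp.gait_features,
    )
    W = decomp.within.to_numpy()
    if np.sum(W**2) < _EXACT:
        warnings.warn(
            "within-subject matrix is (numerically) zero; skipping within-level PLS",
            stacklevel=2,
        )
        return between_model, None
    Xw, Yw = _split_blocks(W, P)
    within_model = pls_fit(
        Xw, Yw, n_components,
        x_names=decomp.pa_features, y_names=decomp.gait_features,
    )
    return between_model, within_model


# ---------------------------------------------------------------------------
# multilevel JIVE
# ---------------------------------------------------------------------------

@dataclass
class MultilevelJIVEModel:
    mpca: MPCAModel
    between_jive: JIVEModel
    within_jive: JIVEModel
    level_table: pd.DataFrame
    ranks: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    #: level -> denoised effects matrix the JIVE was fitted on (rows x (P+Q))
    representations: dict[str, np.ndarray] = field(default_factory=dict)


def _level_representation(scores: np.ndarray, components: pd.DataFrame) -> np.ndarray:
    return scores @ components.to_numpy().T


def ml_jive(
    decomp: MultilevelDecomposition,
    retained_fraction: float = 0.9,
    ranks_between="auto",
    ranks_within="auto",
    n_perm: int = 100,
    seed: int = 0,
    mpca_method: str = "moments",
    **jive_kwargs,
) -> MultilevelJIVEModel:
    """Two-step fit: MPCA level separation, then per-level JIVE.

    The joint/individual decomposition runs on the MPCA-denoised effect
    matrices (scores projected back to feature space) split into their PA and
    gait column blocks.  Rank triples may be given per level or selected by
    the permutation procedure.
    """
    mpca = mpca_fit(decomp, retained_fraction, method=mpca_method)
    P = len(decomp.pa_features)

    reps = {
        "between": _level_representation(mpca.between_scores, mpca.between_components),
        "within": _level_representation(mpca.within_scores, mpca.within_components),
    }
    models: dict[str, JIVEModel] = {}
    ranks: dict[str, tuple[int, int, int]] = {}
    for level, requested in (("between", ranks_between), ("within", ranks_within)):
        Xl = reps[level][:, :P].T
        Yl = reps[level][:, P:].T
        if requested == "auto":
            triple = jive_rank_select(Xl, Yl, n_perm=n_perm, seed=seed)
        else:
            triple = tuple(int(v) for v in requested)
        ranks[level] = triple
        models[level] = jive_fit(Xl, Yl, *triple, **jive_kwargs)

    level_table = _assemble_level_table(mpca, models)
    return MultilevelJIVEModel(
        mpca=mpca,
        between_jive=models["between"],
        within_jive=models["within"],
        level_table=level_table,
        ranks=ranks,
        representations=reps,
    )


def _assemble_level_table(mpca: MPCAModel, models: dict[str, JIVEModel]) -> pd.DataFrame:
    """Summary table: MPCA level split, then per-level JIVE fractions and
    per-domain shares (domain shares sum to 1 within each component)."""
    rows = {}
    rows["mpca_explained"] = {
        lvl: mpca.level_variance_fractions[lvl] for lvl in ("between", "within")
    }
    from .domain_models import variance_table

    for lvl, model in models.items():
        fr = model.variance_fractions()
        vt = variance_table(model)
        rows.setdefault("joint", {})[lvl] = fr["joint"]
        rows.setdefault("individual", {})[lvl] = fr["individual"]
        b1, b2 = model.block_names
        rows.setdefault(f"{b2}_joint_share", {})[lvl] = vt.loc[b2, "joint"]
        rows.setdefault(f"{b1}_joint_share", {})[lvl] = vt.loc[b1, "joint"]
        rows.setdefault(f"{b2}_individual_share", {})[lvl] = vt.loc[b2, "individual"]
        rows.setdefault(f"{b1}_individual_share", {})[lvl] = vt.loc[b1, "individual"]
    return pd.DataFrame(rows).T[["between", "within"]]


# ---------------------------------------------------------------------------
# score-feature correlation report
# ---------------------------------------------------------------------------

@dataclass
class LevelCorrelations:
    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame


def _safe_corr_with_p(F: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = F.shape[0]
    Fc = F - F.mean(axis=0)
    Sc = S - S.mean(axis=0)
    fs = np.sqrt(np.sum(Fc**2, axis=0))
    ss = np.sqrt(np.sum(Sc**2, axis=0))
    denom = np.outer(fs, ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, Fc.T @ Sc / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return r, p


def score_feature_correlations(
    model: MultilevelJIVEModel,
    decomp: MultilevelDecomposition,
    alpha: float = 0.05,
) -> dict[str, LevelCorrelations]:
    """Correlate each feature's level effect with every JIVE score vector.

    Per level the score columns are the joint scores followed by each block's
    individual scores; p-values come from the two-sided t test at that
    level's sample size, starred at ``alpha``.
    """
    out = {}
    for level, jive, effects in (
        ("between", model.between_jive, decomp.between.to_numpy()),
        ("within", model.within_jive, decomp.within.to_numpy()),
    ):
        cols, names = [], []
        for k in range(jive.r):
            cols.append(jive.joint_scores[k])
            names.append(f"joint_{k + 1}")
        for block in jive.block_names:
            S = jive.individual_scores[block]
            for k in range(S.shape[0]):
                cols.append(S[k])
                names.append(f"{block}_ind_{k + 1}")
        S = np.array(cols).T if cols else np.zeros((effects.shape[0], 0))
        r, p = _safe_corr_with_p(effects, S)
        feats = decomp.feature_names
        out[level] = LevelCorrelations(
            r=pd.DataFrame(r, index=feats, columns=names),
            p=pd.DataFrame(p, index=feats, columns=names),
            mask=pd.DataFrame(p < alpha, index=feats, columns=names),
        )
    return out


# ---------------------------------------------------------------------------
# cross-model component comparison
# ---------------------------------------------------------------------------

@dataclass
class ScoreSet:
    """A named set of component score vectors at a known grain."""

    label: str
    scores: np.ndarray           # rows x k
    grain: str                   # "subject" | "observation"
    subject_ids: list            # one id per row


def compare_components(score_sets: list[ScoreSet], n_components: int = 2) -> pd.DataFrame:
    """Pairwise Pearson correlations between models' leading components.

    Observation-grain scores are averaged per subject before comparison, so
    every column lives on the common subject grain.  Signed correlations are
    returned; take absolute values for a sign-free view.
    """
    aligned: dict[str, np.ndarray] = {}
    ref_subjects: list | None = None
    for ss in score_sets:
        df = pd.DataFrame(np.asarray(ss.scores, float))
        df["__subject"] = list(ss.subject_ids)
        agg = df.groupby("__subject", sort=True).mean()
        if ref_subjects is None:
            ref_subjects = list(agg.index)
        elif list(agg.index) != ref_subjects:
            raise ValidationError(
                f"score set {ss.label!r} covers different subjects than the others"
            )
        k = min(n_components, agg.shape[1])
        for j in range(k):
            aligned[f"{ss.label}.PC{j + 1}"] = agg.iloc[:, j].to_numpy()
    mat = pd.DataFrame(aligned)
    return mat.corr(method="pearson")
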