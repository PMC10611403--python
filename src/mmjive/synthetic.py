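"""Synthetic two-block repeated-measures panels with planted low-rank structure.

The generator is the forward model of the between/within decomposition used by
the multilevel analyses: each observation is

    z_ij = mu + u_i + w_ij + eps_ij

where the between-subject effect ``u_i`` and the within-subject effect
``w_ij`` each split into a *joint* low-rank part whose loadings span both
feature blocks and block-specific *individual* parts, and ``eps`` is white
noise.  Loadings are orthonormal; all magnitude is carried by scores, whose
columns are orthogonalised in the expanded (row-replicated) space so the
requested variance fractions are realised essentially exactly.  Individual
scores are projected off the joint scores at each level, mirroring the
row-orthogonality constraint of the joint/individual decomposition that the
downstream estimators enforce.  Within-level scores are i.i.d. across days
(not per-subject centered), so the empirical between-subject effects of the
generated panel carry the usual within-leakage of order 1/n_days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import SpecError, ValidationError
from .features import GAIT_FEATURES, PA_FEATURES
from .panel import DAY_COL, SUBJECT_COL, FeaturePanel, SubjectMeansMatrix


# ---------------------------------------------------------------------------
# specification / truth containers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    Variance fractions refer to the *signal* (noise is on top): ``var_between``
    is the between-level share of total signal variance; ``var_joint_b`` /
    ``var_joint_w`` are the joint shares of each level's signal.  Per-feature
    average signal variance is 1, so ``noise_sd`` is on the z-scale.
    """

    n_subjects: int = 65
    days_mean: float = 8.78
    days_sd: float = 1.86
    P: int = 13
    Q: int = 11
    r_b: int = 1
    r1_b: int = 2
    r2_b: int = 2
    r_w: int = 1
    r1_w: int = 2
    r2_w: int = 2
    var_between: float = 0.5
    var_joint_b: float = 0.5
    var_joint_w: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0
    #: optional (PA, gait) split of the joint energy across blocks; default
    #: leaves it to the random orthonormal loadings (roughly P:Q)
    joint_block_split: tuple[float, float] | None = None
    #: (PA, gait) split of the individual-signal energy
    ind_block_split: tuple[float, float] = (0.5, 0.5)
    #: reuse the between-level joint loadings at the within level (useful for
    #: planting the same cross-domain direction at both levels)
    shared_joint_loadings: bool = False

    def validate(self) -> None:
        D = self.P + self.Q
        if self.n_subjects < 1 or self.P < 1 or self.Q < 1:
            raise SpecError("n_subjects, P and Q must be positive")
        for name in ("r_b", "r1_b", "r2_b", "r_w", "r1_w", "r2_w"):
            if getattr(self, name) < 0:
                raise SpecError(f"rank {name} must be >= 0")
        if self.r_b + max(self.r1_b, self.r2_b) > min(self.n_subjects, D):
            raise SpecError("between-level ranks infeasible for n_subjects and P+Q")
        # the generator plants mutually orthogonal score columns, which needs
        # room in the centered subject space
        if self.r_b + self.r1_b + self.r2_b > self.n_subjects - 1:
            raise SpecError(
                "between-level ranks infeasible: generator requires "
                "r_b + r1_b + r2_b <= n_subjects - 1"
            )
        if self.r1_b > self.P or self.r1_w > self.P:
            raise SpecError("PA individual rank exceeds block width P")
        if self.r2_b > self.Q or self.r2_w > self.Q:
            raise SpecError("gait individual rank exceeds block width Q")
        for name in ("var_between", "var_joint_b", "var_joint_w"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SpecError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        for split in (self.joint_block_split, self.ind_block_split):
            if split is not None:
                if len(split) != 2 or min(split) < 0 or abs(sum(split) - 1) > 1e-12:
                    raise SpecError(f"block split must be two nonnegative shares summing to 1, got {split}")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for recovery testing.

    ``components`` holds the expanded (one row per observation) matrices of
    every planted part; score/loading matrices per level and block are kept
    alongside.  ``realized_fractions`` are exact sums of squares of each
    component over the total.
    """

    spec: SyntheticSpec
    subjects: list
    subject_index: np.ndarray
    pa_features: list[str]
    gait_features: list[str]
    components: dict[str, np.ndarray]
    loadings: dict[str, np.ndarray] = field(default_factory=dict)
    scores: dict[str, np.ndarray] = field(default_factory=dict)
    realized_fractions: dict[str, float] = field(default_factory=dict)


def default_feature_names(P: int, Q: int) -> tuple[list[str], list[str]]:
    """Realistic names when the block widths match the shipped catalogue."""
    if P == len(PA_FEATURES) and Q == len(GAIT_FEATURES):
        return list(PA_FEATURES), list(GAIT_FEATURES)
    return (
        [f"pa_{i + 1:02d}" for i in range(P)],
        [f"gait_{i + 1:02d}" for i in range(Q)],
    )


# ---------------------------------------------------------------------------
# internal linear-algebra helpers
# ---------------------------------------------------------------------------

def _orthonormal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """Random matrix with orthonormal columns (empty-safe)."""
    if cols == 0:
        return np.zeros((rows, 0))
    q, _ = np.linalg.qr(rng.standard_normal((rows, cols)))
    return q[:, :cols]


def _joint_loadings(rng, P, Q, r, split):
    """Orthonormal (P+Q) x r loadings spanning both blocks.

    With an explicit split each column carries exactly ``split`` of its energy
    per block (per-block pieces orthonormal, scaled by sqrt(share)).
    """
    if r == 0:
        return np.zeros((P + Q, 0))
    if split is None:
        return _orthonormal(rng, P + Q, r)
    a = _orthonormal(rng, P, r) * np.sqrt(split[0])
    b = _orthonormal(rng, Q, r) * np.sqrt(split[1])
    return np.vstack([a, b])


def _block_loadings(rng, P, Q, r, block: str) -> np.ndarray:
    """Loadings orthonormal inside one block, zero in the other."""
    L = np.zeros((P + Q, r))
    if r == 0:
        return L
    if block == "PA":
        L[:P, :] = _orthonormal(rng, P, r)
    else:
        L[P:, :] = _orthonormal(rng, Q, r)
    return L


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0, keepdims=True) if M.size else M


def _orth_scores(
    rng: np.random.Generator,
    n_rows: int,
    r: int,
    ss_total: float,
    *,
    centerer,
    project_off: np.ndarray | None = None,
    base: np.ndarray | None = None,
) -> np.ndarray:
    """Score matrix with orthogonal columns of equal squared norm ss_total/r.

    ``centerer`` maps a raw Gaussian draw to the right subspace (global or
    per-subject centering); ``project_off`` removes the span of earlier score
    columns so planted structures are exactly orthogonal.
    """
    if r == 0:
        return np.zeros((n_rows, 0))
    G = base if base is not None else rng.standard_normal((n_rows, r))
    G = centerer(G)
    if project_off is not None and project_off.shape[1] > 0:
        norms = np.linalg.norm(project_off, axis=0)
        keep = norms > 0
        if keep.any():
            Qb = project_off[:, keep] / norms[keep]
            G = G - Qb @ (Qb.T @ G)
    Qm, _ = np.linalg.qr(G)
    Qm = Qm[:, :r]
    return Qm * np.sqrt(ss_total / r)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _draw_day_counts(rng, spec) -> np.ndarray:
    raw = np.round(rng.normal(spec.days_mean, spec.days_sd, spec.n_subjects))
    return np.maximum(raw, 1).astype(int)


def simulate_multilevel(spec: SyntheticSpec) -> tuple[FeaturePanel, SyntheticTruth]:
    """Generate a daily panel with planted between/within joint+individual structure."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    P, Q, D = spec.P, spec.Q, spec.P + spec.Q
    n = spec.n_subjects
    n_days = _draw_day_counts(rng, spec)
    N = int(n_days.sum())
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    subject_index = np.repeat(np.arange(n), n_days)

    if spec.r_w + spec.r1_w + spec.r2_w > 0 and (
        spec.r_w + max(spec.r1_w, spec.r2_w) > min(N - n, D)
        or spec.r_w + spec.r1_w + spec.r2_w > N - 1
    ):
        raise SpecError(
            "within-level ranks infeasible for the sampled day counts: need "
            f"r_w + max(r1_w, r2_w) <= min(N - n, P+Q) = {min(N - n, D)} and "
            f"r_w + r1_w + r2_w <= N - 1 = {N - 1}"
        )

    # loadings ------------------------------------------------------------
    L_jb = _joint_loadings(rng, P, Q, spec.r_b, spec.joint_block_split)
    L1_b = _block_loadings(rng, P, Q, spec.r1_b, "PA")
    L2_b = _block_loadings(rng, P, Q, spec.r2_b, "gait")
    if spec.shared_joint_loadings and spec.r_w == spec.r_b:
        L_jw = L_jb
    else:
        L_jw = _joint_loadings(rng, P, Q, spec.r_w, spec.joint_block_split)
    L1_w = _block_loadings(rng, P, Q, spec.r1_w, "PA")
    L2_w = _block_loadings(rng, P, Q, spec.r2_w, "gait")

    # SS budget: total signal SS = N * D (per-feature average variance 1)
    ss_total = N * D
    ss_b = spec.var_between * ss_total
    ss_w = (1.0 - spec.var_between) * ss_total
    ss = {
        "bj": ss_b * spec.var_joint_b if spec.r_b else 0.0,
        "b1": ss_b * (1 - spec.var_joint_b) * spec.ind_block_split[0] if spec.r1_b else 0.0,
        "b2": ss_b * (1 - spec.var_joint_b) * spec.ind_block_split[1] if spec.r2_b else 0.0,
        "wj": ss_w * spec.var_joint_w if spec.r_w else 0.0,
        "w1": ss_w * (1 - spec.var_joint_w) * spec.ind_block_split[0] if spec.r1_w else 0.0,
        "w2": ss_w * (1 - spec.var_joint_w) * spec.ind_block_split[1] if spec.r2_w else 0.0,
    }

    # scores, in the expanded N-row space.  Between scores are constant
    # within subject (drawn per subject, expanded, then orthogonalised by
    # column operations which preserve that constancy).  Within scores are
    # i.i.d. across days (globally centered), matching the population model
    # z = mu + u_i + w_ij assumed by the level-separation estimators.
    def center_between(G):
        return _center(G)

    def center_within(G):
        return _center(G)

    Ub = _orth_scores(
        rng, N, spec.r_b, ss["bj"], centerer=center_between,
        base=rng.standard_normal((n, spec.r_b))[subject_index] if spec.r_b else None,
    )
    U1 = _orth_scores(
        rng, N, spec.r1_b, ss["b1"], centerer=center_between, project_off=Ub,
        base=rng.standard_normal((n, spec.r1_b))[subject_index] if spec.r1_b else None,
    )
    U2 = _orth_scores(
        rng, N, spec.r2_b, ss["b2"], centerer=center_between,
        project_off=np.hstack([Ub, U1]),
        base=rng.standard_normal((n, spec.r2_b))[subject_index] if spec.r2_b else None,
    )
    Wj = _orth_scores(rng, N, spec.r_w, ss["wj"], centerer=center_within)
    W1 = _orth_scores(rng, N, spec.r1_w, ss["w1"], centerer=center_within, project_off=Wj)
    W2 = _orth_scores(
        rng, N, spec.r2_w, ss["w2"], centerer=center_within,
        project_off=np.hstack([Wj, W1]),
    )

    components = {
        "between_joint": Ub @ L_jb.T,
        "between_individual": U1 @ L1_b.T + U2 @ L2_b.T,
        "within_joint": Wj @ L_jw.T,
        "within_individual": W1 @ L1_w.T + W2 @ L2_w.T,
        "noise": spec.noise_sd * rng.standard_normal((N, D)),
    }
    Z = sum(components.values())

    pa_names, gait_names = default_feature_names(P, Q)
    day_idx = np.concatenate([np.arange(1, k + 1) for k in n_days])
    df = pd.DataFrame(Z, columns=pa_names + gait_names)
    df.insert(0, DAY_COL, day_idx)
    df.insert(0, SUBJECT_COL, np.asarray(subjects)[subject_index])
    panel = FeaturePanel(df, pa_names, gait_names)

    # expanded rows are constant within subject; first row per subject gives
    # the subject-level score matrices
    first = np.searchsorted(subject_index, np.arange(n))
    truth = SyntheticTruth(
        spec=spec,
        subjects=subjects,
        subject_index=subject_index,
        pa_features=pa_names,
        gait_features=gait_names,
        components=components,
        loadings={
            "between_joint": L_jb, "between_ind_PA": L1_b, "between_ind_gait": L2_b,
            "within_joint": L_jw, "within_ind_PA": L1_w, "within_ind_gait": L2_w,
        },
        scores={
            "between_joint": Ub[first], "between_ind_PA": U1[first],
            "between_ind_gait": U2[first],
            "within_joint": Wj, "within_ind_PA": W1, "within_ind_gait": W2,
        },
    )
    truth.realized_fractions = _realized_fractions(Z, components)
    return panel, truth


def simulate_one_level(spec: SyntheticSpec) -> tuple[SubjectMeansMatrix, SyntheticTruth]:
    """Generate a single-level two-block matrix with planted ranks (r, r1, r2).

    Uses the between-level rank fields (r_b, r1_b, r2_b) and ``var_joint_b``
    as the joint share of the signal.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    P, Q, D = spec.P, spec.Q, spec.P + spec.Q
    n = spec.n_subjects

    L_j = _joint_loadings(rng, P, Q, spec.r_b, spec.joint_block_split)
    L1 = _block_loadings(rng, P, Q, spec.r1_b, "PA")
    L2 = _block_loadings(rng, P, Q, spec.r2_b, "gait")

    ss_total = n * D
    ss_j = ss_total * spec.var_joint_b if spec.r_b else 0.0
    ss_1 = ss_total * (1 - spec.var_joint_b) * spec.ind_block_split[0] if spec.r1_b else 0.0
    ss_2 = ss_total * (1 - spec.var_joint_b) * spec.ind_block_split[1] if spec.r2_b else 0.0

    S_j = _orth_scores(rng, n, spec.r_b, ss_j, centerer=_center)
    S_1 = _orth_scores(rng, n, spec.r1_b, ss_1, centerer=_center, project_off=S_j)
    S_2 = _orth_scores(
        rng, n, spec.r2_b, ss_2, centerer=_center, project_off=np.hstack([S_j, S_1])
    )

    components = {
        "joint": S_j @ L_j.T,
        "individual": S_1 @ L1.T + S_2 @ L2.T,
        "noise": spec.noise_sd * rng.standard_normal((n, D)),
    }
    Z = sum(components.values())

    pa_names, gait_names = default_feature_names(P, Q)
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    values = pd.DataFrame(Z, columns=pa_names + gait_names, index=pd.Index(subjects, name=SUBJECT_COL))
    means = SubjectMeansMatrix(values, pa_names, gait_names)

    truth = SyntheticTruth(
        spec=spec,
        subjects=subjects,
        subject_index=np.arange(n),
        pa_features=pa_names,
        gait_features=gait_names,
        components=components,
        loadings={"joint": L_j, "ind_PA": L1, "ind_gait": L2},
        scores={"joint": S_j, "ind_PA": S_1, "ind_gait": S_2},
    )
    truth.realized_fractions = _realized_fractions(Z, components)
    return means, truth


def _realized_fractions(Z: np.ndarray, components: dict[str, np.ndarray]) -> dict[str, float]:
    # component energy shares; cross terms between levels (random, O(1/sqrt(N)))
    # are excluded so requested fractions are realised deterministically
    total = float(sum(np.sum(v * v) for v in components.values()))
    if total == 0.0:
        return {k: 0.0 for k in components}
    out = {k: float(np.sum(v * v)) / total for k, v in components.items()}
    if "between_joint" in components:
        b = out["between_joint"] + out["between_individual"]
        w = out["within_joint"] + out["within_individual"]
        out["between"] = b
        out["within"] = w
        out["joint_frac_between"] = out["between_joint"] / b if b > 0 else 0.0
        out["joint_frac_within"] = out["within_joint"] / w if w > 0 else 0.0
    return out


def empirical_variance_report(data, truth: SyntheticTruth) -> pd.DataFrame:
    """Realized vs requested variance fractions for a generator output pair.

    Fractions are sums of squares of each planted component over the total
    sum of squares of the generated values.  Requested totals account for the
    noise floor analytically: per-feature signal variance is 1 and noise adds
    ``noise_sd**2``, so every signal fraction is deflated by 1/(1+noise_sd^2).
    """
    if isinstance(data, FeaturePanel):
        Z = data.values()
    elif isinstance(data, SubjectMeansMatrix):
        Z = data.all_values()
    else:
        Z = np.asarray(data, dtype=float)
    any_comp = next(iter(truth.components.values()))
    if Z.shape != any_comp.shape:
        raise ValidationError(
            f"data shape {Z.shape} does not match truth components {any_comp.shape}"
        )
    spec = truth.spec
    denom = 1.0 + spec.noise_sd**2
    if "joint" in truth.components:  # one-level
        requested = {
            "joint": (spec.var_joint_b if spec.r_b else 0.0) / denom,
            "individual": (
                (1 - spec.var_joint_b)
                * ((spec.ind_block_split[0] if spec.r1_b else 0.0)
                   + (spec.ind_block_split[1] if spec.r2_b else 0.0))
            ) / denom,
            "noise": spec.noise_sd**2 / denom,
        }
    else:
        vb, vw = spec.var_between, 1 - spec.var_between
        requested = {
            "between_joint": vb * (spec.var_joint_b if spec.r_b else 0.0) / denom,
            "between_individual": vb * (1 - spec.var_joint_b) * (
                (spec.ind_block_split[0] if spec.r1_b else 0.0)
                + (spec.ind_block_split[1] if spec.r2_b else 0.0)
            ) / denom,
            "within_joint": vw * (spec.var_joint_w if spec.r_w else 0.0) / denom,
            "within_individual": vw * (1 - spec.var_joint_w) * (
                (spec.ind_block_split[0] if spec.r1_w else 0.0)
                + (spec.ind_block_split[1] if spec.r2_w else 0.0)
            ) / denom,
            "noise": spec.noise_sd**2 / denom,
        }
    total = float(sum(np.sum(v**2) for v in truth.components.values()))
    rows = []
    for comp, req in requested.items():
        realized = float(np.sum(truth.components[comp] ** 2)) / total if total > 0 else 0.0
        rows.append({"component": comp, "requested": req, "realized": realized})
    return pd.DataFrame(rows)
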