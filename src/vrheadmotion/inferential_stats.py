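"""Factorial self-report statistics: repeated-measures ANOVA and correlations.

``rm_anova`` implements the classical univariate mixed-model ANOVA for
*balanced complete* within-subject factorial data, optionally with
between-subjects factors (used here for the sex/order moderation screens).
Each within effect E (including its interactions with between factors) is
tested against its interaction with subjects nested in groups, E x S(B);
between effects are tested against subjects-within-groups S(B).  Effect sizes
are partial eta squared, SS_effect / (SS_effect + SS_error).

Sums of squares are computed by Moebius (inclusion-exclusion) differencing of
marginal means, which is exact for balanced data.  When between-subjects
group sizes are unequal (e.g. 52 participants over 16 order levels), the
unweighted-means solution is used: cell means are averaged per group and the
harmonic mean group size serves as the replication factor.

No sphericity correction is applied by default (plain degrees of freedom are
reported); a Greenhouse-Geisser correction is available behind
``correction="gg"``.  No multiple-testing correction is applied anywhere: raw
p-values are reported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conformity import ConformityScore
from .errors import InferenceError
from .io_formats import AXES, LAP_SPEEDS, TrialRecord, trial_records_frame

logger = logging.getLogger(__name__)

#: dependent measures of the association table, in report order
ASSOCIATION_MEASURES = (
    ("vection", "vection_magnitude"),
    ("sickness", "sickness"),
    ("presence", "presence"),
)


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p_sq: float
    ss_effect: float
    ss_error: float
    gg_epsilon: float | None = None
    p_gg: float | None = None


@dataclass
class AssociationResult:
    r: float
    p: float
    n: int
    degenerate: bool = False


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels-1) x levels orthonormal rows spanning the complement of the mean."""
    basis = np.hstack([np.ones((levels, 1)) / np.sqrt(levels), np.eye(levels)])
    q, _ = np.linalg.qr(basis)
    return q[:, 1:levels].T


def _moebius_estimate(M: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Inclusion-exclusion effect estimate for the effect spanned by ``axes``.

    ``M`` is the full cell-mean tensor; the result has M's shape (broadcast),
    containing for each cell the estimated pure effect of the given axes.
    """
    all_axes = tuple(range(M.ndim))
    est = np.zeros_like(M)
    k = len(axes)
    for r in range(k + 1):
        for keep in itertools.combinations(axes, r):
            drop = tuple(a for a in all_axes if a not in keep)
            term = M.mean(axis=drop, keepdims=True) if drop else M
            est = est + ((-1) ** (k - r)) * term
    return est


def rm_anova(
    data: pd.DataFrame | Sequence[TrialRecord],
    dv: str,
    within: Sequence[str],
    between: Sequence[str] = (),
    subject: str = "participant_id",
    correction: str | None = None,
) -> pd.DataFrame:
    """Within-subjects (optionally mixed) factorial ANOVA on balanced data.

    Returns one row per effect with F, df, p, and partial eta squared.
    ``correction="gg"`` adds Greenhouse-Geisser epsilon and corrected p for
    within effects.  Missing cells raise an InferenceError naming the
    participant and cell; non-integer dv values are accepted with a warning.
    """
    if not isinstance(data, pd.DataFrame):
        data = trial_records_frame(data)
    within = list(within)
    between = list(between)
    cols = [subject, *within, *between, dv]
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise InferenceError(f"missing columns in trial table: {missing_cols}")
    df = data[cols].copy()
    if df[dv].isna().any():
        raise InferenceError(f"missing {dv} values")
    if not np.allclose(df[dv].astype(float) % 1, 0):
        logger.warning("non-integer %s values supplied to rm_anova; proceeding", dv)

    subjects = sorted(df[subject].unique())
    w_levels = [sorted(df[f].unique()) for f in within]
    w_shape = tuple(len(l) for l in w_levels)
    w_total = int(np.prod(w_shape))

    # completeness: every subject x within-cell exactly once
    counts = df.groupby([subject, *within], sort=True)[dv].count()
    for s in subjects:
        for cell in itertools.product(*w_levels):
            key = (s, *cell) if within else s
            c = counts.get(key, 0)
            if c != 1:
                raise InferenceError(
                    f"participant {s!r}, cell {dict(zip(within, cell))} has "
                    f"{c} observations (expected exactly 1)"
                )

    # between factors must be constant per subject
    group_of = {}
    if between:
        b_levels = [sorted(df[f].unique()) for f in between]
        per_subj = df.groupby(subject)[between].nunique()
        bad = per_subj[(per_subj > 1).any(axis=1)]
        if len(bad):
            raise InferenceError(
                f"between factors vary within participant {bad.index[0]!r}"
            )
        first = df.groupby(subject)[between].first()
        for s in subjects:
            group_of[s] = tuple(first.loc[s, f] for f in between)
        b_shape = tuple(len(l) for l in b_levels)
        group_cells = list(itertools.product(*b_levels))
        present = set(group_of.values())
        absent = [g for g in group_cells if g not in present]
        if absent:
            raise InferenceError(f"empty between-subjects cell {absent[0]}")
    else:
        b_levels, b_shape, group_cells = [], (), [()]
        for s in subjects:
            group_of[s] = ()

    # Y[s, w1, ..., wk]
    pivot = df.set_index([subject, *within])[dv].astype(float)
    Y = np.empty((len(subjects), *w_shape))
    for si, s in enumerate(subjects):
        for idx, cell in zip(itertools.product(*(range(n) for n in w_shape)),
                             itertools.product(*w_levels)):
            key = (s, *cell) if within else s
            Y[(si, *idx)] = pivot.loc[key]

    groups = {g: [si for si, s in enumerate(subjects) if group_of[s] == g]
              for g in group_cells}
    n_per_group = {g: len(m) for g, m in groups.items()}
    n_subj, n_groups = len(subjects), len(group_cells)
    if min(n_per_group.values()) < 1:
        raise InferenceError("every between-subjects cell needs at least one subject")
    n_tilde = n_groups / sum(1.0 / n for n in n_per_group.values())  # harmonic mean
    if len(set(n_per_group.values())) > 1:
        logger.warning(
            "unequal between-group sizes %s: using the unweighted-means solution",
            sorted(n_per_group.values()),
        )

    # group-mean tensor M[b1, ..., bm, w1, ..., wk]
    M = np.empty((*b_shape, *w_shape)) if between else np.empty((1, *w_shape))
    for gi, g in enumerate(group_cells):
        idx = tuple(b_levels[j].index(g[j]) for j in range(len(between))) if between else (0,)
        M[idx] = Y[groups[g]].mean(axis=0)

    n_b_axes = len(between) if between else 1
    df_sb = n_subj - n_groups if between else n_subj - 1
    if df_sb < 1:
        raise InferenceError("no residual subject degrees of freedom")

    # subjects-within-groups error
    subj_means = Y.reshape(n_subj, -1).mean(axis=1)
    grp_mean_of_subj = np.array(
        [subj_means[groups[group_of[subjects[si]]]].mean() for si in range(n_subj)]
    )
    ss_sb = w_total * float(np.sum((subj_means - grp_mean_of_subj) ** 2))

    def within_error(E_axes_w: tuple[int, ...]) -> tuple[float, int]:
        """SS and df of E x S(B) for the within effect over within-axis indices."""
        keep = tuple(1 + a for a in E_axes_w)  # axes of Y, axis 0 = subject
        drop = tuple(a for a in range(1, Y.ndim) if a not in keep)
        A = Y.mean(axis=drop) if drop else Y  # (n_subj, |E| cells...)
        Abar = np.empty_like(A)
        for g, members in groups.items():
            Abar[members] = A[members].mean(axis=0)
        eff_axes = tuple(range(1, A.ndim))
        D = np.zeros_like(A)
        k = len(eff_axes)
        for r in range(k + 1):
            for keep2 in itertools.combinations(eff_axes, r):
                drop2 = tuple(a for a in eff_axes if a not in keep2)
                tA = A.mean(axis=drop2, keepdims=True) if drop2 else A
                tB = Abar.mean(axis=drop2, keepdims=True) if drop2 else Abar
                D = D + ((-1) ** (k - r)) * (tA - tB)
        e_cells = int(np.prod([w_shape[a] for a in E_axes_w]))
        ss = (w_total / e_cells) * float(np.sum(D ** 2))
        df_e = int(np.prod([w_shape[a] - 1 for a in E_axes_w]))
        return ss, df_e * df_sb

    def effect_ss(H_idx: tuple[int, ...], E_idx: tuple[int, ...]) -> tuple[float, int]:
        axes = tuple(H_idx) + tuple(n_b_axes + a for a in E_idx)
        est = _moebius_estimate(M, axes)
        ss = n_tilde * float(np.sum(est ** 2))
        df_num = 1
        for j in H_idx:
            df_num *= len(b_levels[j]) - 1
        for a in E_idx:
            df_num *= w_shape[a] - 1
        return ss, df_num

    # Greenhouse-Geisser machinery (within effects only)
    def gg_epsilon(E_idx: tuple[int, ...]) -> float:
        C = np.ones((1, 1))
        for a in range(len(within)):
            L = w_shape[a]
            block = _orthonormal_contrasts(L) if a in E_idx else np.full((1, L), 1.0 / L)
            C = np.kron(C, block)
        Z = Y.reshape(n_subj, w_total) @ C.T
        Zc = np.empty_like(Z)
        for g, members in groups.items():
            Zc[members] = Z[members] - Z[members].mean(axis=0)
        S = Zc.T @ Zc / df_sb
        q = S.shape[0]
        tr, tr2 = np.trace(S), float(np.sum(S * S))
        if tr2 <= 0:
            return 1.0
        return float(np.clip(tr ** 2 / (q * tr2), 1.0 / q, 1.0))

    rows: list[AnovaResult] = []

    def f_test(name, ss_eff, df_num, ss_err, df_den, eps=None):
        if ss_err <= 0 or df_den <= 0:
            F = 0.0 if ss_eff <= 0 else float("inf")
            p = 1.0 if ss_eff <= 0 else 0.0
        else:
            F = (ss_eff / df_num) / (ss_err / df_den)
            p = float(stats.f.sf(F, df_num, df_den))
        eta = 0.0 if (ss_eff + ss_err) == 0 else ss_eff / (ss_eff + ss_err)
        res = AnovaResult(
            effect=name,
            F=float(F),
            df_num=df_num,
            df_den=df_den,
            p=p,
            eta_p_sq=float(eta),
            ss_effect=float(ss_eff),
            ss_error=float(ss_err),
        )
        if eps is not None:
            res.gg_epsilon = eps
            res.p_gg = float(stats.f.sf(res.F, eps * df_num, eps * df_den)) if np.isfinite(res.F) else res.p
        rows.append(res)

    # between main effects and interactions
    for k in range(1, len(between) + 1):
        for H_idx in itertools.combinations(range(len(between)), k):
            name = ":".join(between[j] for j in H_idx)
            ss_eff, df_num = effect_ss(H_idx, ())
            f_test(name, ss_eff, df_num, ss_sb, df_sb)

    # within effects and their between interactions
    for k in range(1, len(within) + 1):
        for E_idx in itertools.combinations(range(len(within)), k):
            ss_err, df_den = within_error(E_idx)
            eps = gg_epsilon(E_idx) if correction == "gg" else None
            name_w = ":".join(within[a] for a in E_idx)
            ss_eff, df_num = effect_ss((), E_idx)
            f_test(name_w, ss_eff, df_num, ss_err, df_den, eps)
            for kb in range(1, len(between) + 1):
                for H_idx in itertools.combinations(range(len(between)), kb):
                    name = ":".join(between[j] for j in H_idx) + ":" + name_w
                    ss_eff, df_num = effect_ss(H_idx, E_idx)
                    f_test(name, ss_eff, df_num, ss_err, df_den, eps)

    out = pd.DataFrame([vars(r) for r in rows])
    if correction != "gg":
        out = out.drop(columns=["gg_epsilon", "p_gg"])
    return out


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def pearson_assoc(x: Iterable[float], y: Iterable[float]) -> AssociationResult:
    """Pearson r with a two-tailed p; constant input flags a degenerate result."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise InferenceError("x and y must be paired")
    n = x.size
    if n < 3:
        raise InferenceError(f"pearson_assoc needs n >= 3, got {n}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return AssociationResult(r=float("nan"), p=float("nan"), n=n, degenerate=True)
    r, p = stats.pearsonr(x, y)
    return AssociationResult(r=float(r), p=float(p), n=n)


def analysis_condition_mask(frame: pd.DataFrame) -> pd.Series:
    """Lap trials from the typical upright, world-aligned, forward-facing view.

    These are the Experiment 1 upright-aligned laps and the Experiment 2
    forward laps: the condition replicated exactly in both experiments, on
    which the combined head-motion analysis operates.
    """
    lap = frame["speed"].isin(LAP_SPEEDS)
    exp1 = (
        (frame["experiment"] == 1)
        & (frame["posture"] == "upright")
        & (frame["alignment"] == "aligned")
    )
    exp2 = (frame["experiment"] == 2) & (frame["direction"] == "forward")
    return lap & (exp1 | exp2)


def conformity_association_table(
    scores: Sequence[ConformityScore],
    records: pd.DataFrame | Sequence[TrialRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate conformity with ratings: one row per measure x axis x speed.

    Ratings are taken from each participant's matching upright/aligned/forward
    lap trial at the same speed.  Rows built from fewer than 3 joinable pairs
    are flagged ``insufficient_n`` and carry NaN statistics.
    """
    if not isinstance(records, pd.DataFrame):
        records = trial_records_frame(records)
    ratings = records[analysis_condition_mask(records)]
    score_df = pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "axis": s.axis,
                "speed": s.speed_condition,
                "score": s.r,
            }
            for s in scores
            if not s.degenerate
        ]
    )
    rows = []
    for label, column in ASSOCIATION_MEASURES:
        for speed in LAP_SPEEDS:
            rated = ratings[ratings["speed"] == speed][["participant_id", column]]
            for axis in AXES:
                cell = score_df[(score_df.axis == axis) & (score_df.speed == speed)]
                joined = cell.merge(rated, on="participant_id", how="inner").dropna()
                row = {
                    "measure": label,
                    "speed_condition": speed,
                    "axis": axis,
                    "n": len(joined),
                }
                if len(joined) < 3:
                    row.update(r=float("nan"), p=float("nan"),
                               significant=False, insufficient_n=True)
                else:
                    assoc = pearson_assoc(joined["score"], joined[column])
                    row.update(
                        r=assoc.r,
                        p=assoc.p,
                        significant=bool((not assoc.degenerate) and assoc.p < alpha),
                        insufficient_n=False,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def rating_intercorrelation(
    records: pd.DataFrame | Sequence[TrialRecord],
    measure_x: str = "vection_magnitude",
    measure_y: str = "presence",
    experiment: int | None = None,
) -> AssociationResult:
    """Across-condition correlation of two measures over participant means.

    Each participant contributes the mean of each measure over their lap
    (non-stationary) trials; the correlation is computed across participants,
    so df = n_participants - 2.
    """
    if not isinstance(records, pd.DataFrame):
        records = trial_records_frame(records)
    frame = records[records["speed"].isin(LAP_SPEEDS)]
    if experiment is not None:
        frame = frame[frame["experiment"] == experiment]
    columns = list(dict.fromkeys([measure_x, measure_y]))
    means = frame.groupby("participant_id")[columns].mean()
    return pearson_assoc(means[measure_x], means[measure_y])
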