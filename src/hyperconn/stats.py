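"""Session-level aggregation and mixed-design statistics.

The experimental unit is the juggling session (a unique dyad); per-trial
network metrics are first averaged within (session, condition, juggler or
hyperbrain, measure) cells.  The design crosses two within-session factors
— condition (SOLO vs PAIRED) and skill level (the less vs the more
experienced juggler of the dyad) — with one between-session factor, skill
similarity (MATCHED when the jugglers' experience differs by at most three
years, UNMATCHED otherwise).

Because every factor has exactly two levels, the split-plot (mixed) ANOVA
decomposes exactly into per-session contrast scores: each within effect
(and its interaction with the between factor) is a one- or two-sample
*t*-test on the corresponding contrast, with F = t^2 and its own error
stratum; group means are weighted equally (Type-III convention) when group
sizes differ.  Sphericity corrections are moot with 2-level factors.

Effect sizes are partial eta squared, eta_p^2 = F df1 / (F df1 + df2), and
observed power follows the fixed-effects post-hoc convention: the
noncentral-F tail probability beyond the alpha critical value with
noncentrality lambda = F df1.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

MATCHED_MAX_YEARS_DIFF = 3.0
HYPERBRAIN_MEASURES = ("G", "C", "SWI", "D", "IIR")


# ---------------------------------------------------------------------------
# design


@dataclass(frozen=True)
class JugglerInfo:
    subject: str
    handedness: str
    years_experience: float


@dataclass(frozen=True)
class SessionDesign:
    """One session: a unique pairing of two jugglers.

    J1 is always the less experienced juggler.  The matched flag follows
    the three-year rule on the experience difference.
    """

    session_id: str
    j1: JugglerInfo
    j2: JugglerInfo
    matched: bool
    n_solo_trials: dict[str, int] = field(default_factory=dict)  # per juggler
    n_paired_trials: int = 0

    def __post_init__(self) -> None:
        if self.j1.years_experience > self.j2.years_experience:
            raise ValueError("J1 must be the less experienced juggler")
        diff = self.j2.years_experience - self.j1.years_experience
        if self.matched != (diff <= MATCHED_MAX_YEARS_DIFF):
            raise ValueError(
                f"matched flag inconsistent with {diff:g}-year experience difference"
            )

    @property
    def experience_difference(self) -> float:
        return self.j2.years_experience - self.j1.years_experience


def _session(sid, s1, h1, y1, s2, h2, y2, matched, nsolo1, nsolo2, npair):
    return SessionDesign(
        session_id=sid,
        j1=JugglerInfo(s1, h1, y1),
        j2=JugglerInfo(s2, h2, y2),
        matched=matched,
        n_solo_trials={"J1": nsolo1, "J2": nsolo2},
        n_paired_trials=npair,
    )


#: The seven retained dyadic sessions of the study design: subject codes,
#: handedness, years of juggling experience, matched flag (<= 3 years
#: difference) and retained trial counts.  One juggler (Subj. 10) appears
#: in two sessions and is treated as independent across them.
STUDY_SESSIONS: tuple[SessionDesign, ...] = (
    _session("1", "Subj4", "right", 16, "Subj3", "right", 19, True, 8, 9, 4),
    _session("2", "Subj6", "right", 3, "Subj5", "right", 7, False, 9, 12, 3),
    _session("3", "Subj7", "right", 3, "Subj8", "right", 7, False, 9, 10, 6),
    _session("4", "Subj10", "left", 8, "Subj9", "right", 10, True, 8, 12, 6),
    _session("5", "Subj11", "right", 5, "Subj12", "right", 8, True, 10, 10, 4),
    _session("6", "Subj2", "right", 6, "Subj13", "right", 15, False, 7, 10, 3),
    _session("7", "Subj10", "left", 8, "Subj1", "left/right", 14, False, 9, 8, 8),
)


def read_design_csv(path) -> list[SessionDesign]:
    """Read a session design table (one row per session).

    Expected columns: session, subject_j1, handedness_j1, years_j1,
    subject_j2, handedness_j2, years_j2, matched (YES/NO or bool),
    solo_trials_j1, solo_trials_j2, paired_trials.
    """
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        matched = str(r["matched"]).strip().upper() in ("YES", "TRUE", "1")
        out.append(
            _session(
                str(r["session"]),
                str(r["subject_j1"]),
                str(r["handedness_j1"]),
                float(r["years_j1"]),
                str(r["subject_j2"]),
                str(r["handedness_j2"]),
                float(r["years_j2"]),
                matched,
                int(r["solo_trials_j1"]),
                int(r["solo_trials_j2"]),
                int(r["paired_trials"]),
            )
        )
    return out


def design_frame(designs: list[SessionDesign] | None = None) -> pd.DataFrame:
    designs = list(designs) if designs is not None else list(STUDY_SESSIONS)
    return pd.DataFrame(
        {
            "session": [d.session_id for d in designs],
            "matched": [d.matched for d in designs],
            "years_j1": [d.j1.years_experience for d in designs],
            "years_j2": [d.j2.years_experience for d in designs],
        }
    )


# ---------------------------------------------------------------------------
# aggregation


def aggregate_session_means(trial_metrics: pd.DataFrame) -> pd.DataFrame:
    """Average per-trial metric values to session-level cells.

    ``trial_metrics`` is a tidy frame with columns (session, condition,
    unit, measure, trial, value) where ``unit`` is J1, J2 or 'hyperbrain'.
    Undefined values (NaN, e.g. an IIR with no inter-brain edges) are
    excluded from the mean with a warning.  Returns one row per (session,
    condition, unit, measure) with the mean and the trial count used.
    """
    required = {"session", "condition", "unit", "measure", "value"}
    missing = required - set(trial_metrics.columns)
    if missing:
        raise ValueError(f"trial metrics frame misses columns {sorted(missing)}")
    n_bad = int(trial_metrics["value"].isna().sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} undefined trial values excluded from session means",
            stacklevel=2,
        )
    grouped = (
        trial_metrics.dropna(subset=["value"])
        .groupby(["session", "condition", "unit", "measure"], as_index=False)
        .agg(value=("value", "mean"), n_trials=("value", "size"))
    )
    return grouped


# ---------------------------------------------------------------------------
# mixed ANOVA


@dataclass(frozen=True)
class AnovaResult:
    """One effect line of a mixed ANOVA."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    observed_power: float

    def __str__(self) -> str:  # reporting convention
        return (
            f"{self.effect}: F({self.df1},{self.df2}) = {self.F:.3f}, "
            f"p = {self.p:.3f}, eta_p^2 = {self.partial_eta_sq:.3f}, "
            f"Power = {self.observed_power:.3f}"
        )


def partial_eta_squared(F: float, df1: int, df2: int) -> float:
    """eta_p^2 = F df1 / (F df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("need F >= 0 and dfs >= 1")
    return (F * df1) / (F * df1 + df2)


def observed_power(F: float, df1: int, df2: int, alpha: float = 0.05) -> float:
    """Post-hoc power: P(F' > F_crit) with F' noncentral, lambda = F df1."""
    if df1 < 1 or df2 < 1:
        raise ValueError("invalid degrees of freedom")
    fcrit = sps.f.isf(alpha, df1, df2)
    lam = max(F, 0.0) * df1
    if lam == 0.0:
        return alpha
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def _f_to_result(effect: str, num: float, den: float, df2: int) -> AnovaResult:
    """Assemble an effect line from an SS-like numerator and variance."""
    if num <= 1e-24:
        F = 0.0
    elif den <= 1e-24:
        F = float("inf")
    else:
        F = num / den
    p = float(sps.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0
    eta = partial_eta_squared(F, 1, df2) if np.isfinite(F) else 1.0
    power = observed_power(F if np.isfinite(F) else 1e6, 1, df2)
    return AnovaResult(effect, F, 1, df2, p, eta, power)


def _cell_matrix(
    table: pd.DataFrame, dv: str, within: list[str]
) -> tuple[pd.DataFrame, list[tuple]]:
    """Sessions x within-cells matrix of dv means; errors if unbalanced."""
    sub = table[table["measure"] == dv] if "measure" in table.columns else table
    if sub.empty:
        raise ValueError(f"no rows for measure {dv!r}")
    levels = [sorted(sub[w].unique()) for w in within]
    for w, lv in zip(within, levels):
        if len(lv) != 2:
            raise ValueError(f"within factor {w!r} must have exactly 2 levels")
    cells = list(itertools.product(*levels))
    pivot = sub.pivot_table(
        index="session", columns=within, values="value", aggfunc="mean"
    )
    pivot = pivot.reindex(
        columns=cells if len(within) > 1 else [c[0] for c in cells]
    )
    if pivot.isna().any().any():
        missing = pivot.index[pivot.isna().any(axis=1)].tolist()
        raise ValueError(f"sessions with incomplete within-cells: {missing}")
    return pivot, cells


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str],
    between: str | None = None,
) -> list[AnovaResult]:
    """Split-plot ANOVA with 2-level within factors and an optional
    2-level between-session factor.

    ``table`` is tidy with columns (session, <within factors...>, measure,
    value) plus the between column when requested; sessions are the random
    blocking unit.  Returns one :class:`AnovaResult` per main effect and
    interaction.  With a single 2-level within factor and no between
    factor, F equals the squared paired *t* statistic.
    """
    pivot, cells = _cell_matrix(table, dv, within)
    n_cells = len(cells)
    sessions = pivot.index.to_list()
    Y = pivot.to_numpy(dtype=float)

    if between is not None:
        gmap = (
            table.dropna(subset=[between])
            .drop_duplicates("session")
            .set_index("session")[between]
        )
        groups = [gmap.get(s) for s in sessions]
        glevels = sorted(set(groups))
        if len(glevels) != 2:
            raise ValueError(f"between factor {between!r} must have 2 levels")
        idx = [np.array([g == lv for g in groups]) for lv in glevels]
        n1, n2 = int(idx[0].sum()), int(idx[1].sum())
        if min(n1, n2) < 2:
            raise ValueError("each between level needs at least 2 sessions")
        df2 = len(sessions) - 2
    else:
        df2 = len(sessions) - 1
        if df2 < 1:
            raise ValueError("need at least 2 sessions")

    results: list[AnovaResult] = []

    def analyse(scores: np.ndarray, name: str, is_between_score: bool) -> None:
        if between is None:
            mean = scores.mean()
            var = scores.var(ddof=1) / len(scores)
            results.append(_f_to_result(name, mean**2, var, df2))
            return
        s1, s2_ = scores[idx[0]], scores[idx[1]]
        m1, m2 = s1.mean(), s2_.mean()
        ss_err = ((s1 - m1) ** 2).sum() + ((s2_ - m2) ** 2).sum()
        pooled = ss_err / df2
        if is_between_score:
            diff = m1 - m2
            results.append(
                _f_to_result(
                    f"{between}", diff**2, pooled * (1 / n1 + 1 / n2), df2
                )
            )
        else:
            grand = 0.5 * (m1 + m2)  # unweighted (Type-III) mean
            results.append(
                _f_to_result(
                    name, grand**2, pooled * 0.25 * (1 / n1 + 1 / n2), df2
                )
            )
            diff = m1 - m2
            results.append(
                _f_to_result(
                    f"{name} * {between}",
                    diff**2,
                    pooled * (1 / n1 + 1 / n2),
                    df2,
                )
            )

    # between main effect first (scores = subject means)
    if between is not None:
        analyse(Y.mean(axis=1), between, is_between_score=True)

    # within effects: one contrast per non-empty factor subset
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), r):
            codes = np.ones(n_cells)
            for k, cell in enumerate(cells):
                for f_i in combo:
                    lv = sorted({c[f_i] for c in cells})
                    codes[k] *= 1.0 if cell[f_i] == lv[1] else -1.0
            scores = (Y * codes).sum(axis=1) * (2.0**r / n_cells)
            name = " * ".join(within[f_i] for f_i in combo)
            analyse(scores, name, is_between_score=False)

    return results


# ---------------------------------------------------------------------------
# t-tests


@dataclass(frozen=True)
class TTestResult:
    name: str
    t: float
    df: int
    p_raw: float
    p_corrected: float
    cohen_d: float


def _cohen_d_paired(diff: np.ndarray) -> float:
    sd = diff.std(ddof=1)
    return float(diff.mean() / sd) if sd > 0 else 0.0


def followup_ttests(
    contrasts: list[tuple[str, np.ndarray, np.ndarray]],
    paired: bool = True,
    correction: str = "bonferroni",
) -> list[TTestResult]:
    """Follow-up t-tests with Bonferroni correction over the listed contrasts.

    Each contrast is (name, sample_a, sample_b).  Paired contrasts report
    Cohen's d as mean difference over the standard deviation of the
    differences; independent contrasts use the pooled standard deviation.
    """
    m = len(contrasts)
    if m == 0:
        return []
    out = []
    for name, a, b in contrasts:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if paired:
            if len(a) != len(b) or len(a) < 2:
                raise ValueError(f"contrast {name!r}: need >= 2 paired observations")
            diff = a - b
            if diff.std(ddof=1) == 0:
                t, p = (0.0, 1.0) if diff.mean() == 0 else (float("inf"), 0.0)
            else:
                t, p = sps.ttest_rel(a, b)
            df = len(a) - 1
            d = _cohen_d_paired(diff)
        else:
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"contrast {name!r}: need >= 2 per group")
            t, p = sps.ttest_ind(a, b, equal_var=True)
            df = len(a) + len(b) - 2
            pooled = np.sqrt(
                (
                    (len(a) - 1) * a.var(ddof=1)
                    + (len(b) - 1) * b.var(ddof=1)
                )
                / df
            )
            d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
        if correction == "bonferroni":
            p_corr = min(1.0, float(p) * m)
        elif correction is None or correction == "none":
            p_corr = float(p)
        else:
            raise ValueError(f"unknown correction {correction!r}")
        out.append(TTestResult(name, float(t), df, float(p), p_corr, d))
    return out


def hyperbrain_group_ttests(
    session_metrics: pd.DataFrame,
    measures: tuple[str, ...] = HYPERBRAIN_MEASURES,
) -> list[TTestResult]:
    """Independent t-tests comparing hyperbrain metrics between skill groups.

    ``session_metrics`` holds one row per (session, measure) with columns
    (session, measure, value, matched).  One equal-variance two-sided test
    per measure, MATCHED vs UNMATCHED; no multiplicity correction (the five
    tests are reported individually).
    """
    out = []
    for meas in measures:
        sub = session_metrics[session_metrics["measure"] == meas].dropna(
            subset=["value"]
        )
        a = sub[sub["matched"]]["value"].to_numpy(dtype=float)
        b = sub[~sub["matched"]]["value"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"measure {meas}: each group needs >= 2 sessions")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t, p = float("inf"), 0.0
                warnings.warn(
                    f"measure {meas}: zero variance in both groups with "
                    "different means",
                    stacklevel=2,
                )
        else:
            t, p = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
        pooled = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
        )
        d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
        out.append(
            TTestResult(meas, float(t), df, float(p), float(p), d)
        )
    return out
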