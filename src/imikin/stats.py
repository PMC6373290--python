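"""Inferential layer: 2x2x2 repeated-measures ANOVA, partial eta squared,
and Bonferroni-gated paired t tests with a repeated-measures Hedges g.

All factors (stimulation site, action meaning, effector) have two levels, so
every effect has 1 numerator df, its error term is the effect-by-subject
interaction with n-1 df, and sphericity is trivially satisfied — no
Greenhouse-Geisser machinery is needed.  Each effect's F equals the squared
paired t on the corresponding within-subject contrast scores, which the test
suite exploits as an identity check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_trials import EFFECTORS, MEANINGS, SITES, IntegrityError

FACTOR_LEVELS = {"site": SITES, "meaning": MEANINGS, "effector": EFFECTORS}

EFFECT_NAMES = (
    "site", "meaning", "effector",
    "site:meaning", "site:effector", "meaning:effector",
    "site:meaning:effector",
)


class StatError(ValueError):
    pass


@dataclass
class EffectResult:
    """One ANOVA effect: F(df_num, df_den), p, partial eta squared and the
    sums of squares behind them."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


@dataclass
class AnovaResult:
    variable: str
    n_participants: int
    effects: dict[str, EffectResult]
    ss_subject: float
    ss_total: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "variable": self.variable, "effect": e.effect, "F": e.F,
            "df_num": e.df_num, "df_den": e.df_den, "p": e.p,
            "partial_eta_sq": e.partial_eta_sq,
        } for e in self.effects.values()]
        return pd.DataFrame(rows)


@dataclass
class PairedComparison:
    t: float
    df: int
    p: float
    g_rm: float
    alpha_corrected: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.alpha_corrected is None:
            return None
        return self.p < self.alpha_corrected


def _cell_matrix(table: pd.DataFrame, variable: str) -> tuple[np.ndarray,
                                                              list[str]]:
    """Participants x 8 cell-mean matrix in fixed condition order."""
    sub = table[table["variable"] == variable]
    if sub.empty:
        raise StatError(f"no rows for variable {variable!r}")
    participants = sorted(sub["participant_id"].unique())
    cells = [(s, m, e) for s in SITES for m in MEANINGS for e in EFFECTORS]
    lookup = {(r.participant_id, r.site, r.meaning, r.effector): r.cell_mean
              for r in sub.itertuples()}
    Y = np.empty((len(participants), 8))
    for i, p in enumerate(participants):
        for j, cond in enumerate(cells):
            key = (p, *cond)
            if key not in lookup:
                raise IntegrityError(
                    f"participant {p} is missing cell "
                    f"site={cond[0]}, meaning={cond[1]}, effector={cond[2]} "
                    f"for variable {variable!r} (no imputation is performed)"
                )
            Y[i, j] = lookup[key]
    return Y, participants


def _effect_codes() -> dict[str, np.ndarray]:
    """+/-1 contrast codes over the 8 cells for the 7 effects."""
    site = np.repeat([1, -1], 4)
    meaning = np.tile(np.repeat([1, -1], 2), 2)
    effector = np.tile([1, -1], 4)
    return {
        "site": site,
        "meaning": meaning,
        "effector": effector,
        "site:meaning": site * meaning,
        "site:effector": site * effector,
        "meaning:effector": meaning * effector,
        "site:meaning:effector": site * meaning * effector,
    }


def rm_anova_2x2x2(table: pd.DataFrame, variable: str) -> AnovaResult:
    """Classical within-subjects ANOVA of participant x condition cell means.

    ``table`` is a long condition table with columns participant_id, site,
    meaning, effector, variable, cell_mean; every participant must have all
    8 cells (a missing cell raises, naming the participant and condition).
    For each effect, F = MS_effect / MS_(effect x subject) and partial eta
    squared = SS_effect / (SS_effect + SS_error).
    """
    Y, participants = _cell_matrix(table, variable)
    n = len(participants)
    if n < 2:
        raise StatError("repeated-measures ANOVA needs at least 2 participants")
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    ss_subject = 8.0 * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((Y - grand) ** 2).sum())

    # float-noise floor: SS smaller than this relative to the table's total
    # variation is an exact zero (e.g. duplicated factor levels)
    tiny = 1e-12 * max(ss_total, 1e-300)

    effects: dict[str, EffectResult] = {}
    for name, code in _effect_codes().items():
        L = Y @ code  # per-subject contrast totals
        ss_eff = n * float(L.mean()) ** 2 / 8.0
        ss_err = float(((L - L.mean()) ** 2).sum()) / 8.0
        if ss_eff < tiny:
            ss_eff = 0.0
        if ss_err < tiny:
            ss_err = 0.0
        df_den = n - 1
        if ss_err == 0.0:
            F = np.inf if ss_eff > 0 else 0.0
        else:
            F = ss_eff / (ss_err / df_den)
        p = float(sps.f.sf(F, 1, df_den)) if np.isfinite(F) else 0.0
        denom = ss_eff + ss_err
        pes = ss_eff / denom if denom > 0 else 0.0
        effects[name] = EffectResult(
            effect=name, F=float(F), df_num=1, df_den=df_den, p=p,
            partial_eta_sq=float(pes), ss_effect=ss_eff, ss_error=ss_err,
        )
    return AnovaResult(variable=variable, n_participants=n, effects=effects,
                       ss_subject=ss_subject, ss_total=ss_total)


def hedges_g_rm(x: np.ndarray, y: np.ndarray) -> float:
    """Repeated-measures Hedges g for a paired contrast.

    d_rm = (mean(x) - mean(y)) / sqrt(s_x^2 + s_y^2 - 2 r s_x s_y)
           * sqrt(2 (1 - r)),
    then the small-sample correction 1 - 3 / (4 (n - 1) - 1).  The
    denominator before the sqrt(2(1-r)) factor equals the SD of the paired
    differences, so the estimate scales the paired d back onto the raw-score
    metric.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    d = x - y
    if np.allclose(d, 0.0):
        return 0.0
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise StatError("pair correlation undefined: one condition is constant")
    r = float(np.corrcoef(x, y)[0, 1])
    denom = np.sqrt(sx ** 2 + sy ** 2 - 2 * r * sx * sy)
    if denom == 0.0:
        raise StatError("zero variance of paired differences")
    d_rm = float(d.mean()) / denom * np.sqrt(2.0 * (1.0 - r))
    correction = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    return float(d_rm * correction)


def paired_t_grm(x: np.ndarray, y: np.ndarray,
                 alpha_corrected: float | None = None) -> PairedComparison:
    """Two-tailed paired t test with repeated-measures Hedges g.

    Identical vectors give t = 0, g = 0; a constant nonzero difference has no
    variance to test against and raises :class:`StatError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatError("paired vectors must be 1-D and equal length")
    n = len(x)
    if n < 2:
        raise StatError("paired t needs n >= 2")
    d = x - y
    if np.allclose(d, 0.0):
        return PairedComparison(t=0.0, df=n - 1, p=1.0, g_rm=0.0,
                                alpha_corrected=alpha_corrected)
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise StatError("zero difference variance: paired t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return PairedComparison(t=t, df=n - 1, p=p, g_rm=hedges_g_rm(x, y),
                            alpha_corrected=alpha_corrected)


def bonferroni_gate(p_values, family_size: int,
                    alpha: float = 0.05) -> np.ndarray:
    """Significance decisions at alpha / family_size (e.g. 0.05/8 = 0.00625
    for the eight-tracker family and the eight paired contrasts)."""
    if family_size < 1:
        raise StatError("family_size must be >= 1")
    return np.asarray(p_values, dtype=float) < alpha / family_size
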