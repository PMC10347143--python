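"""Within-subject statistical chain for the balance scores.

Reproduces the sensitivity analysis of the perturbation protocol: per
subject, the two repetitions of each of the 12 conditions (direction x
ramp rate x displacement) are averaged; each balance parameter then
enters a three-way repeated-measures ANOVA in which every within-subject
effect is tested against its own subject-by-effect interaction error
term. Sphericity is checked per multi-level effect with Mauchly's test
and, when violated, the Greenhouse-Geisser correction deflates the
degrees of freedom. Effect sizes are partial eta squared; post hoc
pairwise comparisons are Bonferroni-corrected paired t-tests with paired
Cohen's d (d_z) and noncentral-t confidence intervals.
"""
from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize
from scipy import stats as sps

from .trial_io import CopkitError

logger = logging.getLogger(__name__)


class AnalysisError(CopkitError):
    """The design is too incomplete or degenerate to analyse."""


FACTORS = ("direction", "ramp_rate", "displacement")
LEVELS = {
    "direction": ("FW", "BW"),
    "ramp_rate": (100.0, 200.0),
    "displacement": (25.0, 50.0, 100.0),
}

#: analysed balance parameters -> column in the trial-results table
PARAMETER_COLUMNS = {
    "area95": "area95_cm2",
    "unit_path": "unit_path_cm_s",
    "fp": "fp_mm",
    "dcop_max": "dcopmax_mm",
    "ppv": "ppv_mm",
}


# ---------------------------------------------------------------------------
# Condition table
# ---------------------------------------------------------------------------

def build_condition_table(results: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Subjects x 12-condition table of one parameter, repetitions averaged.

    ``results`` is the trial-results table (one row per trial).
    No-perturbation trials and null records are excluded; a cell with two
    repetitions is their mean. Subjects missing any of the 12 cells are
    dropped with a warning; fewer than 2 complete subjects is an error.
    The returned frame has a (direction, ramp_rate, displacement)
    MultiIndex on the columns in protocol order.
    """
    col = PARAMETER_COLUMNS.get(parameter, parameter)
    if col not in results.columns:
        raise AnalysisError(f"results table has no column {col!r}")
    df = results[(results["direction"] != "NONE") & results[col].notna()]
    cell = (
        df.groupby(["subject", "direction", "ramp_rate_mm_s", "displacement_mm"])[col]
        .mean()
    )
    wide = cell.unstack(["direction", "ramp_rate_mm_s", "displacement_mm"])
    wide.columns = wide.columns.set_names(list(FACTORS))
    ordered = pd.MultiIndex.from_tuples(
        list(itertools.product(LEVELS["direction"], LEVELS["ramp_rate"],
                               LEVELS["displacement"])),
        names=list(FACTORS),
    )
    missing_cells = [c for c in ordered if c not in wide.columns]
    if missing_cells:
        raise AnalysisError(
            f"no subject has data for condition(s) {missing_cells}"
        )
    wide = wide.reindex(columns=ordered)
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "dropping %d subject(s) with incomplete cells: %s",
            len(incomplete), ", ".join(map(str, incomplete)),
        )
        wide = wide.drop(index=incomplete)
    if len(wide) < 2:
        raise AnalysisError(
            f"need >= 2 complete subjects for the ANOVA, have {len(wide)}"
        )
    return wide


def _table_to_tensor(table: pd.DataFrame) -> np.ndarray:
    """(n_subjects, 2, 2, 3) tensor in protocol factor order."""
    n = len(table)
    shape = tuple(len(LEVELS[f]) for f in FACTORS)
    return table.to_numpy(dtype=float).reshape((n,) + shape)


# ---------------------------------------------------------------------------
# RM-ANOVA core
# ---------------------------------------------------------------------------

@dataclass
class EffectResult:
    """One within-subject effect of the RM-ANOVA."""

    effect: str
    ss_effect: float
    ss_error: float
    df1: int
    df2: int
    F: float
    p: float
    eta_p_sq: float
    mauchly_w: Optional[float] = None
    mauchly_p: Optional[float] = None
    gg_epsilon: Optional[float] = None
    p_gg: Optional[float] = None
    df1_gg: Optional[float] = None
    df2_gg: Optional[float] = None
    gg_applied: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def p_reported(self) -> float:
        """GG-corrected p when the correction was applied, raw p otherwise."""
        return self.p_gg if self.gg_applied else self.p


@dataclass
class AnovaResult:
    """All seven within-subject effects of the three-way RM-ANOVA."""

    n_subjects: int
    effects: dict[str, EffectResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            d = asdict(e)
            d["flags"] = ";".join(e.flags)
            rows.append(d)
        return pd.DataFrame(rows)


def eta_p_sq_from_f(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise AnalysisError("need F >= 0 and dfs >= 1")
    return F * df1 / (F * df1 + df2)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts (rows orthogonal to the constant)."""
    return sla.helmert(k, full=False)


def _effect_contrast(levels: Sequence[int], subset: Sequence[bool]) -> np.ndarray:
    """Kronecker contrast matrix spanning an interaction's subspace.

    For factors in the effect the (k-1) x k orthonormal contrasts enter
    the product; collapsed factors contribute nothing (the marginal has
    already been averaged over them).
    """
    C = np.ones((1, 1))
    for k, inc in zip(levels, subset):
        if inc:
            C = np.kron(C, _orthonormal_contrasts(k))
    return C


def _mauchly_gg(scores: np.ndarray) -> tuple[float, float, float]:
    """Mauchly's W (with chi-square p) and GG epsilon from contrast scores.

    ``scores`` is subjects x p, the per-subject orthonormal-contrast
    variables of the effect (p = effect df).
    """
    n, p = scores.shape
    S = np.cov(scores, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 0.0, None)
    tr = float(eig.sum())
    if tr <= 0:
        return float("nan"), float("nan"), 1.0
    W = float(np.prod(eig) / (tr / p) ** p)
    df_w = p * (p + 1) // 2 - 1
    if W <= 0 or n - 1 <= p:
        p_m = float("nan")
    else:
        fcorr = 1.0 - (2 * p * p + p + 2) / (6.0 * p * (n - 1))
        chi2_stat = -fcorr * (n - 1) * math.log(W)
        p_m = float(sps.chi2.sf(chi2_stat, df_w))
    eps = float(tr ** 2 / (p * np.sum(eig ** 2)))
    eps = min(max(eps, 1.0 / p), 1.0)
    return W, p_m, eps


def rm_anova_within(
    Y: np.ndarray,
    factor_names: Sequence[str],
    alpha_sphericity: float = 0.05,
) -> dict[str, EffectResult]:
    """Fully within-subject ANOVA of a subjects x levels... data tensor.

    ``Y`` has shape ``(n_subjects, L1, ..., Lk)``. Every within-subject
    effect (each non-empty subset of factors) is tested against its own
    subject-by-effect interaction; for effects with more than one degree
    of freedom Mauchly's test is run and the Greenhouse-Geisser
    correction applied when sphericity is rejected at
    ``alpha_sphericity``. Degenerate effects (zero error SS) are flagged
    with an undefined F rather than raising.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    levels = Y.shape[1:]
    k = len(levels)
    if len(factor_names) != k:
        raise AnalysisError("factor_names must match the tensor rank")
    if n < 2:
        raise AnalysisError("need >= 2 subjects")

    out: dict[str, EffectResult] = {}
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(k), r):
            name = ":".join(factor_names[i] for i in combo)
            inc = [i in combo for i in range(k)]
            # collapse factors outside the effect, center within it
            A = Y
            # averaging from the last axis keeps earlier axis numbers valid
            for ax in range(k, 0, -1):
                if not inc[ax - 1]:
                    A = A.mean(axis=ax)
            for ax in range(1, A.ndim):
                A = A - A.mean(axis=ax, keepdims=True)
            mult = float(np.prod([L for L, i in zip(levels, inc) if not i]))
            est = A.mean(axis=0)
            ss_eff = float(n * mult * np.sum(est ** 2))
            resid = A - est
            ss_err = float(mult * np.sum(resid ** 2))
            df1 = int(np.prod([L - 1 for L, i in zip(levels, inc) if i]))
            df2 = (n - 1) * df1
            flags: list[str] = []
            if ss_err <= 1e-12 * max(ss_eff, 1.0):
                if ss_eff <= 1e-12:
                    F = float("nan")
                    p = float("nan")
                    eta = 0.0
                    flags.append("degenerate_zero_ss")
                else:
                    F = float("nan")
                    p = float("nan")
                    eta = 1.0
                    flags.append("zero_error_ss")
            else:
                F = (ss_eff / df1) / (ss_err / df2)
                p = float(sps.f.sf(F, df1, df2))
                eta = ss_eff / (ss_eff + ss_err)
            res = EffectResult(effect=name, ss_effect=ss_eff, ss_error=ss_err,
                               df1=df1, df2=df2, F=F, p=p, eta_p_sq=eta,
                               flags=flags)

            if df1 > 1:
                # marginal means over the collapsed factors, per subject
                B = Y
                for ax in range(k, 0, -1):
                    if not inc[ax - 1]:
                        B = B.mean(axis=ax)
                B = B.reshape(n, -1)
                C = _effect_contrast(levels, inc)
                scores = B @ C.T
                W, p_m, eps = _mauchly_gg(scores)
                res.mauchly_w = W
                res.mauchly_p = p_m
                res.gg_epsilon = eps
                res.df1_gg = eps * df1
                res.df2_gg = eps * df2
                if np.isfinite(F):
                    res.p_gg = float(sps.f.sf(F, eps * df1, eps * df2))
                res.gg_applied = bool(np.isfinite(p_m) and p_m < alpha_sphericity)
            out[name] = res
    return out


def rm_anova3(table: pd.DataFrame,
              alpha_sphericity: float = 0.05) -> AnovaResult:
    """Three-way RM-ANOVA of a subjects x (2 x 2 x 3) condition table."""
    Y = _table_to_tensor(table)
    effects = rm_anova_within(Y, FACTORS, alpha_sphericity)
    return AnovaResult(n_subjects=Y.shape[0], effects=effects)


# ---------------------------------------------------------------------------
# Post hoc comparisons and effect sizes
# ---------------------------------------------------------------------------

@dataclass
class PairwiseResult:
    """One Bonferroni-corrected paired comparison of two factor levels."""

    comparison: str
    mean_diff: float
    ci_diff_95: tuple[float, float]
    cohens_d: float
    ci_d_95: tuple[float, float]
    t: float
    p_raw: float
    p_bonferroni: float
    n: int
    flags: list[str] = field(default_factory=list)


def cohens_d_paired(x, y) -> tuple[float, tuple[float, float]]:
    """Paired Cohen's d (d_z) with a 95% noncentral-t confidence interval.

    ``d = mean(x - y) / SD(x - y)`` (divisor n-1). The CI inverts the
    noncentral-t distribution of ``t = d*sqrt(n)`` at n-1 degrees of
    freedom. A zero-variance difference yields a signed infinite d.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise AnalysisError("paired vectors must be 1-D, equal length >= 2")
    diff = x - y
    n = diff.size
    sd = float(np.std(diff, ddof=1))
    mean = float(diff.mean())
    if sd == 0.0:
        d = math.copysign(math.inf, mean) if mean != 0 else 0.0
        return d, (float("nan"), float("nan"))
    d = mean / sd
    t_obs = d * math.sqrt(n)
    df = n - 1

    def ncp_for(q: float) -> float:
        # ncp such that the observed t sits at quantile q of nct(df, ncp)
        fn = lambda nc: sps.nct.cdf(t_obs, df, nc) - q
        lo, hi = t_obs - 2.0, t_obs + 2.0
        while fn(lo) < 0:
            lo -= 5.0
        while fn(hi) > 0:
            hi += 5.0
        return optimize.brentq(fn, lo, hi, xtol=1e-10)

    lo = ncp_for(0.975) / math.sqrt(n)
    hi = ncp_for(0.025) / math.sqrt(n)
    return d, (lo, hi)


def bonferroni_pairwise(table: pd.DataFrame, factor: str,
                        conf: float = 0.95) -> list[PairwiseResult]:
    """All pairwise paired t-tests on a factor's subject-level marginals.

    The marginal mean per subject and level averages over the other
    factors; the Bonferroni family is the set of level pairs of this
    factor (m = 3 for displacement, m = 1 for the two-level factors).
    The mean-difference CI uses the paired t distribution; the d CI the
    noncentral-t inversion.
    """
    if factor not in FACTORS:
        raise AnalysisError(f"unknown factor {factor!r}")
    lv = LEVELS[factor]
    marg = table.T.groupby(level=factor).mean().T[list(lv)]
    n = len(marg)
    pairs = list(itertools.combinations(lv, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        x = marg[a].to_numpy()
        y = marg[b].to_numpy()
        diff = x - y
        mean = float(diff.mean())
        sd = float(np.std(diff, ddof=1))
        flags: list[str] = []
        if sd == 0.0:
            flags.append("degenerate_zero_variance")
            d = math.copysign(math.inf, mean) if mean != 0 else 0.0
            res = PairwiseResult(
                comparison=f"{a} vs {b}", mean_diff=mean,
                ci_diff_95=(mean, mean), cohens_d=d,
                ci_d_95=(float("nan"), float("nan")),
                t=float("nan"), p_raw=float("nan") if mean != 0 else 1.0,
                p_bonferroni=float("nan") if mean != 0 else 1.0,
                n=n, flags=flags)
            out.append(res)
            continue
        se = sd / math.sqrt(n)
        t_obs = mean / se
        p_raw = float(2.0 * sps.t.sf(abs(t_obs), n - 1))
        tcrit = float(sps.t.ppf(0.5 + conf / 2.0, n - 1))
        d, ci_d = cohens_d_paired(x, y)
        out.append(PairwiseResult(
            comparison=f"{a} vs {b}", mean_diff=mean,
            ci_diff_95=(mean - tcrit * se, mean + tcrit * se),
            cohens_d=d, ci_d_95=ci_d, t=t_obs, p_raw=p_raw,
            p_bonferroni=min(1.0, m * p_raw), n=n, flags=flags))
    return out


def pairwise_to_frame(results: list[PairwiseResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "comparison": r.comparison,
            "mean_diff": r.mean_diff,
            "ci_diff_low": r.ci_diff_95[0],
            "ci_diff_high": r.ci_diff_95[1],
            "cohens_d": r.cohens_d,
            "ci_d_low": r.ci_d_95[0],
            "ci_d_high": r.ci_d_95[1],
            "t": r.t,
            "p_raw": r.p_raw,
            "p_bonferroni": r.p_bonferroni,
            "n": r.n,
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def run_full_analysis(
    results: pd.DataFrame,
    parameters: Sequence[str] = tuple(PARAMETER_COLUMNS),
    alpha: float = 0.05,
) -> dict:
    """ANOVA + post hocs for each balance parameter.

    Returns ``{parameter: {"anova": AnovaResult,
    "pairwise": {factor: [PairwiseResult, ...]}}}``.
    """
    report = {}
    for param in parameters:
        table = build_condition_table(results, param)
        anova = rm_anova3(table, alpha_sphericity=alpha)
        pairwise = {f: bonferroni_pairwise(table, f) for f in FACTORS}
        report[param] = {"anova": anova, "pairwise": pairwise}
    return report


def _jsonable(x):
    if isinstance(x, float) and not math.isfinite(x):
        return None
    return x


def report_to_json(report: dict) -> dict:
    """JSON-serialisable view of a full-analysis report."""
    out = {}
    for param, blocks in report.items():
        anova = blocks["anova"]
        out[param] = {
            "n_subjects": anova.n_subjects,
            "anova": {
                name: {k: _jsonable(v) for k, v in asdict(e).items()}
                for name, e in anova.effects.items()
            },
            "pairwise": {
                factor: [
                    {k: _jsonable(v) if not isinstance(v, tuple)
                     else [_jsonable(u) for u in v]
                     for k, v in asdict(r).items()}
                    for r in results
                ]
                for factor, results in blocks["pairwise"].items()
            },
        }
    return out


def write_report(report: dict, out_dir) -> None:
    """Write anova_<param>.csv, pairwise_<param>.csv and report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for param, blocks in report.items():
        blocks["anova"].to_frame().to_csv(out / f"anova_{param}.csv", index=False)
        frames = []
        for factor, res in blocks["pairwise"].items():
            frame = pairwise_to_frame(res)
            frame.insert(0, "factor", factor)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(
            out / f"pairwise_{param}.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(report_to_json(report), indent=2))
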