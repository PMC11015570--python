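"""Within-subject statistics on band-power tables.

The central object is :class:`RepeatedMeasuresAnova`, a one-way
within-subject ANOVA model built from a long-format table (one row per
subject × condition); its :meth:`~RepeatedMeasuresAnova.fit` returns a
:class:`RMAnovaResults` carrying the F test, Mauchly's sphericity test with
Greenhouse–Geisser correction, pairwise paired comparisons under Holm or
Bonferroni adjustment, Cousineau–Morey within-subject confidence intervals,
and a ``summary()`` table.

Model
-----
For n subjects and J conditions the classical decomposition is

    SS_total = SS_subjects + SS_conditions + SS_error,
    F = MS_conditions / MS_error  with df (J−1, (J−1)(n−1)).

Sphericity (equal variance of all pairwise condition differences) is
assessed by Mauchly's W; when rejected at α = 0.05 the reported p-value is
Greenhouse–Geisser corrected (df scaled by epsilon), while the uncorrected
F and df are always retained.

Pairwise comparisons default to the pooled ANOVA error term,
t = (M_a − M_b) / sqrt(2·MS_error/n) with df = (J−1)(n−1) — the convention
matching an omnibus df2 of, say, 78 at n = 40 and J = 3 — with an ordinary
paired t (df = n−1) available as ``error_term="per_pair"``.

Within-subject confidence intervals remove between-subject offsets
(Cousineau normalization: subtract the subject mean, add the grand mean)
and scale the normalized standard errors by Morey's factor sqrt(J/(J−1)).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .spectral import BandPowerTable

__all__ = [
    "RepeatedMeasuresAnova",
    "RMAnovaResults",
    "rm_anova",
    "pairwise_tests",
    "within_subject_ci",
    "cousineau_morey_ci",
    "run_statistics",
    "report_to_json",
]

logger = logging.getLogger(__name__)

SPHERICITY_ALPHA = 0.05


def _orthonormal_contrasts(j: int) -> np.ndarray:
    """(J−1) × J orthonormal contrast matrix (rows orthonormal, sum to 0)."""
    h = np.zeros((j - 1, j))
    for k in range(1, j):
        h[k - 1, :k] = 1.0
        h[k - 1, k] = -k
        h[k - 1] /= np.sqrt(k * (k + 1))
    return h


class RepeatedMeasuresAnova:
    """One-way repeated-measures ANOVA model.

    Parameters
    ----------
    data : DataFrame
        Long format: one row per subject × condition observation.
    dv, within, subject : str
        Column names of the dependent variable, the within-subject factor
        and the subject identifier.
    conditions : sequence of str, optional
        Condition order for reporting; defaults to order of appearance.

    Only complete cases are analyzed: subjects missing any condition are
    dropped (listwise) with a log message. At least 3 complete subjects and
    2 conditions are required.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str = "power_uv2",
        within: str = "condition",
        subject: str = "subject_id",
        conditions: Sequence[str] | None = None,
    ) -> None:
        for col in (dv, within, subject):
            if col not in data.columns:
                raise ValueError(f"column {col!r} not in data")
        self.dv, self.within, self.subject = dv, within, subject
        conds = list(conditions) if conditions is not None else list(pd.unique(data[within]))
        d = data[data[within].isin(conds)]
        wide = d.pivot_table(index=subject, columns=within, values=dv, aggfunc="first")
        wide = wide.reindex(columns=conds)
        incomplete = wide.index[wide.isna().any(axis=1)]
        if len(incomplete):
            logger.info("dropping incomplete subjects: %s", list(incomplete))
        wide = wide.dropna()
        if len(conds) < 2:
            raise ValueError("need at least 2 conditions")
        if len(wide) < 3:
            raise ValueError(
                f"need >= 3 complete subjects, have {len(wide)} after listwise deletion"
            )
        self.conditions = conds
        self.wide = wide  # subjects × conditions

    @classmethod
    def from_band_power(
        cls,
        table: BandPowerTable,
        band: str,
        channel: str,
        conditions: Sequence[str] | None = None,
    ) -> "RepeatedMeasuresAnova":
        """Build the model for one (band, channel) cell of a band-power table."""
        cell = table.cell(band, channel)
        if cell.empty:
            raise ValueError(f"no rows for band {band!r}, channel {channel!r}")
        m = cls(cell, conditions=conditions)
        m._band, m._channel = band, channel
        return m

    def fit(self) -> "RMAnovaResults":
        y = self.wide.to_numpy(dtype=float)
        n, j = y.shape
        grand = y.mean()
        subj_means = y.mean(axis=1)
        cond_means = y.mean(axis=0)
        ss_total = float(((y - grand) ** 2).sum())
        ss_subjects = float(j * ((subj_means - grand) ** 2).sum())
        ss_conditions = float(n * ((cond_means - grand) ** 2).sum())
        ss_error = ss_total - ss_subjects - ss_conditions
        df1, df2 = j - 1, (j - 1) * (n - 1)
        ms_cond = ss_conditions / df1
        ms_error = ss_error / df2
        if ms_error <= 0:
            warnings.warn("zero error variance; F reported as infinite", stacklevel=2)
            f_stat, p_unc = np.inf, 0.0
        else:
            f_stat = ms_cond / ms_error
            p_unc = float(sps.f.sf(f_stat, df1, df2))

        w, p_sph, gg_eps = self._sphericity(y)
        corrected = bool(p_sph < SPHERICITY_ALPHA)
        if np.isfinite(f_stat):
            p_gg = float(sps.f.sf(f_stat, df1 * gg_eps, df2 * gg_eps))
        else:
            p_gg = 0.0
        return RMAnovaResults(
            model=self,
            n_subjects=n,
            conditions=list(self.conditions),
            condition_means=dict(zip(self.conditions, cond_means)),
            condition_sds=dict(zip(self.conditions, y.std(axis=0, ddof=1))),
            ss_conditions=ss_conditions,
            ss_subjects=ss_subjects,
            ss_error=ss_error,
            ms_error=ms_error,
            F=float(f_stat),
            df1=df1,
            df2=df2,
            p=p_unc,
            sphericity_W=w,
            sphericity_p=p_sph,
            gg_epsilon=gg_eps,
            p_gg=p_gg,
            corrected=corrected,
            band=getattr(self, "_band", None),
            channel=getattr(self, "_channel", None),
        )

    @staticmethod
    def _sphericity(y: np.ndarray) -> tuple[float, float, float]:
        """Mauchly's W, its p-value, and Greenhouse–Geisser epsilon."""
        n, j = y.shape
        if j == 2:
            # one difference variance only: sphericity holds trivially
            return 1.0, 1.0, 1.0
        c = _orthonormal_contrasts(j)
        s = np.cov(y, rowvar=False, ddof=1)
        t = c @ s @ c.T
        eig = np.linalg.eigvalsh(t)
        eig = np.clip(eig, 0.0, None)
        tr = eig.sum()
        if tr <= 0:
            return 1.0, 1.0, 1.0
        gg_eps = float(tr**2 / ((j - 1) * (eig**2).sum()))
        mean_eig = tr / (j - 1)
        pos = eig[eig > 1e-300]
        w = float(np.exp(np.log(pos).sum()) / mean_eig ** (j - 1)) if len(pos) == j - 1 else 0.0
        d = j - 1
        df_chi = d * (d + 1) // 2 - 1
        if w <= 0:
            return 0.0, 0.0, gg_eps
        # chi-square series approximation with the standard second-order term
        f = 1 - (2 * d**2 + d + 2) / (6 * d * (n - 1))
        w2 = (
            (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * j + 2)
            / (288 * ((n - 1) * d * f) ** 2)
        )
        chi2 = -(n - 1) * f * np.log(w)
        p1 = sps.chi2.sf(chi2, df_chi)
        p2 = sps.chi2.sf(chi2, df_chi + 4)
        p = float(p1 + w2 * (p2 - p1))
        return w, p, gg_eps


@dataclass
class RMAnovaResults:
    """Fitted one-way repeated-measures ANOVA.

    ``p`` is the uncorrected p-value; when ``corrected`` is True (Mauchly's
    test rejected sphericity at α = 0.05) ``p_gg`` carries the
    Greenhouse–Geisser-corrected p alongside the always-reported
    uncorrected F and df.
    """

    model: RepeatedMeasuresAnova
    n_subjects: int
    conditions: list[str]
    condition_means: dict[str, float]
    condition_sds: dict[str, float]
    ss_conditions: float
    ss_subjects: float
    ss_error: float
    ms_error: float
    F: float
    df1: int
    df2: int
    p: float
    sphericity_W: float
    sphericity_p: float
    gg_epsilon: float
    p_gg: float
    corrected: bool
    band: str | None = None
    channel: str | None = None

    @property
    def partial_eta_sq(self) -> float:
        denom = self.ss_conditions + self.ss_error
        return self.ss_conditions / denom if denom > 0 else np.nan

    @property
    def p_reported(self) -> float:
        """GG-corrected p when sphericity was rejected, else the uncorrected p."""
        return self.p_gg if self.corrected else self.p

    def pairwise(self, method: str = "holm", error_term: str = "anova_pooled") -> pd.DataFrame:
        """All J(J−1)/2 pairwise comparisons with multiplicity adjustment.

        ``error_term="anova_pooled"`` uses t = (M_a − M_b)/sqrt(2·MS_error/n)
        with df = (J−1)(n−1); ``"per_pair"`` uses the ordinary paired t with
        df = n−1. ``method`` is "holm" or "bonferroni".
        """
        if method not in ("holm", "bonferroni"):
            raise ValueError(f"unknown adjustment method {method!r}")
        if error_term not in ("anova_pooled", "per_pair"):
            raise ValueError(f"unknown error term {error_term!r}")
        y = self.model.wide
        n = self.n_subjects
        rows = []
        for a, b in combinations(self.conditions, 2):
            ma, mb = self.condition_means[a], self.condition_means[b]
            if error_term == "anova_pooled":
                se = np.sqrt(2.0 * self.ms_error / n)
                t = (ma - mb) / se if se > 0 else np.inf * np.sign(ma - mb)
                df = self.df2
                p_raw = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
                if ma == mb:
                    t, p_raw = 0.0, 1.0
            else:
                t, p_raw = sps.ttest_rel(y[a], y[b])
                t, p_raw = float(t), float(p_raw)
                if np.isnan(t):  # identical columns -> zero variance of differences
                    t, p_raw = 0.0, 1.0
                df = n - 1
            rows.append(
                {
                    "condition_a": a,
                    "condition_b": b,
                    "mean_a": ma,
                    "mean_b": mb,
                    "sd_a": self.condition_sds[a],
                    "sd_b": self.condition_sds[b],
                    "t": t,
                    "df": df,
                    "p_raw": p_raw,
                }
            )
        out = pd.DataFrame(rows)
        out["p_adjusted"] = multipletests(out["p_raw"], method=method)[1]
        out["method"] = method
        return out

    def within_subject_ci(self, level: float = 0.95) -> pd.DataFrame:
        """Cousineau–Morey within-subject confidence intervals per condition.

        Each subject's offset (its mean across conditions) is removed and the
        grand mean restored; the normalized per-condition standard errors are
        scaled by sqrt(J/(J−1)) (Morey's correction) and the interval is
        mean ± t_crit(n−1) · SE · correction. With a single condition this
        reduces to the ordinary one-sample t interval.
        """
        return cousineau_morey_ci(
            self.model.wide.to_numpy(dtype=float), self.conditions, level
        )

    def summary(self) -> str:
        """Plain-text summary table."""
        lab = ""
        if self.band or self.channel:
            lab = f" [{self.band or '?'} @ {self.channel or '?'}]"
        lines = [
            f"Repeated-measures ANOVA{lab}",
            "=" * 58,
            f"n subjects: {self.n_subjects}    conditions: {', '.join(self.conditions)}",
            f"F({self.df1}, {self.df2}) = {self.F:.4g}, p = {self.p:.4g}"
            + (f"  (GG-corrected p = {self.p_gg:.4g})" if self.corrected else ""),
            f"MS_error = {self.ms_error:.4g}   partial eta^2 = {self.partial_eta_sq:.4g}",
            f"Mauchly W = {self.sphericity_W:.4g}, p = {self.sphericity_p:.4g}, "
            f"GG epsilon = {self.gg_epsilon:.4g}"
            + ("  [sphericity rejected]" if self.corrected else "  [sphericity ok]"),
            "-" * 58,
            "condition means (SD):",
        ]
        for c in self.conditions:
            lines.append(
                f"  {c:>16s}: {self.condition_means[c]:.4g} ({self.condition_sds[c]:.4g})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-shaped record with stable key order (both pairwise methods)."""
        d = {
            "band": self.band,
            "channel": self.channel,
            "n_subjects": self.n_subjects,
            "conditions": self.conditions,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "ms_error": self.ms_error,
            "partial_eta_sq": self.partial_eta_sq,
            "sphericity_W": self.sphericity_W,
            "sphericity_p": self.sphericity_p,
            "gg_epsilon": self.gg_epsilon,
            "p_gg": self.p_gg,
            "corrected": self.corrected,
            "condition_means": {c: self.condition_means[c] for c in self.conditions},
            "condition_sds": {c: self.condition_sds[c] for c in self.conditions},
        }
        pw_holm = self.pairwise("holm")
        pw_bonf = self.pairwise("bonferroni")
        pairwise = []
        for (_, h), (_, b) in zip(pw_holm.iterrows(), pw_bonf.iterrows()):
            pairwise.append(
                {
                    "condition_a": h["condition_a"],
                    "condition_b": h["condition_b"],
                    "mean_a": h["mean_a"],
                    "mean_b": h["mean_b"],
                    "sd_a": h["sd_a"],
                    "sd_b": h["sd_b"],
                    "t": h["t"],
                    "df": int(h["df"]),
                    "p_raw": h["p_raw"],
                    "p_holm": h["p_adjusted"],
                    "p_bonferroni": b["p_adjusted"],
                }
            )
        d["pairwise"] = pairwise
        ci = self.within_subject_ci()
        d["within_subject_ci"] = [
            {
                "condition": r["condition"],
                "mean": r["mean"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "level": r["level"],
                "method": r["method"],
            }
            for _, r in ci.iterrows()
        ]
        return d


def cousineau_morey_ci(
    y: np.ndarray, conditions: Sequence[str], level: float = 0.95
) -> pd.DataFrame:
    """Within-subject condition CIs from a subjects × conditions matrix.

    Cousineau normalization (subtract subject mean, add grand mean) followed
    by Morey's sqrt(J/(J−1)) scaling of the normalized standard errors;
    CI = mean ± t_crit(n−1) · SE · correction. With a single condition this
    is exactly the ordinary one-sample t interval.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    y = np.asarray(y, dtype=float)
    n, j = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects for a confidence interval")
    if j > 1:
        normalized = y - y.mean(axis=1, keepdims=True) + y.mean()
        morey = np.sqrt(j / (j - 1))
    else:
        normalized = y
        morey = 1.0
    means = y.mean(axis=0)
    se = normalized.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = sps.t.ppf(0.5 + level / 2, n - 1)
    half = tcrit * se * morey
    return pd.DataFrame(
        {
            "condition": list(conditions),
            "mean": means,
            "ci_low": means - half,
            "ci_high": means + half,
            "level": level,
            "method": "cousineau-morey",
        }
    )


def rm_anova(
    table: BandPowerTable,
    band: str,
    channel: str,
    conditions: Sequence[str] | None = None,
) -> RMAnovaResults:
    """Fit the one-way RM ANOVA for one (band, channel) cell."""
    return RepeatedMeasuresAnova.from_band_power(table, band, channel, conditions).fit()


def pairwise_tests(
    table: BandPowerTable,
    band: str,
    channel: str,
    method: str = "holm",
    error_term: str = "anova_pooled",
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Adjusted pairwise paired comparisons for one (band, channel) cell."""
    return rm_anova(table, band, channel, conditions).pairwise(method, error_term)


def within_subject_ci(
    table: BandPowerTable,
    band: str,
    channel: str,
    level: float = 0.95,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cousineau–Morey condition CIs for one (band, channel) cell.

    Works for any number of conditions (a single condition reduces to the
    ordinary one-sample t interval); complete cases only.
    """
    cell = table.cell(band, channel)
    if cell.empty:
        raise ValueError(f"no rows for band {band!r}, channel {channel!r}")
    conds = list(conditions) if conditions is not None else list(pd.unique(cell["condition"]))
    wide = cell.pivot(index="subject_id", columns="condition", values="power_uv2")
    wide = wide.reindex(columns=conds).dropna()
    return cousineau_morey_ci(wide.to_numpy(dtype=float), conds, level)


def run_statistics(
    table: BandPowerTable,
    bands: Sequence[str] | None = None,
    channels: Sequence[str] | None = None,
    conditions: Sequence[str] | None = None,
) -> dict:
    """ANOVA + pairwise (+ CIs) for every configured (band, channel) cell.

    Returns a JSON-shaped report dict with stable ordering; deterministic
    for a given table.
    """
    bands = list(bands) if bands is not None else table.bands
    channels = list(channels) if channels is not None else table.channels
    report: dict = {"analyses": []}
    for band in bands:
        for ch in channels:
            res = rm_anova(table, band, ch, conditions)
            report["analyses"].append(res.to_dict())
    return report


def report_to_json(report: Mapping, indent: int = 2) -> str:
    """Serialize a statistics report as stable structured text."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    return json.dumps(report, indent=indent, default=_default)
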