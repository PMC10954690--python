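"""The inferential chain linking speech markers to schizotypy and delusional
ideation.

Excerpt-level markers are first averaged per participant and transcript
version ("the mean of the eight one-minute excerpts"), then:

* Spearman correlations of every marker with each outcome, with
  Benjamini–Hochberg step-up FDR control applied per family — one family per
  (outcome × version) — flagged at the 0.05 and 0.01 levels;
* Mann–Whitney U tests between high/low trait groups, BH-corrected per
  version;
* a two-step regression ladder: demographics only, markers only (each
  version), demographics + markers (each version).  Linear models report
  R², adjusted R², RMSE, overall F and p; logistic models report threshold-
  0.5 classification metrics, rank-based AUC, and the Cox & Snell, Nagelkerke
  and Tjur pseudo-R².  All fit metrics are in-sample, matching the study
  design the ladder reproduces.

Missing data: pairwise deletion for correlations, complete-case rows
(identical across the five regressor sets, so the nested-model R² monotonicity
holds by construction) for the ladders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .features import MARKER_COLUMNS

__all__ = [
    "REGRESSOR_SETS",
    "RankDeficientError",
    "aggregate_participant",
    "attach_outcomes",
    "bh_flags",
    "correlate_bh",
    "group_test",
    "rank_auc",
    "LinearLadder",
    "LogisticLadder",
    "fit_linear_ladder",
    "fit_logistic_ladder",
    "report",
]

REGRESSOR_SETS = (
    "demographics",
    "markers_automated",
    "markers_manual",
    "demographics+markers_automated",
    "demographics+markers_manual",
)

KEYS = ["participant_id", "excerpt_id", "version"]


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


def _marker_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c in MARKER_COLUMNS]


def aggregate_participant(
    excerpt_features: pd.DataFrame, markers: Sequence[str] | None = None
) -> pd.DataFrame:
    """Participant-level marker means over available excerpts, per version.

    Missing excerpt-level values are excluded pairwise; a participant with no
    non-missing value for a marker gets a missing cell.
    """
    markers = list(markers) if markers is not None else _marker_columns(excerpt_features)
    grouped = excerpt_features.groupby(["participant_id", "version"], as_index=False)[markers]
    return grouped.mean()


def attach_outcomes(features: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Join the participant-level outcome/demographic table onto a tidy
    (participant, version) feature table."""
    return features.merge(outcomes, on="participant_id", how="left", validate="many_to_one")


def bh_flags(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags (NaN p-values excluded
    from the family and never rejected)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.zeros(len(p), dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    return out


def correlate_bh(
    features: pd.DataFrame,
    outcome_cols: Sequence[str] = ("spq", "pdi"),
    markers: Sequence[str] | None = None,
    alphas: Sequence[float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Spearman rho of each marker with each outcome, per version, with BH
    flags per (outcome × version) family at each requested level.

    ``features`` is the participant-level table with outcomes attached.
    Constant marker columns yield missing rho and leave the BH family.
    """
    markers = list(markers) if markers is not None else _marker_columns(features)
    rows = []
    for version, sub in features.groupby("version"):
        for outcome in outcome_cols:
            for marker in markers:
                pair = sub[[marker, outcome]].dropna()
                if len(pair) < 3 or pair[marker].nunique() == 1 or pair[outcome].nunique() == 1:
                    rho, p = np.nan, np.nan
                else:
                    rho, p = stats.spearmanr(pair[marker], pair[outcome])
                rows.append(
                    {
                        "marker": marker,
                        "outcome": outcome,
                        "version": version,
                        "n": len(pair),
                        "rho": rho,
                        "p_raw": p,
                    }
                )
    result = pd.DataFrame(rows)
    for alpha in alphas:
        col = f"significant_bh_{alpha:g}".replace("0.", "")
        flags = np.zeros(len(result), dtype=bool)
        for (_, _), idx in result.groupby(["outcome", "version"]).groups.items():
            idx = np.asarray(idx)
            flags[idx] = bh_flags(result.loc[idx, "p_raw"].to_numpy(), alpha)
        result[col] = flags
    return result


def group_test(
    features: pd.DataFrame,
    group_col: str = "group",
    markers: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Mann–Whitney U per marker between the two groups, per
    version, BH-corrected across markers within each version."""
    markers = list(markers) if markers is not None else _marker_columns(features)
    levels = sorted(features[group_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    rows = []
    for version, sub in features.groupby("version"):
        a = sub[sub[group_col] == levels[0]]
        b = sub[sub[group_col] == levels[1]]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("both groups need >= 2 participants")
        for marker in markers:
            x = a[marker].dropna().to_numpy()
            y = b[marker].dropna().to_numpy()
            if len(x) < 2 or len(y) < 2 or (np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]):
                u, p = np.nan, np.nan
            else:
                u1, p = stats.mannwhitneyu(x, y, alternative="two-sided")
                u = min(u1, len(x) * len(y) - u1)  # conventional U = min(U1, U2)
            rows.append({"marker": marker, "version": version, "u": u, "p_raw": p})
    result = pd.DataFrame(rows)
    flags = np.zeros(len(result), dtype=bool)
    for _, idx in result.groupby("version").groups.items():
        idx = np.asarray(idx)
        flags[idx] = bh_flags(result.loc[idx, "p_raw"].to_numpy(), alpha)
    result[f"significant_bh_{alpha:g}".replace("0.", "")] = flags
    return result


# ---------------------------------------------------------------------------
# regression ladders


def _wide_features(features: pd.DataFrame, markers: Sequence[str]) -> pd.DataFrame:
    """Pivot the tidy table to one row per participant with
    ``<marker>__<version>`` columns."""
    wide = features.pivot(index="participant_id", columns="version", values=list(markers))
    wide.columns = [f"{m}__{v}" for m, v in wide.columns]
    return wide.reset_index()


def _demographic_design(df: pd.DataFrame) -> pd.DataFrame:
    """Age and ordered education as numbers; gender and device one-hot with
    first-level reference."""
    parts = [df[["age"]].astype(float), df[["education"]].astype(float)]
    for cat in ("gender", "device"):
        dummies = pd.get_dummies(df[cat].astype(str), prefix=cat, drop_first=True, dtype=float)
        parts.append(dummies)
    return pd.concat(parts, axis=1)


def _regressors(
    table: pd.DataFrame, set_label: str, markers: Sequence[str]
) -> pd.DataFrame:
    cols = []
    if "demographics" in set_label:
        cols.append(_demographic_design(table))
    for version in ("automated", "manual"):
        if f"markers_{version}" in set_label:
            cols.append(table[[f"{m}__{version}" for m in markers]].astype(float))
    if not cols:  # intercept-only model
        return pd.DataFrame(index=table.index)
    return pd.concat(cols, axis=1)


def _drop_constant(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    constant = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
    return X.drop(columns=constant), constant


def _dependent_columns(X: pd.DataFrame) -> list[str]:
    """Columns exactly collinear with an *earlier* column (or the constant),
    by the diagonal of an unpivoted QR: R[j, j] ~ 0 iff column j lies in the
    span of the preceding ones."""
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    scale = np.linalg.norm(arr, axis=0)
    scale[scale == 0] = 1.0
    r = np.linalg.qr(arr / scale, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(arr.shape) * np.finfo(float).eps * 100
    names = ["const"] + list(X.columns)
    bad = [names[j] for j in range(len(diag)) if diag[j] < tol]
    bad += list(X.columns[len(diag) - 1 :]) if arr.shape[1] > len(diag) else []
    return [b for b in bad if b != "const"]


def _resolve_design(X: pd.DataFrame, drop_collinear: bool) -> tuple[pd.DataFrame, list[str]]:
    if X.shape[1] == 0:
        return X, []
    X, constant = _drop_constant(X)
    dropped = list(constant)
    for _ in range(2):  # one recheck after dropping
        bad = _dependent_columns(X)
        if not bad:
            break
        if not drop_collinear:
            raise RankDeficientError(f"collinear design columns: {sorted(bad)}")
        X = X.drop(columns=bad)
        dropped += bad
    return X, dropped


@dataclass
class _LadderBase:
    """Shared plumbing: complete-case rows over the union of all requested
    regressor sets, so every model in the ladder is fit on identical rows.

    Exactly collinear regressors (the marker set contains definitional
    identities, e.g. the all-tag count equals the word count) are dropped
    keeping the first occurrence and recorded in ``dropped_columns_``;
    ``drop_collinear=False`` raises instead, naming the columns.
    """

    markers: Sequence[str] | None = None
    drop_collinear: bool = True
    sets: Sequence[str] = REGRESSOR_SETS

    def _prepare(self, features: pd.DataFrame, outcomes: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        markers = list(self.markers) if self.markers is not None else _marker_columns(features)
        wide = _wide_features(features, markers)
        table = wide.merge(outcomes, on="participant_id", validate="one_to_one")
        versions = sorted(features["version"].unique())
        used = [f"{m}__{v}" for m in markers for v in versions
                if any(f"markers_{v}" in s for s in self.sets)]
        demo = ["age", "gender", "education", "device"] if any(
            "demographics" in s for s in self.sets) else []
        table = table.dropna(subset=[c for c in used + demo if c in table.columns])
        return table.reset_index(drop=True), markers


class LinearLadder(_LadderBase):
    """Ordinary-least-squares ladder over the five regressor sets.

    ``fit`` populates ``results_`` (one row per regressor set with R²,
    adjusted R², RMSE, F, p) and ``models_``.
    """

    def fit(self, features: pd.DataFrame, outcomes: pd.DataFrame, outcome: str = "spq") -> "LinearLadder":
        table, markers = self._prepare(features, outcomes)
        table = table.dropna(subset=[outcome]).reset_index(drop=True)
        y = table[outcome].astype(float)
        rows = []
        self.models_ = {}
        self.dropped_columns_ = {}
        for label in self.sets:
            X, dropped = _resolve_design(_regressors(table, label, markers), self.drop_collinear)
            self.dropped_columns_[label] = dropped
            if len(table) < X.shape[1] + 2:
                raise ValueError(f"{label}: need >= {X.shape[1] + 2} complete cases, have {len(table)}")
            design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add") if X.shape[1] else np.ones((len(y), 1))
            res = sm.OLS(y.to_numpy(), design).fit()
            rows.append(
                {
                    "regressor_set": label,
                    "outcome": outcome,
                    "n": int(res.nobs),
                    "k": X.shape[1],
                    "r2": res.rsquared,
                    "adjusted_r2": res.rsquared_adj,
                    "rmse": float(np.sqrt(res.ssr / res.nobs)),
                    "f": res.fvalue,
                    "p": res.f_pvalue,
                }
            )
            self.models_[label] = res
        self.results_ = pd.DataFrame(rows)
        return self


def rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve from the rank statistic (ties get half
    credit); 0.5 for constant scores."""
    y = np.asarray(y, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both classes for AUC")
    r = stats.rankdata(scores)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


class LogisticLadder(_LadderBase):
    """Maximum-likelihood logistic ladder over the five regressor sets.

    In-sample metrics per set: threshold-0.5 accuracy/sensitivity/
    specificity/precision/F-measure, rank AUC, and Cox & Snell
    (1 − (L₀/L₁)^(2/n)), Nagelkerke (Cox & Snell rescaled to max 1) and Tjur
    (mean p̂ separation) pseudo-R².  Perfect separation is flagged and the
    bounded (lbfgs-converged) estimates are still reported.
    """

    def fit(
        self,
        features: pd.DataFrame,
        outcomes: pd.DataFrame,
        group_col: str = "group",
        positive: str | None = None,
    ) -> "LogisticLadder":
        table, markers = self._prepare(features, outcomes)
        table = table.dropna(subset=[group_col]).reset_index(drop=True)
        levels = sorted(table[group_col].astype(str).unique())
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 classes, got {levels}")
        positive = positive or levels[1]
        y = (table[group_col].astype(str) == positive).to_numpy()
        if y.all() or not y.any():
            raise ValueError("both classes must be present")

        rows = []
        self.models_ = {}
        self.dropped_columns_ = {}
        for label in self.sets:
            X, dropped = _resolve_design(_regressors(table, label, markers), self.drop_collinear)
            self.dropped_columns_[label] = dropped
            if len(table) < X.shape[1] + 2:
                raise ValueError(f"{label}: need >= {X.shape[1] + 2} complete cases, have {len(table)}")
            design = (
                sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
                if X.shape[1]
                else np.ones((len(y), 1))
            )
            model = sm.Logit(y.astype(float), design)
            separated = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = model.fit(disp=0)
                    if not res.mle_retvals.get("converged", True):
                        raise PerfectSeparationError
                except (PerfectSeparationError, np.linalg.LinAlgError, Exception):
                    separated = True
                    res = model.fit(method="lbfgs", maxiter=500, disp=0)
            phat = res.predict(design)
            n = len(y)
            ll1, ll0 = res.llf, res.llnull
            cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
            nagelkerke = cox_snell / (1.0 - np.exp(2.0 * ll0 / n))
            tjur = float(phat[y].mean() - phat[~y].mean())

            pred = phat >= 0.5
            tp = int((pred & y).sum())
            tn = int((~pred & ~y).sum())
            fp = int((pred & ~y).sum())
            fn = int((~pred & y).sum())
            sens = tp / (tp + fn)
            spec = tn / (tn + fp)
            prec = tp / (tp + fp) if tp + fp else np.nan
            f1 = 2 * prec * sens / (prec + sens) if prec and not np.isnan(prec) and (prec + sens) else np.nan

            rows.append(
                {
                    "regressor_set": label,
                    "n": n,
                    "k": X.shape[1],
                    "accuracy": (tp + tn) / n,
                    "auc": rank_auc(y, phat),
                    "sensitivity": sens,
                    "specificity": spec,
                    "precision": prec,
                    "f_measure": f1,
                    "nagelkerke_r2": float(nagelkerke),
                    "tjur_r2": tjur,
                    "cox_snell_r2": float(cox_snell),
                    "log_likelihood": float(ll1),
                    "separation_flagged": separated,
                }
            )
            self.models_[label] = res
        self.results_ = pd.DataFrame(rows)
        return self


def fit_linear_ladder(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome: str = "spq",
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    return LinearLadder(markers=markers).fit(features, outcomes, outcome=outcome).results_


def fit_logistic_ladder(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    group_col: str = "group",
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    return LogisticLadder(markers=markers).fit(features, outcomes, group_col=group_col).results_


def report(results: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write each result table as CSV plus a human-readable summary.

    Recognized keys: ``correlations``, ``group_tests``, ``linear_ladder``,
    ``logistic_ladder``, ``agreement``, ``quality`` — unknown keys are written
    as CSV too.  Re-running on the same inputs reproduces identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in results.items():
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)

    lines = []
    corr = results.get("correlations")
    if corr is not None and not corr.empty:
        stars = corr.copy()
        level_cols = [c for c in corr.columns if c.startswith("significant_bh_")]

        def star(row):
            s = f"{row['rho']:.3f}" if np.isfinite(row["rho"]) else "NA"
            if level_cols and row[level_cols[-1]]:
                s += "**"
            elif level_cols and row[level_cols[0]]:
                s += "*"
            return s

        stars["cell"] = stars.apply(star, axis=1)
        matrix = stars.pivot(index="marker", columns=["outcome", "version"], values="cell")
        lines += ["Spearman rho (marker x outcome, BH-flagged)", matrix.to_string(), ""]
    for key in ("group_tests", "linear_ladder", "logistic_ladder", "agreement", "quality"):
        table = results.get(key)
        if table is not None and not table.empty:
            lines += [key.replace("_", " "), table.to_string(index=False), ""]
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines), encoding="utf-8")
    written.append(summary)
    return written
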